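"""Online phase: basis pushforward, projection, convective tensor, errors."""

import numpy as np
import pytest

from rbeflow.coupling import build_global_system
from rbeflow.geometry import DeformationParams, build_chain
from rbeflow.offline import (PODConfig, run_offline, piola_pullback,
                             _ref_coords_of)
from rbeflow.online import (broken_norm_errors, build_convective_tensor,
                            build_reduced_system, pushforward_basis,
                            reconstruct, reduced_solve)
from rbeflow.timestepping import BDFScheme, InflowSpec, NewtonConfig, time_loop


@pytest.fixture(scope="module")
def rom_setup(props, basis2d):
    """Archive + FOM system + reduced system on a two-tube chain."""
    kinds = ["T1", "T1"]
    factory = lambda params: build_chain(kinds, params, resolution=4)
    base = [DeformationParams.identity(k) for k in kinds]
    pod = PODConfig(eps_u=1e-5, eps_p=1e-6, n_configurations=3, seed=2)
    inflow = InflowSpec(Q0=1.0, t_ramp=0.0, t0=0.02)
    scheme = BDFScheme(2, 2.5e-3)
    archive = run_offline(factory, base, kinds, pod, basis2d, t_end=0.03,
                          resolution=4, scheme=scheme, inflow=inflow)
    geo = build_chain(kinds, base, resolution=4)
    fom = build_global_system(geo, basis2d, props, inflow)
    rsys = build_reduced_system(fom, archive)
    return archive, fom, rsys, scheme


class TestPushforward:
    def test_identity_map_leaves_basis_unchanged(self, rom_setup):
        archive, fom, rsys, _ = rom_setup
        b = fom.blocks[0]
        V_hat = archive.blocks["T1"].V_u
        V = pushforward_basis(V_hat, b.subdomain.map, _ref_coords_of(b))
        assert np.allclose(V, V_hat)

    def test_pullback_of_pushforward_is_identity(self, props, basis2d):
        kinds = ["T1", "T1"]
        pars = [DeformationParams({"length_ratio": 1.3, "radius_ratio": 0.9,
                                   "bend_angle": 0.2}),
                DeformationParams.identity("T1")]
        geo = build_chain(kinds, pars, resolution=4)
        fom = build_global_system(geo, basis2d, props)
        b = fom.blocks[0]
        coords = _ref_coords_of(b)
        rng = np.random.default_rng(0)
        V_hat = rng.normal(size=(b.n_uf, 3))
        V = pushforward_basis(V_hat, b.subdomain.map, coords)
        for c in range(3):
            col = V[:, c]
            v = np.column_stack([col[0::2], col[1::2]])
            back = piola_pullback(b.subdomain.map, coords, v)
            flat = np.empty_like(col)
            flat[0::2], flat[1::2] = back[:, 0], back[:, 1]
            assert np.abs(flat - V_hat[:, c]).max() < 1e-10

    def test_rigid_rotation_preserves_h1_norms(self, props, basis2d):
        kinds = ["T1"]
        par = DeformationParams(DeformationParams.identity("T1").values,
                                rotation=0.8, translation=[1.0, 1.0])
        from rbeflow.geometry import (apply_deformation, build_reference_block,
                                      compose_modular_geometry, nonaffine_map)

        block = build_reference_block("T1", 4)
        sd = apply_deformation(block, nonaffine_map(block, par))
        geo = compose_modular_geometry([sd], [], inlets=[(0, "inlet")])
        fom = build_global_system(geo, basis2d, props)
        b = fom.blocks[0]
        rng = np.random.default_rng(1)
        V_hat = rng.normal(size=(b.n_uf, 4))
        V = pushforward_basis(V_hat, sd.map, _ref_coords_of(b))
        from rbeflow.offline import ReferenceBlockSpace

        rs = ReferenceBlockSpace.build("T1", 4)
        X_def = b.ops.X_u[np.ix_(b.free, b.free)]
        for c in range(4):
            n_ref = V_hat[:, c] @ (rs.X_u @ V_hat[:, c])
            n_def = V[:, c] @ (X_def @ V[:, c])
            assert n_def == pytest.approx(n_ref, rel=1e-8)


class TestProjection:
    def test_galerkin_congruence_identity(self, rom_setup):
        archive, fom, rsys, _ = rom_setup
        rng = np.random.default_rng(0)
        s = rsys.subs[0]
        y = rng.normal(size=s.n_u)
        full = s.V_u @ y
        assert full @ (fom.blocks[0].M_ff() @ full) == pytest.approx(
            y @ s.M @ y, rel=1e-10)

    def test_multiplier_rows_not_reduced(self, rom_setup):
        _, fom, rsys, _ = rom_setup
        assert rsys.B_red.shape[0] == fom.n_Lambda

    def test_identity_basis_reproduces_fe_system(self, props, basis2d):
        """With the full identity basis the reduced system IS the FE system."""
        geo = build_chain(["T1"], resolution=3)
        fom = build_global_system(geo, basis2d, props,
                                  InflowSpec(Q0=1.0, t_ramp=0.0, t0=0.01))
        import rbeflow.online as onl

        b = fom.blocks[0]
        sub = onl.ReducedSubdomain(
            V_u=np.eye(b.n_uf), V_p=np.eye(b.n_p),
            M=b.M_ff().toarray(), K=b.K_ff().toarray(),
            D=b.D_f().toarray(), blockop=b)
        B_red = fom.B_matrix().toarray()
        rsys = onl.ReducedSystem(fom, [sub], B_red)
        rng = np.random.default_rng(3)
        Y = rng.normal(size=fom.n_Y)
        t = 0.01
        assert np.allclose(rsys.F0(t, Y), fom.F0(t, Y), atol=1e-10)


class TestConvectiveTensor:
    def test_zero_truncation_gives_zero_contribution(self, rom_setup):
        _, _, rsys, _ = rom_setup
        s = rsys.subs[0]
        T = build_convective_tensor(s, 0)
        assert T.shape == (s.n_u, 0, 0)

    def test_full_tensor_matches_direct_projection(self, rom_setup):
        """Contraction of the precomputed tensor equals assembling the full
        convective operator and projecting, for random reduced states."""
        _, _, rsys, _ = rom_setup
        s = rsys.subs[0]
        s.tensor = build_convective_tensor(s, s.n_u)
        rng = np.random.default_rng(1)
        for _ in range(3):
            u = rng.normal(size=s.n_u)
            direct = s.convective_residual(u, use_tensor=False)
            tens = s.convective_residual(u, use_tensor=True)
            assert np.abs(direct - tens).max() < 1e-9 * max(np.abs(direct).max(), 1)
        s.tensor = None

    def test_single_mode_contribution(self, rom_setup):
        _, _, rsys, _ = rom_setup
        s = rsys.subs[0]
        T = build_convective_tensor(s, 1)
        u = np.zeros(s.n_u)
        u[0] = 0.7
        expected = 0.7**2 * T[:, 0, 0]
        s.tensor = T
        got = s.convective_residual(u, use_tensor=True)
        s.tensor = None
        assert np.allclose(got, expected)

    def test_invalid_truncation_rejected(self, rom_setup):
        _, _, rsys, _ = rom_setup
        with pytest.raises(ValueError):
            build_convective_tensor(rsys.subs[0], rsys.subs[0].n_u + 1)


class TestReducedSolve:
    def test_close_to_fom_with_tight_basis(self, rom_setup):
        archive, fom, rsys, scheme = rom_setup
        times, fstates, _ = time_loop(fom, scheme, 0.0, 0.03)
        _, rstates, _ = reduced_solve(rsys, scheme, 0.0, 0.03)
        rep = broken_norm_errors(fom, fstates, rsys, rstates, times)
        assert rep.e_u < 0.05
        assert rep.e_p < 0.05

    def test_multiplier_size_preserved(self, rom_setup):
        _, fom, rsys, scheme = rom_setup
        _, rstates, _ = reduced_solve(rsys, scheme, 0.0, 0.01)
        from rbeflow.coupling import multiplier_dof_count

        assert rstates.shape[1] - rsys.n_W == multiplier_dof_count(
            fom.geometry, fom.basis)

    def test_reduced_coefficients_decay(self, rom_setup):
        """Time-averaged magnitude of the reduced velocity coefficients
        decreases with the mode index (energy ordering of the POD)."""
        archive, fom, rsys, scheme = rom_setup
        _, rstates, _ = reduced_solve(rsys, scheme, 0.0, 0.03)
        s = rsys.subs[0]
        n_pod = archive.blocks["T1"].n_pod_u  # energy-ordered POD block
        coeffs = np.abs(rstates[1:, :n_pod]).mean(axis=0)
        head = coeffs[:5].mean()
        tail = coeffs[-10:].mean()
        assert head >= 10 * tail


class TestReconstruction:
    def test_project_then_reconstruct_in_span(self, rom_setup):
        _, fom, rsys, _ = rom_setup
        s = rsys.subs[0]
        rng = np.random.default_rng(2)
        y = rng.normal(size=s.n_u)
        u_full = s.V_u @ y
        X = fom.blocks[0].ops.X_u[np.ix_(fom.blocks[0].free, fom.blocks[0].free)]
        y_back = s.V_u.T @ (X @ u_full)  # X-orthonormal basis
        assert np.abs(s.V_u @ y_back - u_full).max() < 1e-8

    def test_zero_coefficients_zero_fields(self, rom_setup):
        _, _, rsys, _ = rom_setup
        rec = reconstruct(rsys, np.zeros(rsys.n_Y))
        for u, p in rec:
            assert np.abs(u).max() == 0.0 and np.abs(p).max() == 0.0


class TestBrokenNorms:
    def test_identical_trajectories_give_zero(self, rom_setup):
        _, fom, rsys, scheme = rom_setup
        times, rstates, _ = reduced_solve(rsys, scheme, 0.0, 0.01)
        # build the "FOM" trajectory by reconstructing the ROM itself
        nt = rstates.shape[0]
        fstates = np.zeros((nt, fom.n_Y))
        off_f = fom.w_offsets
        for k in range(nt):
            rec = reconstruct(rsys, rstates[k])
            for j, b in enumerate(fom.blocks):
                fstates[k, off_f[j]: off_f[j] + b.n_uf] = rec[j][0]
                fstates[k, off_f[j] + b.n_uf: off_f[j + 1]] = rec[j][1]
        rep = broken_norm_errors(fom, fstates, rsys, rstates, times)
        assert rep.e_u == 0.0 and rep.e_p == 0.0

    def test_mismatched_lengths_rejected(self, rom_setup):
        _, fom, rsys, _ = rom_setup
        with pytest.raises(ValueError):
            broken_norm_errors(fom, np.zeros((3, fom.n_Y)), rsys,
                               np.zeros((4, rsys.n_Y)), np.zeros(3))

    def test_two_domain_combination_closed_form(self, rom_setup):
        """Broken norm combines per-subdomain norms by root sum of squares
        before taking the ratio (hand-checkable two-domain case)."""
        _, fom, rsys, scheme = rom_setup
        times = np.array([0.0, 1.0])
        # FOM states: subdomain fields with known X-norms; ROM states zero
        fstates = np.zeros((2, fom.n_Y))
        rng = np.random.default_rng(4)
        fstates[:, :] = rng.normal(size=fom.n_Y)
        rstates = np.zeros((2, rsys.n_Y))
        rep = broken_norm_errors(fom, fstates, rsys, rstates, times)
        # with u_N = 0 the relative velocity error is exactly 1
        assert rep.e_u == pytest.approx(1.0, rel=1e-12)
        # and the traces combine the two subdomains in quadrature
        per_dom = []
        for j, b in enumerate(fom.blocks):
            u, _ = fom.subdomain_state(fstates[0], j)
            X = b.ops.X_u[np.ix_(b.free, b.free)]
            per_dom.append(u @ (X @ u))
        assert rep.u_traces[0] == pytest.approx(np.sqrt(sum(per_dom)), rel=1e-12)
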
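"""Offline phase: sampling, Piola transformation, weighted POD, supremizers."""

import numpy as np
import pytest
import scipy.sparse as sp

from rbeflow.geometry import (DeformationParams, TUBE_PARAM_SPEC,
                              build_chain, build_reference_block,
                              nonaffine_map)
from rbeflow.interface_basis import build_basis_set
from rbeflow.offline import (PODConfig, ReferenceBlockSpace, BasisArchive,
                             build_archive, collect_snapshots,
                             compute_supremizers, finalize_basis,
                             piola_pullback, piola_pushforward,
                             pod_truncation_rank, run_offline,
                             sample_configurations, weighted_pod)
from rbeflow.timestepping import BDFScheme, InflowSpec


def spec_of(_j):
    return TUBE_PARAM_SPEC


class TestSampling:
    def test_zero_halfwidths_reproduce_base(self):
        base = [DeformationParams.identity("T1")]
        pod = PODConfig(halfwidth_ratio=0.0, halfwidth_angle=0.0,
                        n_configurations=4, seed=0)
        cfgs = sample_configurations(base, spec_of, pod)
        for cfg in cfgs:
            assert cfg[0].values == base[0].values

    def test_fixed_seed_is_reproducible(self):
        base = [DeformationParams.identity("T2")] * 2
        pod = PODConfig(n_configurations=5, seed=42)
        a = sample_configurations(base, spec_of, pod)
        b = sample_configurations(base, spec_of, pod)
        for ca, cb in zip(a, b):
            for pa, pb in zip(ca, cb):
                assert pa.values == pb.values

    def test_samples_centred_on_base(self):
        """Empirical mean within 3 standard errors of the base value."""
        base = [DeformationParams.identity("T1")]
        pod = PODConfig(n_configurations=200, seed=7)
        cfgs = sample_configurations(base, spec_of, pod)
        draws = np.array([c[0].values["length_ratio"] for c in cfgs])
        se = (2 * pod.halfwidth_ratio / np.sqrt(12)) / np.sqrt(len(draws))
        assert abs(draws.mean() - 1.0) < 3 * se

    def test_samples_admissible(self):
        base = [DeformationParams({"length_ratio": 0.8, "radius_ratio": 0.55,
                                   "bend_angle": -0.35})]
        pod = PODConfig(n_configurations=100, seed=3)
        for cfg in sample_configurations(base, spec_of, pod):
            for k, (lo, hi) in TUBE_PARAM_SPEC.items():
                assert lo <= cfg[0].values[k] <= hi


@pytest.fixture(scope="module")
def tube_space():
    return ReferenceBlockSpace.build("T1", 5)


class TestPiola:
    def test_identity_map_is_identity(self, tube_space):
        block = tube_space.block
        gmap = nonaffine_map(block, DeformationParams.identity("T1"))
        rng = np.random.default_rng(0)
        v = rng.normal(size=(tube_space.ref_coords_free_nodes.shape[0], 2))
        v_hat = piola_pullback(gmap, tube_space.ref_coords_free_nodes, v)
        assert np.allclose(v_hat, v)

    def test_rigid_motion_rotates_components(self, tube_space):
        block = tube_space.block
        par = DeformationParams(DeformationParams.identity("T1").values,
                                rotation=0.9, translation=[3.0, -1.0])
        gmap = nonaffine_map(block, par)
        rng = np.random.default_rng(1)
        v = rng.normal(size=(tube_space.ref_coords_free_nodes.shape[0], 2))
        v_hat = piola_pullback(gmap, tube_space.ref_coords_free_nodes, v)
        # |J| = 1 for rigid motions: pullback is Q^T v
        assert np.allclose(v_hat, v @ par.Q)

    def test_roundtrip_identity(self, tube_space):
        block = tube_space.block
        gmap = nonaffine_map(block, DeformationParams(
            {"length_ratio": 1.4, "radius_ratio": 0.8, "bend_angle": 0.3}))
        coords = tube_space.ref_coords_free_nodes
        rng = np.random.default_rng(2)
        v = rng.normal(size=(coords.shape[0], 2))
        back = piola_pullback(gmap, coords, piola_pushforward(gmap, coords, v))
        assert np.abs(back - v).max() < 1e-10

    def test_divergence_preservation_under_stretch(self):
        """An exactly solenoidal field mapped through an analytic stretch
        keeps its discrete divergence at the FE-interpolation level."""
        from rbeflow.fem import (FluidProperties, assemble_constant_operators,
                                 build_taylor_hood_space, interpolate_velocity)

        block = build_reference_block("T1", 6)
        space = build_taylor_hood_space(block.mesh)
        ops = assemble_constant_operators(space, FluidProperties(1.0, 1.0))
        gmap = nonaffine_map(block, DeformationParams(
            {"length_ratio": 1.5, "radius_ratio": 1.0, "bend_angle": 0.0}))

        def v_phys(P):
            # divergence-free in physical coordinates
            return np.column_stack([np.sin(np.pi * P[:, 1]),
                                    np.cos(2 * P[:, 0])])

        coords = space.vel_node_coords()
        v_at_mapped = v_phys(gmap.phi(coords))
        v_hat = piola_pullback(gmap, coords, v_at_mapped)
        u_hat = np.empty(space.n_u)
        u_hat[0::2], u_hat[1::2] = v_hat[:, 0], v_hat[:, 1]
        div_mapped = np.abs(ops.D @ u_hat).max()
        # reference: discrete divergence of the interpolant of an exactly
        # solenoidal (unmapped) field of the same magnitude
        u_ref = interpolate_velocity(space, v_phys)
        div_ref = np.abs(ops.D @ u_ref).max()
        assert div_mapped < 5 * div_ref  # same interpolation-error scale


class TestWeightedPOD:
    def test_euclidean_weight_reduces_to_svd(self):
        rng = np.random.default_rng(0)
        S = rng.normal(size=(40, 8))
        modes, sigma = weighted_pod(S, sp.eye(40).tocsr(), eps=1e-12)
        U, s, _ = np.linalg.svd(S, full_matrices=False)
        assert np.allclose(sigma, s)
        for k in range(modes.shape[1]):
            assert min(np.abs(modes[:, k] - U[:, k]).max(),
                       np.abs(modes[:, k] + U[:, k]).max()) < 1e-8

    def test_projection_error_identity(self):
        """Sum of squared X-norm projection errors equals the sum of the
        discarded squared singular values (evaluated independently)."""
        rng = np.random.default_rng(1)
        n_h, n_s = 30, 12
        Q = rng.normal(size=(n_h, n_h))
        X = sp.csr_matrix(Q @ Q.T + n_h * np.eye(n_h))
        S = rng.normal(size=(n_h, n_s))
        modes, sigma = weighted_pod(S, X, eps=0.3)
        N = modes.shape[1]
        proj = modes @ (modes.T @ (X @ S))
        err = 0.0
        for i in range(n_s):
            d = S[:, i] - proj[:, i]
            err += d @ (X @ d)
        tail = np.sum(sigma[N:] ** 2)
        assert err == pytest.approx(tail, rel=1e-8)

    def test_truncation_boundary_case(self):
        """sigma = (2, 1), eps = sqrt(0.2): content 4/5 = 1 - eps^2 exactly,
        so a single mode suffices."""
        assert pod_truncation_rank(np.array([2.0, 1.0]), np.sqrt(0.2)) == 1

    def test_truncation_monotone_in_tolerance(self):
        sigma = np.geomspace(1, 1e-6, 20)
        ranks = [pod_truncation_rank(sigma, e) for e in (1e-1, 1e-3, 1e-5)]
        assert ranks == sorted(ranks)

    def test_gram_and_cholesky_paths_agree(self):
        rng = np.random.default_rng(2)
        n_h, n_s = 10, 18  # snapshots > DOFs forces the Cholesky path
        Q = rng.normal(size=(n_h, n_h))
        X = sp.csr_matrix(Q @ Q.T + n_h * np.eye(n_h))
        S = rng.normal(size=(n_h, n_s))
        m1, s1 = weighted_pod(S, X, eps=1e-10)
        m2, s2 = weighted_pod(S[:, : n_h - 1], X, eps=1e-10)  # Gram path
        assert np.allclose(s1[: n_h - 2][:3] > 0, [True] * 3)
        G = m1.T @ (X @ m1)
        assert np.abs(G - np.eye(G.shape[0])).max() < 1e-8


@pytest.fixture(scope="module")
def enriched(basis2d):
    rs = ReferenceBlockSpace.build("T1", 5)
    from rbeflow.offline import _ref_divergence, _reference_couplings

    D = _ref_divergence(rs)
    B_list = _reference_couplings(rs, basis2d)
    rng = np.random.default_rng(0)
    Sp_snap = rng.normal(size=(rs.space.n_p, 6))
    V_p, _ = weighted_pod(Sp_snap, rs.X_p, eps=1e-10)
    S_p, S_c = compute_supremizers(rs.X_u, D, V_p, B_list)
    return rs, D, B_list, V_p, S_p, S_c


class TestSupremizers:
    def test_defining_systems_satisfied(self, enriched):
        rs, D, B_list, V_p, S_p, S_c = enriched
        for l in range(S_p.shape[1]):
            r = rs.X_u @ S_p[:, l] - D.T @ V_p[:, l]
            assert np.abs(r).max() < 1e-10
        k = 0
        for B in B_list:
            for l in range(B.shape[0]):
                r = rs.X_u @ S_c[:, k] - np.asarray(B.todense())[l]
                assert np.abs(r).max() < 1e-10
                k += 1

    def test_coupling_supremizer_count(self, enriched, basis2d):
        _, _, B_list, _, _, S_c = enriched
        # tube: 2 interfaces x N_lambda
        assert S_c.shape[1] == 2 * basis2d.n_lambda

    def test_enrichment_raises_pressure_infsup(self, enriched):
        """beta_p^N strictly increases when the supremizers are appended."""
        rs, D, _, V_p, S_p, _ = enriched
        rng = np.random.default_rng(5)
        V_u_raw, _ = weighted_pod(rng.normal(size=(rs.free.size, 8)), rs.X_u, 1e-12)

        def infsup(V_u):
            Dn = V_p.T @ (D @ V_u)
            Xu_n = V_u.T @ (rs.X_u @ V_u)
            # normalize: columns X_u-orthonormal already
            s = np.linalg.svd(Dn, compute_uv=False)
            return s.min() if s.size else 0.0

        V_plain = finalize_basis(V_u_raw, np.zeros((rs.free.size, 0)), rs.X_u)
        V_enr = finalize_basis(V_u_raw, S_p, rs.X_u)
        assert infsup(V_enr) > infsup(V_plain) + 1e-10


class TestFinalize:
    def test_orthonormality_certificate(self, basis2d):
        rs = ReferenceBlockSpace.build("T1", 4)
        rng = np.random.default_rng(1)
        V = finalize_basis(rng.normal(size=(rs.free.size, 5)),
                           rng.normal(size=(rs.free.size, 3)), rs.X_u)
        G = V.T @ (rs.X_u @ V)
        assert np.abs(G - np.eye(G.shape[0])).max() < 1e-8

    def test_idempotent_on_orthonormal_input(self):
        rng = np.random.default_rng(2)
        X = sp.eye(20).tocsr()
        q, _ = np.linalg.qr(rng.normal(size=(20, 6)))
        V = finalize_basis(q, np.zeros((20, 0)), X)
        assert np.abs(V - q).max() < 1e-12

    def test_duplicate_vector_dropped(self):
        rng = np.random.default_rng(3)
        X = sp.eye(15).tocsr()
        v = rng.normal(size=(15, 1))
        V = finalize_basis(np.hstack([v, v]), np.zeros((15, 0)), X)
        assert V.shape[1] == 1

    def test_empty_basis_rejected(self):
        with pytest.raises(ValueError):
            finalize_basis(np.zeros((10, 0)), np.zeros((10, 0)), sp.eye(10).tocsr())


@pytest.fixture(scope="module")
def small_archive(basis2d):
    kinds = ["T1", "T1"]
    factory = lambda params: build_chain(kinds, params, resolution=4)
    base = [DeformationParams.identity(k) for k in kinds]
    pod = PODConfig(eps_u=1e-3, eps_p=1e-4, n_configurations=2, seed=5)
    return run_offline(factory, base, kinds, pod, basis2d, t_end=0.02,
                       resolution=4, scheme=BDFScheme(2, 2.5e-3),
                       inflow=InflowSpec(Q0=1.0, t_ramp=0.0, t0=0.015))


class TestOfflinePipeline:
    def test_smoke_and_certificates(self, small_archive):
        arch = small_archive
        bb = arch.blocks["T1"]
        rs = arch.ref_space("T1")
        G = bb.V_u.T @ (rs.X_u @ bb.V_u)
        assert np.abs(G - np.eye(G.shape[0])).max() < 1e-8
        Gp = bb.V_p.T @ (rs.X_p @ bb.V_p)
        assert np.abs(Gp - np.eye(Gp.shape[0])).max() < 1e-8
        assert arch.metadata["failures"] == 0

    def test_singular_values_nonincreasing(self, small_archive):
        bb = small_archive.blocks["T1"]
        assert np.all(np.diff(bb.sigma_u) <= 1e-12)
        assert np.all(np.diff(bb.sigma_p) <= 1e-12)

    def test_tighter_tolerance_gives_weakly_larger_basis(self, basis2d):
        kinds = ["T1", "T1"]
        factory = lambda params: build_chain(kinds, params, resolution=4)
        base = [DeformationParams.identity(k) for k in kinds]
        pod_loose = PODConfig(eps_u=1e-1, eps_p=1e-1, n_configurations=2, seed=5)
        snaps = collect_snapshots(factory, base, kinds, pod_loose, basis2d,
                                  t_end=0.02, scheme=BDFScheme(2, 2.5e-3),
                                  inflow=InflowSpec(Q0=1.0, t_ramp=0.0, t0=0.015))
        sizes = []
        for eps in (1e-1, 1e-2, 1e-4):
            pod = PODConfig(eps_u=eps, eps_p=eps, n_configurations=2, seed=5)
            arch = build_archive(snaps, kinds, pod, basis2d, resolution=4)
            sizes.append(arch.blocks["T1"].n_pod_u)
        assert sizes == sorted(sizes)
        assert sizes[-1] > sizes[0]

    def test_archive_roundtrip_and_hash_guard(self, small_archive, tmp_path):
        arch = small_archive
        arch.save(tmp_path / "arch")
        arch2 = BasisArchive.load(tmp_path / "arch")
        assert np.allclose(arch2.blocks["T1"].V_u, arch.blocks["T1"].V_u)
        # corrupt the stored hash: loading must fail loudly
        import json

        man = json.loads((tmp_path / "arch" / "manifest.json").read_text())
        man["blocks"]["T1"]["mesh_hash"] = "deadbeef00000000"
        (tmp_path / "arch" / "manifest.json").write_text(json.dumps(man))
        with pytest.raises(ValueError, match="hash"):
            BasisArchive.load(tmp_path / "arch")
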
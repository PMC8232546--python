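"""Truncated evaluation of the reduced convective term.

The quadratic convective term can be contracted from a precomputed
third-order tensor T[i,l,m] = int rho [(zeta_m . grad) zeta_l] . zeta_i
instead of assembling the full-order operator each Newton iteration.
Because the reduced coefficients decay rapidly with the mode index, the
double sum can be truncated to the first N_c modes with little accuracy
loss.  This script sweeps N_c and prints the error against the full-order
solution.
"""

import numpy as np

from rbeflow import (BDFScheme, DeformationParams, FluidProperties,
                     InflowSpec, PODConfig, broken_norm_errors, build_basis_set,
                     build_chain, build_global_system, build_reduced_system,
                     reduced_solve, run_offline, time_loop)

kinds = ["T1", "T1"]
factory = lambda params: build_chain(kinds, params, resolution=4)
base = [DeformationParams.identity(k) for k in kinds]
basis = build_basis_set(2, 5)
props = FluidProperties()
inflow = InflowSpec(Q0=1.0, t_ramp=0.0, t0=0.05)
scheme = BDFScheme(2, 2.5e-3)

pod = PODConfig(eps_u=4e-3, eps_p=1e-4, n_configurations=4, seed=7)
archive = run_offline(factory, base, kinds, pod, basis, props=props,
                      scheme=scheme, inflow=inflow, t_end=0.1, resolution=4)

geo = build_chain(kinds, base, resolution=4)
fom = build_global_system(geo, basis, props, inflow)
times, fstates, _ = time_loop(fom, scheme, 0.0, 0.1)

n_full = archive.blocks["T1"].V_u.shape[1]
print(f"velocity basis size N = {n_full}")
print(f"{'N_c':>6} {'e_u':>12} {'e_p':>12}")
for n_c in (None, n_full, n_full // 2, n_full // 4, n_full // 8):
    rsys = build_reduced_system(fom, archive, n_c=n_c,
                                use_tensor=n_c is not None)
    _, rstates, _ = reduced_solve(rsys, scheme, 0.0, 0.1)
    rep = broken_norm_errors(fom, fstates, rsys, rstates, times)
    label = "direct" if n_c is None else str(n_c)
    print(f"{label:>6} {rep.e_u:>12.3e} {rep.e_p:>12.3e}")
print("\nN_c = N reproduces the direct projection; moderate truncation "
      "leaves the error at the POD level while cutting the online cost.")
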
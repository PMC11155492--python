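"""Spectral photon-counting CT: simulate a scan and reconstruct materials.

Generates the small preset (16x16 grid, 3 materials, 24 angles x 24 cells,
3 energy windows, 1e5 photons per ray), draws Poisson counts, reconstructs
the material images by maximum likelihood with nonconvex ADMM, and prints
the loss and error trajectory.
"""

import numpy as np

from nladmm.ct.forward import (
    build_projection_matrix,
    expected_counts,
    forward_project,
    simulate_counts,
)
from nladmm.ct.recon import CtReconConfig, ct_loss, run_ct_recon
from nladmm.synthetic import ct_preset

bundle = ct_preset("small")
P = build_projection_matrix(bundle["grid"], bundle["geometry"])
y_true = forward_project(P, bundle["phantom"])
mean = expected_counts(y_true, bundle["spectrum"], bundle["attenuation"])
counts = simulate_counts(mean, seed=1)
loss_at_truth = ct_loss(y_true, bundle["spectrum"], bundle["attenuation"], counts)

result = run_ct_recon(
    P,
    bundle["spectrum"],
    bundle["attenuation"],
    counts,
    CtReconConfig(sigma=100.0, T=300),
    truth=bundle["phantom"],
)
log = result.log

print(f"scan: {P.shape[0]} rays x {P.shape[1]} pixels, {int(counts.sum())} photons detected")
print(f"negative log-likelihood at the true phantom: {loss_at_truth:.6g}")
for t in (1, 50, 150, 300):
    row = log[log.t == t].iloc[0]
    print(
        f"  t={t:4d}  loss(Px_t)-loss(truth)={row.loss_Pxt - loss_at_truth:12.2f}"
        f"  rmse={row.rmse_x:.4f}  newton_resid={row.max_newton_residual:.2e}"
    )
print("The data loss descends toward (and below) the truth's loss as the")
print("estimate fits the Poisson noise; the RMSE drops sharply from the zero")
print("init and settles at the statistical floor of this photon budget.")
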
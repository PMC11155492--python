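"""Empirical restricted-strong-convexity and stationarity reports.

The convergence guarantee for nonconvex ADMM rests on two conditions that
cannot be verified analytically for the CT likelihood: restricted strong
convexity along the algorithm's path, and approximate first-order
optimality of the ground truth. In simulation both are checkable: the
per-iteration curvature ratio ``alpha_t`` should stay bounded away from
zero, and the gradient-norm ratio ``||grad g(y~)|| / ||grad g(0)||``
should be small. This module packages those checks into a report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import RunResult
from .ct.forward import AttenuationTable, SpectralModel
from .ct.recon import ct_grad_g, fosp_gradient_ratio, rsc_alpha_series

__all__ = ["RscReport", "compute_rsc_report"]


@dataclass
class RscReport:
    """alpha_t series, its minimum, and the stationarity ratio for one run."""

    alpha_series: np.ndarray
    min_alpha: float
    fosp_ratio: float
    sigma: float
    T: int
    seed: object = None
    undefined_count: int = 0
    params: dict = field(default_factory=dict)

    @property
    def rsc_holds(self) -> bool:
        return np.isfinite(self.min_alpha) and self.min_alpha > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": np.arange(1, len(self.alpha_series) + 1), "alpha_t": self.alpha_series}
        )

    def summary(self) -> str:
        lines = [
            "Restricted strong convexity / stationarity report",
            f"  sigma = {self.sigma:g}, T = {self.T}, seed = {self.seed}",
            f"  min alpha_t over defined entries: {self.min_alpha:.6g}"
            + ("" if self.rsc_holds else "  <-- RSC SURROGATE FAILURE (min alpha <= 0)"),
            f"  undefined alpha_t entries (||y_t - y~|| ~ 0): {self.undefined_count}",
            f"  ||grad g(y~)||/||grad g(0)||: {self.fosp_ratio:.6g}",
        ]
        return "\n".join(lines)


def compute_rsc_report(
    result: RunResult,
    P: sp.spmatrix,
    spectrum: SpectralModel,
    att: AttenuationTable,
    counts: np.ndarray,
    truth: np.ndarray,
    sigma: float,
    seed=None,
) -> RscReport:
    """Build the report from a reconstruction run with stored history.

    ``truth`` is the ground-truth phantom (nk, nm); the diagnostic needs it
    (simulation-only feature) to form ``y~ = P x~``.
    """
    if result.history is None:
        raise ValueError("run was executed without store_history=True")
    if truth is None:
        raise ValueError("the RSC diagnostic needs the ground-truth phantom")
    nl, nk = P.shape
    nm = att.nm
    truth = np.asarray(truth, dtype=float)
    truth_y = np.asarray(P @ truth).ravel()
    from .ct.recon import build_preconditioners

    pre = build_preconditioners(P, sigma)
    sigma_diag = np.repeat(pre.SigmaTilde_diag, nm)

    def grad_g(y_vec):
        return ct_grad_g(y_vec.reshape(nl, nm), spectrum, att, counts).ravel()

    def apply_A(x_vec):
        return np.asarray(P @ x_vec.reshape(nk, nm)).ravel()

    alphas = rsc_alpha_series(result.history, truth_y, grad_g, sigma_diag, apply_A)
    defined = alphas[np.isfinite(alphas)]
    return RscReport(
        alpha_series=alphas,
        min_alpha=float(defined.min()) if defined.size else np.nan,
        fosp_ratio=fosp_gradient_ratio(
            truth_y.reshape(nl, nm), spectrum, att, counts
        ),
        sigma=float(sigma),
        T=len(result.history),
        seed=seed,
        undefined_count=int(np.sum(~np.isfinite(alphas))),
    )
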
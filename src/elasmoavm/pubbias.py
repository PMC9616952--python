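"""Publication-bias diagnostics: contour-enhanced funnel plot and an
Egger-type regression asymmetry test.

Effect sizes are continuity-corrected logit proportions with delta-method
standard errors. The pooled effect comes from a random-effects fit on the
logit scale; asymmetry is tested by inverse-variance-weighted regression of
effect on standard error with study-cluster-robust errors. The funnel's
shaded contours mark conventional two-sided significance bands (p = 0.10,
0.05, 0.01) around the no-effect reference, widening linearly with the
standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .data import AVMDataset
from .screening import dersimonian_laird_tau2, logit_effects

__all__ = ["FunnelResult", "funnel_analysis", "funnel_plot", "egger_test"]

CONTOUR_P = (0.10, 0.05, 0.01)
_Z = {0.10: 1.6449, 0.05: 1.9600, 0.01: 2.5758}


@dataclass
class FunnelResult:
    effects: np.ndarray  # logit-scale effect per record
    std_errors: np.ndarray
    pooled_effect: float
    tau2: float
    slope: float
    slope_se: float
    p_value: float
    n_records: int
    n_clusters: int

    @property
    def asymmetric(self) -> bool:
        return self.p_value < 0.05

    def to_dict(self) -> dict:
        return {
            "pooled_effect": self.pooled_effect, "tau2": self.tau2,
            "egger_slope": self.slope, "egger_slope_se": self.slope_se,
            "egger_p": self.p_value, "asymmetric": self.asymmetric,
            "n_records": self.n_records, "n_clusters": self.n_clusters,
        }


def egger_test(
    effects: np.ndarray,
    std_errors: np.ndarray,
    weights: np.ndarray,
    groups: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Weighted regression of effect on standard error; returns
    (slope, slope SE, two-sided p). Cluster-robust covariance when study
    groups are supplied."""
    X = sm.add_constant(std_errors)
    model = sm.WLS(effects, X, weights=weights)
    if groups is not None and len(np.unique(groups)) >= 2:
        res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
    else:
        res = model.fit(cov_type="HC1")
    return float(res.params[1]), float(res.bse[1]), float(res.pvalues[1])


def funnel_analysis(ds: AVMDataset, min_records: int = 10) -> FunnelResult:
    """Funnel asymmetry analysis of one dataset's effect sizes.

    Uses record-level points with study-level clustering: the pooled effect
    is the DerSimonian-Laird random-effects mean of the logit proportions,
    and the asymmetry test regresses effect on standard error with weights
    ``1 / (v_i + tau^2)`` and cluster-robust (study) covariance.
    """
    frame = ds.frame
    if len(frame) < min_records:
        raise ValueError(
            f"asymmetry tests are unreliable below {min_records} records (have {len(frame)})"
        )
    y, v = logit_effects(frame)
    se = np.sqrt(v)
    if np.allclose(y, y[0]):
        raise ValueError("all effects identical; funnel analysis degenerate")
    tau2 = dersimonian_laird_tau2(y, v)
    w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * y) / np.sum(w))

    groups = frame["study_id"].astype(str).to_numpy()
    n_clusters = len(np.unique(groups))
    slope, slope_se, p_value = egger_test(y, se, w, groups)
    return FunnelResult(
        effects=y, std_errors=se, pooled_effect=pooled, tau2=tau2,
        slope=slope, slope_se=slope_se, p_value=p_value,
        n_records=len(frame), n_clusters=n_clusters,
    )


def contour_bounds(se_grid: np.ndarray, reference: float = 0.0) -> dict:
    """Significance contour boundaries around the reference effect; the
    bands widen linearly with standard error and meet at the reference at
    SE = 0."""
    return {
        p: (reference - _Z[p] * se_grid, reference + _Z[p] * se_grid)
        for p in CONTOUR_P
    }


def funnel_plot(result: FunnelResult, path=None, reference: float = 0.0):
    """Contour-enhanced funnel plot: effect vs standard error with shaded
    significance regions and the pooled-effect line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    se_max = float(result.std_errors.max()) * 1.05
    grid = np.linspace(0, se_max, 100)
    bands = contour_bounds(grid, reference)
    fig, ax = plt.subplots(figsize=(6, 5))
    shades = {0.10: "0.92", 0.05: "0.82", 0.01: "0.70"}
    prev_lo, prev_hi = bands[0.10]
    ax.fill_betweenx(grid, prev_lo, prev_hi, color="white", zorder=0)
    for p in (0.10, 0.05, 0.01):
        lo, hi = bands[p]
        ax.fill_betweenx(grid, lo, prev_lo, color=shades[p], zorder=0)
        ax.fill_betweenx(grid, prev_hi, hi, color=shades[p], zorder=0)
        prev_lo, prev_hi = lo, hi
    ax.plot(result.effects, result.std_errors, "o", ms=4, mfc="steelblue", mec="black", mew=0.3)
    ax.axvline(result.pooled_effect, color="firebrick", ls="--", lw=1.2,
               label=f"pooled logit = {result.pooled_effect:.2f}")
    ax.invert_yaxis()
    ax.set_xlabel("logit AVM proportion")
    ax.set_ylabel("standard error")
    ax.set_title(f"Egger slope p = {result.p_value:.3f}")
    ax.legend(loc="lower right", fontsize=8)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
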
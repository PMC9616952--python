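"""Posterior summaries: pooled and species-specific AVM rates, phylogenetic
signal, probability of direction, marginal means, ratio contrasts, forest
plots.

All derived quantities are computed draw-by-draw from the joint posterior and
summarized with the posterior mean and the 95% highest density interval
(the shortest credible interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import AVMDataset
from .model import FitResult

__all__ = [
    "PosteriorSummary",
    "SignalEstimate",
    "hdi",
    "probability_of_direction",
    "pooled_avm",
    "species_avm",
    "phylo_signal",
    "marginal_means",
    "ratio_contrast",
    "forest_plot",
]


@dataclass
class PosteriorSummary:
    label: str
    mean: float
    hdi_low: float
    hdi_high: float
    pd: float | None
    n_draws: int

    def to_dict(self) -> dict:
        return {
            "label": self.label, "mean": self.mean,
            "hdi_low": self.hdi_low, "hdi_high": self.hdi_high,
            "pd": self.pd, "n_draws": self.n_draws,
        }


@dataclass
class SignalEstimate:
    """Phylogenetic signal: posterior proportion of summed group-level
    variance attributable to the phylogenetic component."""

    draws: np.ndarray
    mean: float
    hdi_low: float
    hdi_high: float

    def summary(self) -> PosteriorSummary:
        return PosteriorSummary(
            "phylo_signal", self.mean, self.hdi_low, self.hdi_high, None, self.draws.size
        )


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Highest density interval: the narrowest contiguous window containing
    ``ceil(mass * n)`` of the sorted draws. Ties go to the lower window."""
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError("need >= 100 draws for an HDI")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    m = int(np.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first (lowest) minimizer
    return float(x[i]), float(x[i + m - 1])


def equal_tailed_interval(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    a = (1 - mass) / 2
    lo, hi = np.quantile(np.asarray(draws, dtype=float).ravel(), [a, 1 - a])
    return float(lo), float(hi)


def probability_of_direction(draws: np.ndarray) -> float:
    """max(P(effect > 0), P(effect < 0)); exact zeros split equally."""
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("need >= 100 draws")
    pos = np.mean(x > 0) + 0.5 * np.mean(x == 0)
    return float(max(pos, 1 - pos))


def _summarize(label, draws, signed=False, mass=0.95) -> PosteriorSummary:
    d = np.asarray(draws, dtype=float).ravel()
    lo, hi = hdi(d, mass)
    return PosteriorSummary(
        label, float(d.mean()), lo, hi,
        probability_of_direction(d) if signed else None, d.size,
    )


def _record_weights(fit: FitResult, weights: str) -> np.ndarray:
    if weights == "proportional":
        w = fit.design.trials.astype(float)
    elif weights == "equal":
        w = np.ones(fit.design.n)
    else:
        raise ValueError("weights must be 'proportional' or 'equal'")
    return w / w.sum()


def pooled_avm(fit: FitResult, weights: str = "proportional") -> PosteriorSummary:
    """Pooled mean AVM: per draw, the population-level expected response
    averaged over the observed moderator configurations (group effects at
    zero), weighted by sample size by default."""
    w = _record_weights(fit, weights)
    p = expit(fit.fixed_eta(fit.frame))  # (c, d, n)
    return _summarize("pooled_avm", p @ w)


def species_avm(fit: FitResult, weights: str = "proportional") -> list[PosteriorSummary]:
    """Conditional species-specific AVM rates: population terms plus each
    species' phylogenetic effect, sorted ascending by posterior mean."""
    if "phylo" not in fit.group_labels():
        raise ValueError("fit has no species-level (phylo) group term")
    w = _record_weights(fit, weights)
    eta_pop = fit.fixed_eta(fit.frame) @ w  # (c, d)
    levels, u = fit.group_effects("phylo")  # u: (c, d, S)
    out = [
        _summarize(sp, expit(eta_pop + u[..., i]))
        for i, sp in enumerate(levels)
    ]
    return sorted(out, key=lambda s: (s.mean, s.label))


def phylo_signal(fit: FitResult) -> SignalEstimate:
    """lambda = sigma_phylo^2 / sum_k sigma_k^2 over all group-level terms."""
    labels = fit.group_labels()
    if "phylo" not in labels:
        raise ValueError("fit has no phylogenetic group term")
    if len(labels) < 2:
        raise ValueError("signal needs at least one non-phylogenetic group term")
    var_phylo = fit.sigma("phylo") ** 2
    total = sum(fit.sigma(lb) ** 2 for lb in labels)
    lam = (var_phylo / total).ravel()
    lo, hi = hdi(lam)
    return SignalEstimate(lam, float(lam.mean()), lo, hi)


def marginal_means(
    fit: FitResult, by: str, weights: str = "proportional"
) -> list[PosteriorSummary]:
    """Estimated marginal means of the response for each level of ``by``.

    Per level, every record in the reference grid (the observed data) has the
    moderator forced to that level; predictions on the response scale are
    averaged with weights proportional to sample size (or equal)."""
    if by not in fit.frame.columns:
        raise ValueError(f"moderator {by!r} not in the fitted data")
    used = {e.column for e in fit.design.cat_encoders}
    used |= {e.column for e in fit.design.spline_encoders}
    used |= {c for c, _ in fit.design.spline_lin_only}
    if by not in used:
        raise ValueError(f"moderator {by!r} is not a term of the fitted model")
    w = _record_weights(fit, weights)
    out = []
    enc = next(e for e in fit.design.cat_encoders if e.column == by)
    for level in enc.levels:
        grid = fit.frame.copy()
        grid[by] = level
        p = expit(fit.fixed_eta(grid))
        out.append(_summarize(f"{by}={level}", p @ w))
    return out


def _level_mean_draws(fit: FitResult, term: str, level: str, w: np.ndarray) -> np.ndarray:
    grid = fit.frame.copy()
    grid[term] = level
    return expit(fit.fixed_eta(grid)) @ w


def ratio_contrast(
    fit: FitResult, term: str, level_a: str, level_b: str, weights: str = "proportional"
) -> PosteriorSummary:
    """Posterior ratio of marginal mean AVM at ``level_a`` over ``level_b``;
    ``pd`` is the probability the ratio exceeds 1."""
    enc = next((e for e in fit.design.cat_encoders if e.column == term), None)
    if enc is None:
        raise ValueError(f"term {term!r} is not a categorical term of the model")
    for lv in (level_a, level_b):
        if lv not in enc.levels:
            raise ValueError(f"level {lv!r} not present in term {term!r}")
    w = _record_weights(fit, weights)
    ratio = _level_mean_draws(fit, term, level_a, w) / _level_mean_draws(fit, term, level_b, w)
    d = ratio.ravel()
    lo, hi = hdi(d)
    return PosteriorSummary(
        f"{term}:{level_a}/{level_b}", float(d.mean()), lo, hi,
        float(np.mean(d > 1) + 0.5 * np.mean(d == 1)), d.size,
    )


def summaries_to_frame(summaries: list[PosteriorSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])


# ---------------------------------------------------------------------------
# forest plot


def _forest_table(ds: AVMDataset, pooled_p: float) -> pd.DataFrame:
    f = ds.frame
    x, n = f["n_dead"].to_numpy(float), f["n_caught"].to_numpy(float)
    p_tilde = (x + 0.5) / (n + 1.0)
    se_logit = np.sqrt(1 / (x + 0.5) + 1 / (n - x + 0.5))
    log_rr = np.log(p_tilde / pooled_p)
    # delta method: se(log p) ~ se(logit p) * (1 - p)
    se_log = se_logit * (1 - p_tilde)
    tab = pd.DataFrame(
        {
            "record_id": f["record_id"].to_numpy(),
            "study_id": f["study_id"].to_numpy(),
            "proportion": x / n,
            "log_rr": log_rr,
            "log_rr_low": log_rr - 1.96 * se_log,
            "log_rr_high": log_rr + 1.96 * se_log,
        }
    )
    return tab.sort_values("log_rr", kind="stable").reset_index(drop=True)


def forest_plot(
    ds: AVMDataset,
    fit: FitResult,
    split_by: str | None = None,
    path=None,
) -> dict:
    """Forest plot of study-level log relative risk ratios (vs the pooled
    rate) for a single-species subset, with the pooled-effect row and dashed
    pooled line; optionally split into panels by a moderator."""
    if ds.frame["species"].nunique() != 1:
        raise ValueError("forest plots are drawn per species; subset first")
    if len(ds.frame) < 2:
        raise ValueError("need >= 2 records for a forest plot")
    pooled = pooled_avm(fit)
    panels: dict[str, pd.DataFrame] = {}
    if split_by is None:
        panels["all records"] = _forest_table(ds, pooled.mean)
    else:
        for level, sub in ds.frame.groupby(split_by):
            if len(sub):
                panels[f"{split_by}={level}"] = _forest_table(AVMDataset(sub.copy()), pooled.mean)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        1, len(panels), figsize=(4.5 * len(panels), 0.28 * len(ds.frame) + 2),
        squeeze=False,
    )
    for ax, (title, tab) in zip(axes[0], panels.items()):
        ypos = np.arange(len(tab))[::-1] + 1
        ax.hlines(ypos, tab["log_rr_low"], tab["log_rr_high"], color="gray", lw=1)
        ax.plot(tab["log_rr"], ypos, "o", color="black", ms=3)
        ax.axvline(0.0, color="steelblue", ls="--", lw=1)
        ax.plot([0.0], [0], "D", color="steelblue", ms=6)
        ax.set_yticks(list(ypos) + [0])
        ax.set_yticklabels(list(tab["record_id"]) + ["Pooled"], fontsize=6)
        ax.set_xlabel("log relative risk vs pooled")
        ax.set_title(title, fontsize=9)
    fig.suptitle(f"{ds.frame['species'].iloc[0]} (pooled AVM {pooled.mean:.3f})")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return {"pooled": pooled, "panels": panels, "figure": fig}
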
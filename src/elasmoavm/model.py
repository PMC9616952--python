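"""Bayesian binomial-Normal hierarchical meta-regression.

The likelihood is an exact binomial for each effect size,
``n_dead_i ~ Binomial(n_caught_i, p_i)``, with

``logit(p_i) = b0 + X_i beta + f(z_i) + u_phylo[sp_i] + u_study[st_i]
               + u_record[i] + u_group[rg_i]``

Phylogenetic species effects are multivariate Normal with covariance
``sigma_phylo^2 * C`` (Brownian correlation matrix ``C``); the other group
effects are iid Normal; smooths use the mixed-model representation of a
penalized B-spline basis. Everything is sampled jointly with NUTS on a
non-centered parameterization with analytic gradients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .data import AVMDataset
from .design import Design, GroupTerm, ModelSpec, PriorSettings, build_design
from .hmc import sample_nuts

__all__ = [
    "FitResult",
    "BinomialPhyloMetaRegression",
    "fit_model",
    "convergence_report",
    "compare_models",
    "posterior_predictive_check",
]

RHAT_THRESHOLD = 1.01


# ---------------------------------------------------------------------------
# log posterior


class _Posterior:
    """Log posterior density and gradient over the unconstrained vector."""

    def __init__(self, design: Design, priors: PriorSettings):
        self.d = design
        self.priors = priors
        self._half_t_ss = priors.sd_df * priors.sd_scale**2

    def unpack(self, theta):
        s = self.d.slices
        return theta[s["intercept"]][0], theta[s["beta"]]

    def eta(self, theta, include_groups=True):
        d, s = self.d, self.d.slices
        b0 = theta[s["intercept"]][0]
        eta = b0 + d.X @ theta[s["beta"]]
        for i, enc in enumerate(d.spline_encoders):
            sig = np.exp(theta[s[f"log_sigma_spline_{enc.column}"]][0])
            eta = eta + sig * (d.spline_bases[i] @ theta[s[f"z_spline_{enc.column}"]])
        if include_groups:
            for g in d.groups:
                sig = np.exp(theta[s[f"log_sigma_{g.label}"]][0])
                z = theta[s[f"z_{g.label}"]]
                u = g.chol @ z if g.chol is not None else z
                eta = eta + sig * u[g.index]
        return eta

    def logp_and_grad(self, theta):
        d, s, pr = self.d, self.d.slices, self.priors
        grad = np.zeros_like(theta)
        b0 = theta[s["intercept"]][0]
        beta = theta[s["beta"]]

        eta = b0 + d.X @ beta
        spline_sigmas, group_sigmas, group_u = [], [], []
        for i, enc in enumerate(d.spline_encoders):
            sig = np.exp(theta[s[f"log_sigma_spline_{enc.column}"]][0])
            spline_sigmas.append(sig)
            eta = eta + sig * (d.spline_bases[i] @ theta[s[f"z_spline_{enc.column}"]])
        for g in d.groups:
            sig = np.exp(theta[s[f"log_sigma_{g.label}"]][0])
            group_sigmas.append(sig)
            z = theta[s[f"z_{g.label}"]]
            u = g.chol @ z if g.chol is not None else z
            group_u.append(u)
            eta = eta + sig * u[g.index]

        p = expit(eta)
        lp = float(np.sum(d.y * eta - d.trials * np.logaddexp(0.0, eta)))
        r = d.y - d.trials * p  # d loglik / d eta

        # intercept prior
        if pr.intercept == "flat_response":
            lp += b0 - 2.0 * np.logaddexp(0.0, b0)
            grad[s["intercept"]] = np.sum(r) + 1.0 - 2.0 * expit(b0)
        else:  # Student-t(3, 0, scale)
            ss = 3.0 * pr.intercept_scale**2
            lp += -2.0 * np.log1p(b0**2 / ss)
            grad[s["intercept"]] = np.sum(r) - 4.0 * b0 / (ss + b0**2)

        # fixed-effect coefficients ~ Normal(0, coef_scale)
        cs2 = pr.coef_scale**2
        lp += -0.5 * float(beta @ beta) / cs2
        grad[s["beta"]] = d.X.T @ r - beta / cs2

        for i, enc in enumerate(d.spline_encoders):
            key, kls = f"z_spline_{enc.column}", f"log_sigma_spline_{enc.column}"
            z = theta[s[key]]
            sig = spline_sigmas[i]
            bt_r = d.spline_bases[i].T @ r
            lp += -0.5 * float(z @ z)
            grad[s[key]] = sig * bt_r - z
            lp += self._log_half_t(sig)
            grad[s[kls]] = sig * float(bt_r @ z) + self._dlog_half_t(sig)

        for j, g in enumerate(d.groups):
            key, kls = f"z_{g.label}", f"log_sigma_{g.label}"
            z = theta[s[key]]
            sig = group_sigmas[j]
            u = group_u[j]
            agg = np.bincount(g.index, weights=r, minlength=len(g.levels))
            lp += -0.5 * float(z @ z)
            grad[s[key]] = sig * (g.chol.T @ agg if g.chol is not None else agg) - z
            lp += self._log_half_t(sig)
            grad[s[kls]] = sig * float(agg @ u) + self._dlog_half_t(sig)
        return lp, grad

    def _log_half_t(self, sig):
        # half-Student-t(df, 0, scale) density on sigma, plus log-Jacobian of
        # the log transform
        nu = self.priors.sd_df
        return -(nu + 1) / 2 * np.log1p(sig**2 / self._half_t_ss) + np.log(sig)

    def _dlog_half_t(self, sig):
        nu = self.priors.sd_df
        return -(nu + 1) * sig**2 / (self._half_t_ss + sig**2) + 1.0

    def initial_point(self, rng):
        d = self.d
        theta = 0.1 * rng.standard_normal(d.dim)
        p0 = (d.y.sum() + 0.5) / (d.trials.sum() + 1.0)
        theta[d.slices["intercept"]] = np.log(p0 / (1 - p0)) + 0.2 * rng.standard_normal()
        for name, sl in d.slices.items():
            if name.startswith("log_sigma"):
                theta[sl] = np.log(0.4) + 0.2 * rng.standard_normal()
        return theta


# ---------------------------------------------------------------------------
# fit result


@dataclass
class FitResult:
    """Posterior draws plus the design metadata needed for prediction."""

    spec: ModelSpec
    design: Design
    frame: pd.DataFrame
    theta: np.ndarray  # (chains, draws, dim)
    step_sizes: list
    divergences: int
    warning_flags: list = field(default_factory=list)
    _diagnostics: pd.DataFrame | None = None

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.theta.shape[1]

    def parameter(self, name: str) -> np.ndarray:
        """Draws for a named block, shape (chains, draws, size)."""
        return self.theta[..., self.design.slices[name]]

    def sigma(self, label: str) -> np.ndarray:
        """(chains, draws) draws of a group or spline standard deviation."""
        return np.exp(self.theta[..., self.design.slices[f"log_sigma_{label}"]][..., 0])

    def group_labels(self) -> list[str]:
        return [g.label for g in self.design.groups]

    def group_effects(self, label: str) -> tuple[list, np.ndarray]:
        """(level names, draws (chains, draws, m)) of u = sigma * L z."""
        g = next(gr for gr in self.design.groups if gr.label == label)
        z = self.parameter(f"z_{label}")
        if g.chol is not None:
            z = z @ g.chol.T
        return g.levels, z * self.sigma(label)[..., None]

    def named_posterior(self) -> dict:
        """Posterior as named (chains, draws, ...) arrays for diagnostics."""
        out = {"intercept": self.parameter("intercept")[..., 0]}
        beta = self.parameter("beta")
        for i, nm in enumerate(self.design.coef_names):
            out[f"b_{nm}"] = beta[..., i]
        for g in self.design.groups:
            out[f"sigma_{g.label}"] = self.sigma(g.label)
        for e in self.design.spline_encoders:
            out[f"sigma_spline_{e.column}"] = self.sigma(f"spline_{e.column}")
        return out

    # -- linear predictors --------------------------------------------------
    def linear_predictor(self, include_groups=True) -> np.ndarray:
        """eta draws on the fit data, shape (chains, draws, n_records)."""
        eta = self.fixed_eta(self.frame)
        if include_groups:
            for g in self.design.groups:
                _, u = self.group_effects(g.label)
                eta = eta + u[..., g.index]
        return eta

    def fixed_eta(self, frame: pd.DataFrame) -> np.ndarray:
        """Population-level (group effects at zero) eta draws for new data:
        intercept + fixed effects + spline smooths; shape (c, d, len(frame))."""
        s = self.design.slices
        X = self.design.fixed_matrix(frame)
        b0 = self.theta[..., s["intercept"]][..., 0]
        eta = b0[..., None] + self.theta[..., s["beta"]] @ X.T
        for i, enc in enumerate(self.design.spline_encoders):
            B = enc.random(frame)
            sig = np.exp(self.theta[..., s[f"log_sigma_spline_{enc.column}"]][..., 0])
            eta = eta + sig[..., None] * (self.theta[..., s[f"z_spline_{enc.column}"]] @ B.T)
        return eta

    def log_likelihood(self) -> np.ndarray:
        """Pointwise binomial log-likelihood, shape (chains, draws, n)."""
        eta = self.linear_predictor(include_groups=True)
        y, n = self.design.y, self.design.trials
        const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
        return const + y * eta - n * np.logaddexp(0.0, eta)

    def to_inference_data(self, include_log_likelihood: bool = False):
        kwargs = {"posterior": self.named_posterior()}
        if include_log_likelihood:
            kwargs["log_likelihood"] = {"n_dead": self.log_likelihood()}
        return az.from_dict(**kwargs)

    @property
    def diagnostics(self) -> pd.DataFrame:
        if self._diagnostics is None:
            self._diagnostics = convergence_report(self)["table"]
        return self._diagnostics

    def converged(self) -> bool:
        return bool((self.diagnostics["rhat"] < RHAT_THRESHOLD).all())


# ---------------------------------------------------------------------------
# estimator


class BinomialPhyloMetaRegression:
    """Binomial-Normal hierarchical meta-regression estimator.

    scikit-learn-style interface: configure with a :class:`ModelSpec`, call
    :meth:`fit` with a moderator/grouping DataFrame ``X`` and a two-column
    count array ``y = [n_dead, n_caught]``. After fitting, ``result_`` holds
    the :class:`FitResult` with posterior draws and diagnostics.
    """

    def __init__(self, spec: ModelSpec | None = None):
        self.spec = spec

    def get_params(self, deep=True):
        return {"spec": self.spec}

    def set_params(self, **params):
        for k, v in params.items():
            if k != "spec":
                raise ValueError(f"unknown parameter {k!r}")
            self.spec = v
        return self

    def fit(self, X: pd.DataFrame, y: np.ndarray):
        y = np.asarray(y)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must be (n, 2): columns [n_dead, n_caught]")
        if (y[:, 0] < 0).any() or (y[:, 0] > y[:, 1]).any() or (y[:, 1] < 1).any():
            raise ValueError("counts must satisfy 0 <= n_dead <= n_caught, n_caught >= 1")
        frame = X.copy().reset_index(drop=True)
        frame["n_dead"] = y[:, 0].astype(int)
        frame["n_caught"] = y[:, 1].astype(int)
        spec = self.spec if self.spec is not None else ModelSpec(
            group_terms=[GroupTerm("record", "__record__")]
        )
        self.result_ = _fit_frame(frame, spec)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior-mean AVM probability for new moderator rows (population
        level: group effects marginalized at zero)."""
        if not hasattr(self, "result_"):
            raise RuntimeError("call fit first")
        return expit(self.result_.fixed_eta(X)).mean(axis=(0, 1))


def _fit_frame(frame: pd.DataFrame, spec: ModelSpec) -> FitResult:
    if spec.has_phylo and frame["species"].nunique() < 2:
        raise ValueError("phylogenetic term requires >= 2 species")
    design = build_design(frame, spec)
    post = _Posterior(design, spec.priors)
    ss = spec.sampler
    seeds = np.random.SeedSequence(ss.seed).spawn(ss.chains)
    chains, step_sizes, n_div = [], [], 0
    for c in range(ss.chains):
        rng = np.random.default_rng(seeds[c])
        x0 = post.initial_point(rng)
        draws, st = sample_nuts(
            post.logp_and_grad, x0, ss.warmup, ss.draws, rng,
            target_accept=ss.target_accept, max_treedepth=ss.max_treedepth,
        )
        chains.append(draws)
        step_sizes.append(st.step_size)
        n_div += st.divergences
    theta = np.stack(chains)
    fit = FitResult(
        spec=spec, design=design, frame=frame, theta=theta,
        step_sizes=step_sizes, divergences=n_div,
    )
    report = convergence_report(fit)
    fit._diagnostics = report["table"]
    if not report["pass"]:
        worst = report["table"]["rhat"].max()
        fit.warning_flags.append(f"convergence: max Rhat {worst:.4f} >= {RHAT_THRESHOLD}")
        warnings.warn(fit.warning_flags[-1], stacklevel=2)
    if n_div:
        fit.warning_flags.append(f"{n_div} divergent transitions")
    return fit


def fit_model(ds: AVMDataset, spec: ModelSpec) -> FitResult:
    """Fit the hierarchical model to an effect-size dataset."""
    return _fit_frame(ds.frame.copy(), spec)


# ---------------------------------------------------------------------------
# diagnostics / comparison / checks


def convergence_report(fit: FitResult) -> dict:
    """Rank-normalized split-Rhat and bulk/tail ESS per monitored parameter."""
    if fit.n_chains < 2:
        raise ValueError("convergence diagnostics require >= 2 chains")
    post = fit.named_posterior()
    rows = []
    for name, arr in post.items():
        da = arr[None] if arr.ndim == 1 else arr
        rows.append(
            {
                "parameter": name,
                "rhat": float(az.rhat(az.convert_to_dataset(da)).x),
                "ess_bulk": float(az.ess(az.convert_to_dataset(da), method="bulk").x),
                "ess_tail": float(az.ess(az.convert_to_dataset(da), method="tail").x),
            }
        )
    table = pd.DataFrame(rows)
    return {
        "table": table,
        "pass": bool((table["rhat"] < RHAT_THRESHOLD).all()),
        "divergences": fit.divergences,
    }


def compare_models(fits: dict | list, names: list[str] | None = None) -> pd.DataFrame:
    """PSIS-LOO comparison with Bayesian stacking weights.

    Returns one row per model: elpd_loo, its SE, the elpd difference to the
    best model with SE, the stacking weight, and the worst Pareto k-hat.
    """
    if isinstance(fits, list):
        names = names or [f"model_{i}" for i in range(len(fits))]
        fits = dict(zip(names, fits))
    sizes = {name: f.design.n for name, f in fits.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"models were fit to different observation sets: {sizes}")
    idatas = {name: f.to_inference_data(include_log_likelihood=True) for name, f in fits.items()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if len(idatas) == 1:
            name, idata = next(iter(idatas.items()))
            loo = az.loo(idata)
            return pd.DataFrame(
                [{"model": name, "elpd_loo": loo.elpd_loo, "se": loo.se,
                  "elpd_diff": 0.0, "dse": 0.0, "stacking_weight": 1.0,
                  "pareto_k_max": float(np.max(loo.pareto_k))}]
            ).set_index("model")
        cmp = az.compare(idatas, ic="loo", method="stacking")
    out = cmp.rename(
        columns={"elpd_loo": "elpd_loo", "se": "se", "elpd_diff": "elpd_diff",
                 "dse": "dse", "weight": "stacking_weight"}
    )[["elpd_loo", "se", "elpd_diff", "dse", "stacking_weight"]]
    kmax = {}
    for name, idata in idatas.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kmax[name] = float(np.max(az.loo(idata).pareto_k))
    out["pareto_k_max"] = pd.Series(kmax)
    out.index.name = "model"
    return out


@dataclass
class PPCResult:
    observed_proportions: np.ndarray  # (n_records,)
    replicated_proportions: np.ndarray  # (n_rep, n_records)
    observed_species_totals: pd.Series
    replicated_species_totals: pd.DataFrame  # (n_rep, n_species)
    replicated_counts: np.ndarray  # (n_rep, n_records)

    def species_outside_band(self, mass: float = 0.95) -> list[str]:
        lo = self.replicated_species_totals.quantile((1 - mass) / 2)
        hi = self.replicated_species_totals.quantile(1 - (1 - mass) / 2)
        obs = self.observed_species_totals
        return sorted(obs.index[(obs < lo) | (obs > hi)])

    def plot(self, path=None):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for rep in self.replicated_proportions[: min(50, len(self.replicated_proportions))]:
            pd.Series(rep).plot.kde(ax=ax, color="steelblue", alpha=0.15, lw=0.8)
        pd.Series(self.observed_proportions).plot.kde(ax=ax, color="black", lw=2)
        ax.set_xlabel("record-level AVM proportion")
        ax.set_title("posterior predictive check")
        if path:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return fig


def posterior_predictive_check(
    fit: FitResult, ds: AVMDataset | None = None, n_rep: int = 200, seed: int = 0
) -> PPCResult:
    """Replicate datasets from the posterior predictive and compare summary
    statistics (record-level proportions, per-species death totals) with the
    observed data."""
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    frame = ds.frame if ds is not None else fit.frame
    if ds is not None and len(frame) != fit.design.n:
        raise ValueError("dataset does not match the fitted model")
    rng = np.random.default_rng(seed)
    eta = fit.linear_predictor(include_groups=True).reshape(-1, fit.design.n)
    pick = rng.choice(len(eta), size=n_rep, replace=len(eta) < n_rep)
    p = expit(eta[pick])
    trials = fit.design.trials.astype(int)
    reps = rng.binomial(trials[None, :], p)
    species = frame["species"].to_numpy()
    obs_tot = pd.Series(fit.design.y).groupby(species).sum()
    rep_tot = pd.DataFrame(reps).T.groupby(species).sum().T
    return PPCResult(
        observed_proportions=fit.design.y / fit.design.trials,
        replicated_proportions=reps / trials[None, :],
        observed_species_totals=obs_tot,
        replicated_species_totals=rep_tot,
        replicated_counts=reps,
    )
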
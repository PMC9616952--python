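"""Moderator screening and missing-moderator imputation.

Screening fits random forests to the logit-transformed AVM proportions with
random-effects meta-analytic case weights, resampling whole studies
(clustered bootstrap) and averaging permutation importance across
replicates; predictors below a cut-off (percent of the top predictor's
importance) are dropped before the Bayesian stage. Taxonomic predictors
(genus/family/order) may screen as informative but are represented in the
Bayesian models by the phylogenetic tree structure instead of fixed effects.

Imputation fills missing moderators by chained random forests with
predictive mean matching, so numeric imputations are always members of the
observed value set and observed cells are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .data import AVMDataset

__all__ = [
    "ImportanceTable",
    "ImputedDataset",
    "ModeratorScreener",
    "ChainedForestImputer",
    "screen_predictors",
    "impute_missing",
    "informative_moderators",
]

TAXONOMIC_PREDICTORS = ("genus", "family", "order")
DEFAULT_CANDIDATES = (
    "genus", "family", "order", "ocean", "hook_shape", "hook_type",
    "hooks_between_floats", "soak_duration", "bait_type", "body_form",
    "ventilation_mode",
)


def logit_effects(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Continuity-corrected logit proportions and delta-method variances:
    p~ = (x + 0.5) / (n + 1), v = 1/(x + 0.5) + 1/(n - x + 0.5)."""
    x = frame["n_dead"].to_numpy(float)
    n = frame["n_caught"].to_numpy(float)
    p = (x + 0.5) / (n + 1.0)
    y = np.log(p / (1 - p))
    v = 1.0 / (x + 0.5) + 1.0 / (n - x + 0.5)
    return y, v


def dersimonian_laird_tau2(y: np.ndarray, v: np.ndarray) -> float:
    """Method-of-moments between-study variance on the logit scale."""
    w = 1.0 / v
    ybar = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - ybar) ** 2))
    k = y.size
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    return max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0


@dataclass
class ImportanceTable:
    """Permutation importances on a percent-of-maximum scale."""

    table: pd.DataFrame  # columns: predictor, importance
    n_boot: int
    threshold: float = 10.0

    def selected(self, exclude_taxonomic: bool = False) -> list[str]:
        keep = self.table.loc[self.table["importance"] > self.threshold, "predictor"]
        if exclude_taxonomic:
            keep = keep[~keep.isin(TAXONOMIC_PREDICTORS)]
        return list(keep)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def plot(self, path=None):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        tab = self.table.sort_values("importance")
        fig, ax = plt.subplots(figsize=(6, 0.4 * len(tab) + 1.5))
        ax.barh(tab["predictor"], tab["importance"], color="steelblue")
        ax.axvline(self.threshold, color="firebrick", ls="--", lw=1)
        ax.set_xlabel("permutation importance (% of maximum)")
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return fig


def informative_moderators(
    table: ImportanceTable,
    always_include: tuple = (),
) -> list[str]:
    """Predictors passing the cut-off, with taxonomic predictors removed —
    the phylogenetic correlation structure represents them in the Bayesian
    models — plus any operationally interesting predictors forced in."""
    keep = table.selected(exclude_taxonomic=True)
    for extra in always_include:
        if extra not in keep:
            keep.append(extra)
    return keep


def _encode_features(frame: pd.DataFrame, candidates: list[str]) -> np.ndarray:
    """Ordinal-encode a candidate matrix (one column per predictor so that
    permutation importance is attributable per predictor)."""
    cols = []
    for c in candidates:
        s = frame[c]
        if pd.api.types.is_numeric_dtype(s):
            if s.isna().any():
                raise ValueError(f"candidate {c!r} has missing values; impute first")
            cols.append(s.to_numpy(float))
        else:
            cols.append(pd.factorize(s.astype(str), sort=True)[0].astype(float))
    return np.column_stack(cols)


class ModeratorScreener:
    """Random-effects-weighted random-forest moderator screen.

    Parameters follow common random-forest meta-screening practice:
    ``n_boot`` clustered bootstrap replicates, 500 trees, sqrt(p) features
    per split, minimum node size 5. ``fit`` expects a DataFrame with the
    candidate columns plus a study-identifier column, and ``y`` as the
    two-column count array ``[n_dead, n_caught]``. Fitted attributes:
    ``importances_`` (percent of maximum) and ``importance_table_``.
    """

    def __init__(
        self,
        candidates: tuple = DEFAULT_CANDIDATES,
        n_boot: int = 100,
        n_trees: int = 500,
        min_node_size: int = 5,
        threshold: float = 10.0,
        cluster_col: str = "study_id",
        seed: int = 0,
    ):
        self.candidates = candidates
        self.n_boot = n_boot
        self.n_trees = n_trees
        self.min_node_size = min_node_size
        self.threshold = threshold
        self.cluster_col = cluster_col
        self.seed = seed

    def get_params(self, deep=True):
        return {
            "candidates": self.candidates, "n_boot": self.n_boot,
            "n_trees": self.n_trees, "min_node_size": self.min_node_size,
            "threshold": self.threshold, "cluster_col": self.cluster_col,
            "seed": self.seed,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y: np.ndarray):
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        y = np.asarray(y)
        frame = X.copy().reset_index(drop=True)
        frame["n_dead"], frame["n_caught"] = y[:, 0], y[:, 1]
        resp, v = logit_effects(frame)
        if np.allclose(resp, resp[0]):
            raise ValueError("constant response; nothing to screen")
        clusters = frame[self.cluster_col].astype(str).to_numpy()
        uniq = np.unique(clusters)
        if uniq.size < 2:
            raise ValueError("clustered bootstrap requires >= 2 study clusters")
        tau2 = dersimonian_laird_tau2(resp, v)
        weights = 1.0 / (v + tau2)
        features = _encode_features(frame, list(self.candidates))
        cluster_rows = {c: np.flatnonzero(clusters == c) for c in uniq}

        rng = np.random.default_rng(self.seed)
        raw = np.zeros((self.n_boot, len(self.candidates)))
        for b in range(self.n_boot):
            picked = rng.choice(uniq, size=uniq.size, replace=True)
            rows = np.concatenate([cluster_rows[c] for c in picked])
            # importance is scored on the clusters left out of the bootstrap
            # replicate, suppressing the in-sample bias that favours
            # high-cardinality/continuous predictors
            held_out = [c for c in uniq if c not in set(picked)]
            oob = (
                np.concatenate([cluster_rows[c] for c in held_out])
                if held_out
                else rows
            )
            rf = RandomForestRegressor(
                n_estimators=self.n_trees,
                max_features="sqrt",
                min_samples_leaf=self.min_node_size,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(features[rows], resp[rows], sample_weight=weights[rows])
            Xo, yo, wo = features[oob], resp[oob], weights[oob]
            base = np.average((rf.predict(Xo) - yo) ** 2, weights=wo)
            for j in range(len(self.candidates)):
                Xp = Xo.copy()
                Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
                mse = np.average((rf.predict(Xp) - yo) ** 2, weights=wo)
                raw[b, j] = mse - base
        mean_imp = np.clip(raw.mean(axis=0), 0.0, None)
        top = mean_imp.max()
        self.importances_ = 100.0 * mean_imp / top if top > 0 else mean_imp
        self.tau2_ = tau2
        self.importance_table_ = ImportanceTable(
            pd.DataFrame(
                {"predictor": list(self.candidates), "importance": self.importances_}
            ).sort_values("importance", ascending=False, kind="stable").reset_index(drop=True),
            n_boot=self.n_boot,
            threshold=self.threshold,
        )
        return self


def screen_predictors(
    ds: AVMDataset,
    candidates: list[str] | None = None,
    n_boot: int = 100,
    seed: int = 0,
    n_trees: int = 500,
    threshold: float = 10.0,
) -> ImportanceTable:
    """Screen candidate moderators of the AVM rate; see
    :class:`ModeratorScreener`."""
    cands = tuple(candidates) if candidates is not None else DEFAULT_CANDIDATES
    scr = ModeratorScreener(
        candidates=cands, n_boot=n_boot, n_trees=n_trees, threshold=threshold, seed=seed
    )
    scr.fit(
        ds.frame.drop(columns=["n_dead", "n_caught"]),
        ds.frame[["n_dead", "n_caught"]].to_numpy(),
    )
    return scr.importance_table_


# ---------------------------------------------------------------------------
# imputation


@dataclass
class ImputedDataset:
    dataset: AVMDataset
    flags: pd.DataFrame  # boolean, True where a cell was imputed
    oob_trace: list = field(default_factory=list)

    @property
    def n_imputed(self) -> int:
        return int(self.flags.to_numpy().sum())


class ChainedForestImputer:
    """Chained random-forest imputation with predictive mean matching.

    Iterates over incomplete columns (in increasing-missingness order),
    fitting a random forest of each column on all other moderators and
    replacing missing numeric cells with the observed value of one of the
    ``pmm_donors`` nearest predicted neighbours; categorical cells take the
    forest's class vote. Iteration stops when the mean out-of-bag error stops
    improving or after ``max_iter`` sweeps.
    """

    def __init__(
        self,
        columns: tuple = ("hooks_between_floats", "soak_duration"),
        feature_columns: tuple = (
            "study_id", "ocean", "hook_shape", "hook_type", "bait_type",
            "body_form", "ventilation_mode", "species",
            "hooks_between_floats", "soak_duration",
        ),
        max_iter: int = 10,
        pmm_donors: int = 5,
        n_trees: int = 100,
        seed: int = 0,
    ):
        self.columns = columns
        self.feature_columns = feature_columns
        self.max_iter = max_iter
        self.pmm_donors = pmm_donors
        self.n_trees = n_trees
        self.seed = seed

    def get_params(self, deep=True):
        return {
            "columns": self.columns, "feature_columns": self.feature_columns,
            "max_iter": self.max_iter, "pmm_donors": self.pmm_donors,
            "n_trees": self.n_trees, "seed": self.seed,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        frame = X.copy().reset_index(drop=True)
        rng = np.random.default_rng(self.seed)
        targets = [c for c in self.columns if c in frame.columns]
        miss = {c: frame[c].isna().to_numpy() for c in targets}
        for c in targets:
            if miss[c].all():
                raise ValueError(f"column {c!r} is entirely missing; cannot impute")
            frac = miss[c].mean()
            if frac >= 0.5:
                raise ValueError(f"column {c!r} is {frac:.0%} missing (>= 50%)")
        self.missing_mask_ = pd.DataFrame(
            {c: miss.get(c, np.zeros(len(frame), bool)) for c in targets},
            index=frame.index,
        )
        incomplete = sorted(
            (c for c in targets if miss[c].any()), key=lambda c: miss[c].mean()
        )
        self.oob_trace_ = []
        if not incomplete:
            self.frame_ = frame
            return frame

        # initial fill: marginal draws from the observed values
        for c in incomplete:
            obs = frame.loc[~miss[c], c].to_numpy()
            frame.loc[miss[c], c] = rng.choice(obs, size=int(miss[c].sum()))

        feats = [f for f in self.feature_columns if f in frame.columns]
        best = np.inf
        for _ in range(self.max_iter):
            errors = []
            for c in incomplete:
                other = [f for f in feats if f != c]
                Xenc = _encode_features(frame, other)
                yobs = frame[c].to_numpy()
                numeric = pd.api.types.is_numeric_dtype(X[c])
                seed_i = int(rng.integers(2**31 - 1))
                obs_vals = yobs[~miss[c]]
                if len(pd.unique(obs_vals)) == 1:
                    frame.loc[miss[c], c] = obs_vals[0]
                    errors.append(0.0)
                    continue
                if numeric:
                    rf = RandomForestRegressor(
                        n_estimators=self.n_trees, min_samples_leaf=5,
                        oob_score=True, bootstrap=True, random_state=seed_i, n_jobs=1,
                    )
                    rf.fit(Xenc[~miss[c]], yobs[~miss[c]].astype(float))
                    errors.append(max(0.0, 1.0 - rf.oob_score_))
                    pred_miss = rf.predict(Xenc[miss[c]])
                    pred_obs = rf.predict(Xenc[~miss[c]])
                    donors_vals = yobs[~miss[c]].astype(float)
                    fill = np.empty(len(pred_miss))
                    for i, pm in enumerate(pred_miss):
                        order = np.argsort(np.abs(pred_obs - pm), kind="stable")
                        pick = order[: self.pmm_donors]
                        fill[i] = donors_vals[pick[rng.integers(0, len(pick))]]
                    frame.loc[miss[c], c] = fill
                else:
                    rf = RandomForestClassifier(
                        n_estimators=self.n_trees, min_samples_leaf=5,
                        oob_score=True, bootstrap=True, random_state=seed_i, n_jobs=1,
                    )
                    rf.fit(Xenc[~miss[c]], yobs[~miss[c]].astype(str))
                    errors.append(max(0.0, 1.0 - rf.oob_score_))
                    frame.loc[miss[c], c] = rf.predict(Xenc[miss[c]])
            current = float(np.mean(errors))
            self.oob_trace_.append(current)
            if current >= best - 1e-6:
                break
            best = current
        # observed cells are untouched by construction; assert the contract
        for c in targets:
            obs_mask = ~miss[c]
            assert frame.loc[obs_mask, c].equals(X.reset_index(drop=True).loc[obs_mask, c])
        self.frame_ = frame
        return frame


def impute_missing(
    ds: AVMDataset,
    max_iter: int = 10,
    pmm_donors: int = 5,
    seed: int = 0,
    n_trees: int = 100,
) -> ImputedDataset:
    """Impute missing moderators of an effect-size dataset; see
    :class:`ChainedForestImputer`."""
    imp = ChainedForestImputer(
        max_iter=max_iter, pmm_donors=pmm_donors, seed=seed, n_trees=n_trees
    )
    frame = imp.fit_transform(ds.frame)
    return ImputedDataset(
        dataset=AVMDataset(frame, provenance=f"{ds.provenance} | imputed"),
        flags=imp.missing_mask_,
        oob_trace=imp.oob_trace_,
    )
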
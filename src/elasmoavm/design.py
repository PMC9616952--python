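"""Design matrices for the binomial-Normal hierarchical meta-regression.

Builds the fixed-effect matrix (treatment contrasts, alphabetically first
level as reference), penalized-spline bases in their mixed-model
(random-effect) representation, and the group-level index structures
(phylogenetic species effect, study, record-within-study, research group).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .phylo import CHOLESKY_JITTER, CorrMatrix


@dataclass
class GroupTerm:
    """One group-level (random) effect.

    ``column`` names the grouping column; the reserved value ``"__record__"``
    gives one level per row (the record-within-study effect). ``corr``
    correlates the levels (Brownian matrix for the phylogenetic term);
    ``None`` means iid Normal levels.
    """

    label: str
    column: str
    corr: CorrMatrix | None = None


@dataclass
class SplineTerm:
    """Penalized cubic B-spline smooth of a continuous covariate."""

    column: str
    k: int = 10  # basis dimension before penalty-null-space removal


@dataclass
class PriorSettings:
    """Weakly informative defaults on the logit scale.

    ``intercept="student_t"`` is Student-t(3, 0, 2.5); ``"flat_response"``
    puts a uniform prior on the response-scale probability (logistic density
    on the intercept), useful for conjugate cross-checks.
    """

    intercept: str = "student_t"
    intercept_scale: float = 2.5
    coef_scale: float = 2.0
    sd_scale: float = 2.5
    sd_df: float = 3.0


@dataclass
class SamplerSettings:
    chains: int = 4
    draws: int = 10_000
    warmup: int = 2_000
    seed: int = 0
    target_accept: float = 0.95
    max_treedepth: int = 10


#: reduced profile for continuous-integration scale runs
CI_SAMPLER = SamplerSettings(chains=4, draws=500, warmup=500)


@dataclass
class ModelSpec:
    """Declarative description of one binomial-Normal GAMM."""

    fixed_effects: list[str] = field(default_factory=list)
    spline_terms: list[SplineTerm] = field(default_factory=list)
    group_terms: list[GroupTerm] = field(default_factory=list)
    priors: PriorSettings = field(default_factory=PriorSettings)
    sampler: SamplerSettings = field(default_factory=SamplerSettings)

    def __post_init__(self):
        if self.sampler.chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        labels = [g.label for g in self.group_terms]
        if len(set(labels)) != len(labels):
            raise ValueError("group term labels must be unique")

    @property
    def has_phylo(self) -> bool:
        return any(g.corr is not None for g in self.group_terms)

    def n_parameters(self, frame: pd.DataFrame) -> int:
        return build_design(frame, self).dim

    def to_dict(self) -> dict:
        return {
            "fixed_effects": list(self.fixed_effects),
            "spline_terms": [{"column": s.column, "k": s.k} for s in self.spline_terms],
            "group_terms": [
                {
                    "label": g.label,
                    "column": g.column,
                    "corr": None
                    if g.corr is None
                    else {"species": g.corr.species, "values": g.corr.values.tolist()},
                }
                for g in self.group_terms
            ],
            "priors": vars(self.priors).copy(),
            "sampler": vars(self.sampler).copy(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        groups = []
        for g in d.get("group_terms", []):
            corr = g.get("corr")
            groups.append(
                GroupTerm(
                    g["label"],
                    g["column"],
                    None
                    if corr is None
                    else CorrMatrix(np.asarray(corr["values"]), list(corr["species"])),
                )
            )
        return cls(
            fixed_effects=list(d.get("fixed_effects", [])),
            spline_terms=[SplineTerm(**s) for s in d.get("spline_terms", [])],
            group_terms=groups,
            priors=PriorSettings(**d.get("priors", {})),
            sampler=SamplerSettings(**d.get("sampler", {})),
        )


def canonical_spec(
    corr: CorrMatrix | None,
    fixed_effects: list[str] | None = None,
    spline_columns: list[str] = ("hooks_between_floats",),
    sampler: SamplerSettings | None = None,
) -> ModelSpec:
    """The clade-analysis model: ocean and hook-shape fixed effects with their
    interaction, a smooth of hooks-between-floats, and the four canonical
    group terms (phylogenetic species, study, record-within-study, research
    group)."""
    groups = [GroupTerm("study", "study_id"), GroupTerm("record", "__record__"),
              GroupTerm("research_group", "research_group_id")]
    if corr is not None:
        groups.insert(0, GroupTerm("phylo", "species", corr))
    return ModelSpec(
        fixed_effects=list(
            fixed_effects if fixed_effects is not None
            else ["ocean", "hook_shape", "ocean:hook_shape"]
        ),
        spline_terms=[SplineTerm(c) for c in spline_columns],
        group_terms=groups,
        sampler=sampler or SamplerSettings(),
    )


# ---------------------------------------------------------------------------
# encoders


@dataclass
class _CategoricalEncoder:
    column: str
    levels: list[str]

    def dummies(self, frame: pd.DataFrame) -> np.ndarray:
        """Indicator columns for the non-reference levels (n, len(levels)-1)."""
        vals = frame[self.column].astype(str).to_numpy()
        return np.column_stack(
            [(vals == lv).astype(float) for lv in self.levels[1:]]
        ) if len(self.levels) > 1 else np.empty((len(frame), 0))

    @property
    def names(self) -> list[str]:
        return [f"{self.column}[{lv}]" for lv in self.levels[1:]]


@dataclass
class _SplineEncoder:
    column: str
    center: float
    scale: float
    knots: np.ndarray
    transform: np.ndarray  # maps raw basis -> penalized random columns

    def _basis(self, x: np.ndarray) -> np.ndarray:
        z = (x - self.center) / self.scale
        z = np.clip(z, self.knots[3], self.knots[-4])  # clamp to boundary knots
        dm = BSpline.design_matrix(z, self.knots, 3).toarray()
        return dm

    def linear(self, frame: pd.DataFrame) -> np.ndarray:
        x = frame[self.column].to_numpy(dtype=float)
        return (x - self.center) / self.scale

    def random(self, frame: pd.DataFrame) -> np.ndarray:
        x = frame[self.column].to_numpy(dtype=float)
        b = self._basis(x) @ self.transform
        return b - self._col_center

    def finalize(self, frame: pd.DataFrame) -> None:
        x = frame[self.column].to_numpy(dtype=float)
        self._col_center = (self._basis(x) @ self.transform).mean(axis=0)


def _make_spline_encoder(frame: pd.DataFrame, term: SplineTerm) -> _SplineEncoder | None:
    x = frame[term.column].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError(
            f"spline covariate {term.column!r} has missing values; impute first"
        )
    uniq = np.unique(x)
    if uniq.size < 5:
        return None  # too few distinct values to smooth; linear term only
    center, scale = float(x.mean()), float(x.std() or 1.0)
    z = (x - center) / scale
    k = int(min(term.k, uniq.size - 1))
    # cubic B-spline: k basis functions need k+4 knots
    lo, hi = z.min(), z.max()
    # equally spaced interior knots: robust for discrete covariates such as
    # hooks-between-floats where quantile knots would coincide
    inner = np.linspace(lo, hi, k - 2)
    knots = np.concatenate([[lo] * 3, inner, [hi] * 3])
    b = BSpline.design_matrix(z, knots, 3).toarray()
    nb = b.shape[1]
    d2 = np.diff(np.eye(nb), n=2, axis=0)
    s = d2.T @ d2
    w, v = np.linalg.eigh(s)
    keep = w > 1e-8 * w.max()
    transform = v[:, keep] / np.sqrt(w[keep])
    enc = _SplineEncoder(term.column, center, scale, knots, transform)
    enc._col_center = np.zeros(transform.shape[1])
    enc.finalize(frame)
    return enc


@dataclass
class GroupInfo:
    label: str
    column: str
    levels: list[str]
    index: np.ndarray  # (n,) level index per record
    chol: np.ndarray | None  # Cholesky of corr (+jitter), None for iid


@dataclass
class Design:
    """Frozen design metadata: everything needed to map parameters to the
    linear predictor, for the fit data and for new reference grids."""

    n: int
    y: np.ndarray
    trials: np.ndarray
    cat_encoders: list
    interactions: list  # (colA, colB) pairs
    spline_encoders: list
    spline_lin_only: list  # spline columns reduced to a linear term
    groups: list
    coef_names: list
    X: np.ndarray
    spline_bases: list  # aligned with spline_encoders: (n, K_r) arrays
    slices: dict
    dim: int

    def fixed_matrix(self, frame: pd.DataFrame) -> np.ndarray:
        """Rebuild the fixed-effect matrix for (possibly counterfactual) data."""
        cols = []
        enc_by_col = {e.column: e for e in self.cat_encoders}
        for e in self.cat_encoders:
            cols.append(e.dummies(frame))
        for a, b in self.interactions:
            da, db = enc_by_col[a].dummies(frame), enc_by_col[b].dummies(frame)
            cols.append(
                np.column_stack(
                    [da[:, i] * db[:, j] for i in range(da.shape[1]) for j in range(db.shape[1])]
                )
                if da.shape[1] and db.shape[1]
                else np.empty((len(frame), 0))
            )
        for e in self.spline_encoders:
            cols.append(e.linear(frame)[:, None])
        for col, (center, scale) in self.spline_lin_only:
            x = frame[col].to_numpy(dtype=float)
            cols.append(((x - center) / scale)[:, None])
        if not cols:
            return np.empty((len(frame), 0))
        return np.column_stack(cols)

    def spline_random(self, frame: pd.DataFrame) -> list:
        return [e.random(frame) for e in self.spline_encoders]


def build_design(frame: pd.DataFrame, spec: ModelSpec) -> Design:
    n = len(frame)
    y = frame["n_dead"].to_numpy(dtype=float)
    trials = frame["n_caught"].to_numpy(dtype=float)

    cat_cols: list[str] = []
    interactions: list[tuple[str, str]] = []
    for term in spec.fixed_effects:
        if ":" in term:
            a, b = term.split(":")
            interactions.append((a, b))
            for c in (a, b):
                if c not in cat_cols:
                    cat_cols.append(c)
        elif term not in cat_cols:
            cat_cols.append(term)
    cat_encoders = [
        _CategoricalEncoder(c, sorted(frame[c].astype(str).unique())) for c in cat_cols
    ]
    enc_by_col = {e.column: e for e in cat_encoders}

    coef_names: list[str] = []
    for e in cat_encoders:
        coef_names.extend(e.names)
    for a, b in interactions:
        for na in enc_by_col[a].names:
            for nb in enc_by_col[b].names:
                coef_names.append(f"{na}:{nb}")

    spline_encoders, spline_lin_only = [], []
    for term in spec.spline_terms:
        enc = _make_spline_encoder(frame, term)
        if enc is None:
            x = frame[term.column].to_numpy(dtype=float)
            spline_lin_only.append((term.column, (float(x.mean()), float(x.std() or 1.0))))
        else:
            spline_encoders.append(enc)
    # linear columns appear in fixed_matrix order: encoder splines, then
    # linear-only covariates
    coef_names.extend(f"{e.column}_linear" for e in spline_encoders)
    coef_names.extend(f"{col}_linear" for col, _ in spline_lin_only)

    groups: list[GroupInfo] = []
    for g in spec.group_terms:
        if g.column == "__record__":
            levels = [str(i) for i in range(n)]
            index = np.arange(n)
        else:
            vals = frame[g.column].astype(str).to_numpy()
            levels = sorted(set(vals))
            lookup = {lv: i for i, lv in enumerate(levels)}
            index = np.array([lookup[v] for v in vals])
        chol = None
        if g.corr is not None:
            missing = [lv for lv in levels if lv not in g.corr.species]
            if missing:
                raise ValueError(
                    f"group term {g.label!r}: levels absent from correlation matrix: {missing}"
                )
            chol = g.corr.reorder(levels).cholesky(CHOLESKY_JITTER)
        groups.append(GroupInfo(g.label, g.column, levels, index, chol))

    design = Design(
        n=n, y=y, trials=trials,
        cat_encoders=cat_encoders, interactions=interactions,
        spline_encoders=spline_encoders, spline_lin_only=spline_lin_only,
        groups=groups, coef_names=coef_names,
        X=np.empty((n, 0)), spline_bases=[], slices={}, dim=0,
    )
    design.X = design.fixed_matrix(frame)
    design.spline_bases = design.spline_random(frame)

    # parameter layout
    pos = 0
    slices = {"intercept": slice(0, 1)}
    pos = 1
    p = design.X.shape[1]
    slices["beta"] = slice(pos, pos + p)
    pos += p
    for i, b in enumerate(design.spline_bases):
        slices[f"z_spline_{design.spline_encoders[i].column}"] = slice(pos, pos + b.shape[1])
        pos += b.shape[1]
    for g in design.groups:
        slices[f"z_{g.label}"] = slice(pos, pos + len(g.levels))
        pos += len(g.levels)
    for e in design.spline_encoders:
        slices[f"log_sigma_spline_{e.column}"] = slice(pos, pos + 1)
        pos += 1
    for g in design.groups:
        slices[f"log_sigma_{g.label}"] = slice(pos, pos + 1)
        pos += 1
    design.slices = slices
    design.dim = pos
    return design
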
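"""Synthetic trees and effect-size datasets with known generating truth.

The generator mirrors the statistical structure the meta-regression assumes:
species-level effects correlated under Brownian motion on a phylogeny,
iid study / record-within-study / research-group effects, categorical and
continuous moderators with controllable effect sizes, overdispersed
per-record catch sizes, binomial death counts, and missing-completely-at-
random masking of two gear moderators. The default scenario is sized like a
single-clade analysis: 13 species on a Yule tree, ~35 studies and ~460
records spread over two ocean basins.
"""

from __future__ import annotations

import json
import random as _pyrandom
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data import AVMDataset
from .phylo import PhyloTree, brownian_correlation, parse_tree_string

__all__ = ["TruthConfig", "SyntheticTruth", "simulate_tree", "simulate_dataset",
           "simulate_funnel_records"]


def _species_labels(n: int) -> list[str]:
    return [f"Species_{i:02d}" for i in range(n)]


def simulate_tree(n_species: int, model: str = "yule", seed: int = 0) -> PhyloTree:
    """Simulate a rooted ultrametric tree with unit root-to-tip depth.

    ``model="yule"`` is a pure-birth tree; ``model="star"`` attaches every
    tip directly to the root (no shared history, identity correlation).
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    labels = _species_labels(n_species)
    if model == "star":
        newick = "(" + ",".join(f"{lb}:1" for lb in labels) + ");"
        return parse_tree_string(newick)
    if model != "yule":
        raise ValueError("model must be 'yule' or 'star'")
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=_pyrandom.Random(seed),
    )
    # deterministic relabelling in leaf-iteration order
    for label, leaf in zip(labels, tree.leaf_node_iter()):
        leaf.taxon.label = label
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depth = max(float(lf.root_distance) for lf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    return PhyloTree(tree)


@dataclass
class TruthConfig:
    """Generating parameters; defaults are the package's study conditions."""

    n_species: int = 13
    n_studies: int = 35
    records_per_study: tuple = (8, 18)
    n_research_groups: int = 8
    intercept: float = float(logit(0.35))
    #: fixed-effect coefficients on the logit scale, keyed "column[level]"
    beta: dict = field(default_factory=lambda: {"ocean[Pacific]": 1.0})
    sigma_phylo: float = 0.8
    sigma_study: float = 0.5
    sigma_record: float = 0.3
    sigma_research_group: float = 0.3
    #: amplitude of the sinusoidal smooth of hooks-between-floats (logit scale)
    smooth_amplitude: float = 0.3
    hooks_range: tuple = (15, 35)
    catch_mean: float = 30.0
    catch_dispersion: float = 2.0
    ocean_probs: dict = field(default_factory=lambda: {"Atlantic": 0.6, "Pacific": 0.4})
    hook_shape_probs: dict = field(
        default_factory=lambda: {"circle": 0.45, "J": 0.45, "unknown": 0.10}
    )
    bait_probs: dict = field(
        default_factory=lambda: {"squid": 0.40, "fish": 0.40, "mixed": 0.15, "unknown": 0.05}
    )
    soak_lognormal: tuple = (2.3, 0.3)  # ~10 h median soak
    miss_hooks_between_floats: float = 0.04
    miss_soak_duration: float = 0.14
    order_name: str = "Testiformes"
    tree_model: str = "yule"

    @property
    def true_lambda(self) -> float:
        tot = (
            self.sigma_phylo**2 + self.sigma_study**2
            + self.sigma_record**2 + self.sigma_research_group**2
        )
        return self.sigma_phylo**2 / tot if tot > 0 else 0.0


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset, for recovery tests."""

    config: TruthConfig
    seed: int
    tree_newick: str
    species: list
    species_effects: dict
    study_effects: dict
    research_group_effects: dict
    record_effects: list
    true_p: list
    smooth_values: dict  # hooks value -> logit-scale smooth contribution
    masked_hooks_records: list
    masked_soak_records: list

    @property
    def true_lambda(self) -> float:
        return self.config.true_lambda

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def _smooth(hooks: np.ndarray, cfg: TruthConfig) -> np.ndarray:
    lo, hi = cfg.hooks_range
    span = max(hi - lo, 1)
    return cfg.smooth_amplitude * np.sin(2 * np.pi * (hooks - lo) / span)


def _draw_categorical(rng, probs: dict, size: int) -> np.ndarray:
    levels = list(probs)
    p = np.array([probs[l] for l in levels], dtype=float)
    return rng.choice(levels, size=size, p=p / p.sum())


def simulate_dataset(
    config: TruthConfig | None = None,
    seed: int = 0,
    tree: PhyloTree | None = None,
    **overrides,
) -> tuple[AVMDataset, SyntheticTruth]:
    """Simulate an effect-size dataset with known truth.

    Returns the dataset (same CSV dialect the loader reads, with MCAR-masked
    moderator cells as missing values) and the :class:`SyntheticTruth`.
    """
    cfg = config or TruthConfig(**overrides)
    if overrides and config is not None:
        cfg = TruthConfig(**{**asdict(config), **overrides})
    rng = np.random.default_rng(seed)

    if tree is None:
        tree = simulate_tree(cfg.n_species, model=cfg.tree_model, seed=seed)
    species = sorted(tree.tip_labels)
    if len(species) != cfg.n_species:
        raise ValueError("tree tip count does not match n_species")
    corr = brownian_correlation(tree, species)
    chol = corr.cholesky()
    u_species = cfg.sigma_phylo * (chol @ rng.standard_normal(cfg.n_species))

    u_study = cfg.sigma_study * rng.standard_normal(cfg.n_studies)
    u_group = cfg.sigma_research_group * rng.standard_normal(cfg.n_research_groups)
    study_group = rng.integers(0, cfg.n_research_groups, size=cfg.n_studies)

    lo_r, hi_r = cfg.records_per_study
    n_per_study = rng.integers(lo_r, hi_r + 1, size=cfg.n_studies)
    # gear configuration is a fishery/study attribute: hooks-between-floats
    # and soak duration cluster within studies, as in compiled longline data
    lo_h, hi_h = cfg.hooks_range
    study_hooks_center = rng.uniform(lo_h, hi_h, size=cfg.n_studies)
    study_soak_mu = rng.normal(cfg.soak_lognormal[0], 0.25, size=cfg.n_studies)
    rows = []
    rec_effects, true_p = [], []
    rid = 0
    for st in range(cfg.n_studies):
        for _ in range(int(n_per_study[st])):
            sp = int(rng.integers(0, cfg.n_species))
            ocean = str(_draw_categorical(rng, cfg.ocean_probs, 1)[0])
            hook_shape = str(_draw_categorical(rng, cfg.hook_shape_probs, 1)[0])
            bait = str(_draw_categorical(rng, cfg.bait_probs, 1)[0])
            hooks = int(np.clip(round(rng.normal(study_hooks_center[st], 2.5)), lo_h, hi_h))
            soak = float(rng.lognormal(study_soak_mu[st], cfg.soak_lognormal[1]))
            u_rec = cfg.sigma_record * rng.standard_normal()
            eta = cfg.intercept + u_species[sp] + u_study[st] + u_group[study_group[st]] + u_rec
            eta += float(_smooth(np.array([hooks]), cfg)[0])
            for key, val in cfg.beta.items():
                col, level = key[:-1].split("[")
                value = {"ocean": ocean, "hook_shape": hook_shape, "bait_type": bait}.get(col)
                if value is None:
                    raise ValueError(f"unsupported coefficient column in {key!r}")
                if value == level:
                    eta += val
            p = float(np.clip(expit(eta), 1e-9, 1 - 1e-9))
            n_caught = 1 + int(
                rng.negative_binomial(
                    cfg.catch_dispersion,
                    cfg.catch_dispersion / (cfg.catch_dispersion + cfg.catch_mean - 1),
                )
            )
            n_dead = int(rng.binomial(n_caught, p))
            rows.append(
                dict(
                    record_id=f"rec{rid:04d}",
                    study_id=f"study{st:02d}",
                    research_group_id=f"group{study_group[st]:02d}",
                    species=species[sp],
                    genus=f"Genus_{sp:02d}",
                    family=f"Family_{sp // 3:02d}",
                    order=cfg.order_name,
                    n_caught=n_caught,
                    n_dead=n_dead,
                    ocean=ocean,
                    hook_shape=hook_shape,
                    hook_type="unknown",
                    hooks_between_floats=float(hooks),
                    soak_duration=soak,
                    bait_type=bait,
                    body_form="fusiform" if sp % 2 == 0 else "dorsoventrally_flattened",
                    ventilation_mode="ram_obligate" if sp % 3 else "buccal_facultative",
                )
            )
            rec_effects.append(float(u_rec))
            true_p.append(p)
            rid += 1

    frame = pd.DataFrame(rows)
    mask_h = rng.random(len(frame)) < cfg.miss_hooks_between_floats
    mask_s = rng.random(len(frame)) < cfg.miss_soak_duration
    frame.loc[mask_h, "hooks_between_floats"] = np.nan
    frame.loc[mask_s, "soak_duration"] = np.nan

    ds = AVMDataset(frame, provenance=f"synthetic seed={seed}")
    hooks_grid = np.arange(cfg.hooks_range[0], cfg.hooks_range[1] + 1)
    truth = SyntheticTruth(
        config=cfg,
        seed=seed,
        tree_newick=tree.as_newick(),
        species=species,
        species_effects={s: float(u) for s, u in zip(species, u_species)},
        study_effects={f"study{i:02d}": float(u) for i, u in enumerate(u_study)},
        research_group_effects={f"group{i:02d}": float(u) for i, u in enumerate(u_group)},
        record_effects=rec_effects,
        true_p=true_p,
        smooth_values={int(h): float(v) for h, v in zip(hooks_grid, _smooth(hooks_grid, cfg))},
        masked_hooks_records=frame.loc[mask_h, "record_id"].tolist(),
        masked_soak_records=frame.loc[mask_s, "record_id"].tolist(),
    )
    return ds, truth


def simulate_funnel_records(
    n_records: int = 60,
    theta: float = -0.5,
    tau: float = 0.3,
    mean_n: float = 25.0,
    dispersion: float = 1.0,
    seed: int = 0,
    suppress: bool = False,
    suppress_z: float = 0.0,
    n_studies: int | None = None,
) -> AVMDataset:
    """Simulate single-species records for funnel-plot calibration.

    True logit rates are Normal(theta, tau^2); catch sizes are overdispersed
    negative binomial. With ``suppress=True``, small-catch records
    (``n_caught`` below the mean catch) whose continuity-corrected logit
    effect falls more than ``suppress_z`` standard errors below ``theta``
    are censored — the small-study low-mortality suppression pattern a
    contour-enhanced funnel plot is designed to reveal.
    """
    rng = np.random.default_rng(seed)
    n_studies = n_studies or max(6, n_records // 3)
    rows = []
    rid = 0
    while len(rows) < n_records:
        n = 2 + int(rng.negative_binomial(dispersion, dispersion / (dispersion + mean_n - 2)))
        p = float(expit(rng.normal(theta, tau)))
        x = int(rng.binomial(n, p))
        if suppress and n < mean_n:
            eff = np.log((x + 0.5) / (n - x + 0.5))
            se = np.sqrt(1 / (x + 0.5) + 1 / (n - x + 0.5))
            if eff < theta - suppress_z * se:
                continue
        st = rng.integers(0, n_studies)
        rows.append(
            dict(
                record_id=f"rec{rid:04d}", study_id=f"study{st:02d}",
                research_group_id=f"group{st % 5:02d}",
                species="Species_00", genus="Genus_00", family="Family_00",
                order="Testiformes", n_caught=n, n_dead=x,
                ocean="Atlantic", hook_shape="unknown", hook_type="unknown",
                hooks_between_floats=np.nan, soak_duration=np.nan,
                bait_type="unknown", body_form="unknown", ventilation_mode="unknown",
            )
        )
        rid += 1
    return AVMDataset(pd.DataFrame(rows), provenance=f"synthetic funnel seed={seed}")
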
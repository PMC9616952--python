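"""End-to-end orchestration: screen -> impute -> fit -> summarize -> diagnose.

A single :class:`RunConfig` drives the whole analysis; every run writes its
tables, plots and a JSON report plus a manifest (config hash, derived seeds,
package versions) sufficient to rerun the result exactly. All randomness
flows from one root seed split per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .data import read_dataset, subset_clade, write_dataset
from .design import SamplerSettings, canonical_spec
from .inference import (
    marginal_means,
    phylo_signal,
    pooled_avm,
    ratio_contrast,
    species_avm,
    summaries_to_frame,
)
from .model import fit_model, posterior_predictive_check
from .phylo import brownian_correlation, parse_tree, parse_tree_string
from .pubbias import funnel_analysis, funnel_plot
from .screening import impute_missing, informative_moderators, screen_predictors
from .sparse import sparse_species_table
from .synthetic import TruthConfig, simulate_dataset

logger = logging.getLogger("elasmoavm")

PROFILES = {
    "paper": SamplerSettings(chains=4, draws=10_000, warmup=2_000),
    "ci": SamplerSettings(chains=2, draws=400, warmup=400, target_accept=0.9),
}


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    outdir: str = "elasmoavm_run"
    seed: int = 0
    profile: str = "ci"
    # input data: either a CSV+tree, or a synthetic scenario
    dataset: str | None = None
    tree: str | None = None
    tree_schema: str = "newick"
    tree_index: int = 0
    synthetic: bool = True
    synthetic_config: dict = field(default_factory=dict)
    # selection
    clade: str | None = None
    oceans_keep: tuple = ("Atlantic", "Pacific")
    # modelling
    fixed_effects: list | None = None
    spline_columns: tuple = ("hooks_between_floats",)
    screen: bool = True
    n_boot: int = 50
    n_trees: int = 200
    ratio_term: str = "ocean"
    ratio_levels: tuple = ("Atlantic", "Pacific")
    sparse_threshold: int = 5

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        return cls(**payload)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


def _stage_seeds(seed: int) -> dict:
    names = ("simulate", "screen", "impute", "fit", "ppc", "tree")
    ss = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(s.generate_state(1)[0] % (2**31 - 1)) for n, s in zip(names, ss)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the JSON-serializable run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report: dict = {"config_hash": config.config_hash(), "seeds": seeds}

    # ---- data ------------------------------------------------------------
    truth = None
    if config.dataset is not None:
        try:
            ds = read_dataset(config.dataset)
        except Exception as exc:
            raise PipelineError("load", str(exc)) from exc
        tree = None
        if config.tree is not None:
            tree = parse_tree(config.tree, schema=config.tree_schema, tree_index=config.tree_index)
    elif config.synthetic:
        cfg = TruthConfig(**config.synthetic_config)
        ds, truth = simulate_dataset(cfg, seed=seeds["simulate"])
        tree = parse_tree_string(truth.tree_newick)
        write_dataset(ds, outdir / "synthetic_dataset.csv")
        truth.to_json(outdir / "synthetic_truth.json")
    else:
        raise PipelineError("load", "config names no dataset and synthetic=False")
    report["load"] = ds.load_report()

    if config.clade is not None:
        try:
            ds = subset_clade(ds, config.clade, config.oceans_keep)
        except Exception as exc:
            raise PipelineError("subset", str(exc)) from exc
        report["subset"] = ds.load_report()

    # ---- sparse species routed out of the regression ----------------------
    sparse_tab = sparse_species_table(ds, threshold=config.sparse_threshold)
    sparse_tab.to_csv(outdir / "sparse_species.csv", index=False)
    report["sparse_species"] = sparse_tab.to_dict(orient="records")

    # ---- imputation (before screening, as in the modelling workflow) ------
    needs_imputation = ds.frame[["hooks_between_floats", "soak_duration"]].isna().any().any()
    if needs_imputation:
        try:
            imputed = impute_missing(ds, seed=seeds["impute"], n_trees=config.n_trees)
        except Exception as exc:
            raise PipelineError("impute", str(exc)) from exc
        ds = imputed.dataset
        report["imputation"] = {
            "n_imputed": imputed.n_imputed,
            "oob_trace": imputed.oob_trace,
        }
    else:
        report["imputation"] = {"n_imputed": 0, "skipped": True}

    # ---- screening ---------------------------------------------------------
    fixed_effects = config.fixed_effects
    if config.screen:
        try:
            table = screen_predictors(
                ds, n_boot=config.n_boot, n_trees=config.n_trees, seed=seeds["screen"]
            )
        except Exception as exc:
            raise PipelineError("screen", str(exc)) from exc
        table.to_csv(outdir / "importance.csv")
        table.plot(outdir / "importance.png")
        report["screening"] = table.table.to_dict(orient="records")
        if fixed_effects is None:
            chosen = informative_moderators(table)
            fixed_effects = [c for c in chosen if c not in ("hooks_between_floats", "soak_duration")]
            if not fixed_effects:
                fixed_effects = ["ocean"]
        report["fixed_effects"] = fixed_effects
    elif fixed_effects is None:
        fixed_effects = ["ocean"]
        report["fixed_effects"] = fixed_effects

    # ---- phylogenetic structure -------------------------------------------
    species = sorted(ds.frame["species"].unique())
    corr = None
    if tree is not None and len(species) >= 2:
        try:
            corr = brownian_correlation(tree, species)
        except Exception as exc:
            raise PipelineError("phylo", str(exc)) from exc
        corr.to_csv(outdir / "correlation_matrix.csv")

    # ---- fit ----------------------------------------------------------------
    sampler = PROFILES[config.profile]
    sampler = SamplerSettings(**{**vars(sampler), "seed": seeds["fit"]})
    spec = canonical_spec(
        corr, fixed_effects=fixed_effects,
        spline_columns=[c for c in config.spline_columns if ds.frame[c].notna().all()],
        sampler=sampler,
    )
    try:
        fit = fit_model(ds, spec)
    except Exception as exc:
        raise PipelineError("fit", str(exc)) from exc
    fit.diagnostics.to_csv(outdir / "diagnostics.csv", index=False)
    report["convergence"] = {
        "pass": fit.converged(),
        "max_rhat": float(fit.diagnostics["rhat"].max()),
        "divergences": fit.divergences,
        "warnings": fit.warning_flags,
    }

    # ---- summaries ----------------------------------------------------------
    pooled = pooled_avm(fit)
    report["pooled_avm"] = pooled.to_dict()
    if corr is not None:
        sig = phylo_signal(fit)
        report["phylo_signal"] = sig.summary().to_dict()
        sp_tab = summaries_to_frame(species_avm(fit))
        sp_tab.to_csv(outdir / "species_avm.csv", index=False)
        report["species_avm"] = sp_tab.to_dict(orient="records")
    mm_tab = summaries_to_frame(marginal_means(fit, by=config.ratio_term))
    mm_tab.to_csv(outdir / "marginal_means.csv", index=False)
    report["marginal_means"] = mm_tab.to_dict(orient="records")
    la, lb = config.ratio_levels
    levels = set(ds.frame[config.ratio_term].astype(str))
    if {la, lb} <= levels:
        report["risk_ratio"] = ratio_contrast(fit, config.ratio_term, la, lb).to_dict()

    ppc = posterior_predictive_check(fit, n_rep=100, seed=seeds["ppc"])
    ppc.plot(outdir / "ppc.png")
    report["ppc_species_outside_95"] = ppc.species_outside_band()

    # ---- publication bias ---------------------------------------------------
    try:
        funnel = funnel_analysis(ds)
        funnel_plot(funnel, outdir / "funnel.png")
        report["publication_bias"] = funnel.to_dict()
    except ValueError as exc:
        report["publication_bias"] = {"skipped": str(exc)}

    if truth is not None:
        report["truth"] = {
            "lambda": truth.true_lambda,
            "sigma_phylo": truth.config.sigma_phylo,
            "beta": truth.config.beta,
        }

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "package_version": __version__,
        "profile": config.profile,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    config.to_json(outdir / "config.json")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
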
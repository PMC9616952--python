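import numpy as np
import pandas as pd
import pytest

from elasmoavm.data import AVMDataset
from elasmoavm.screening import (
    ChainedForestImputer,
    ModeratorScreener,
    dersimonian_laird_tau2,
    impute_missing,
    informative_moderators,
    logit_effects,
    screen_predictors,
)
from elasmoavm.synthetic import TruthConfig, simulate_dataset

SCREEN_CONFIG = TruthConfig(
    n_species=6,
    n_studies=25,
    records_per_study=(6, 10),
    beta={"ocean[Pacific]": 1.5},
    sigma_phylo=0.2,
    sigma_study=0.3,
    sigma_record=0.2,
    sigma_research_group=0.0,
    smooth_amplitude=0.0,
    miss_hooks_between_floats=0.0,
    miss_soak_duration=0.0,
)


def with_noise_columns(frame: pd.DataFrame, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed + 10_000)
    out = frame.copy()
    out["noise_cat3"] = rng.choice(list("abc"), size=len(out))
    out["noise_num"] = rng.standard_normal(len(out))
    out["noise_cat2"] = rng.choice(["u", "v"], size=len(out))
    return out


class TestWeights:
    def test_logit_effects_continuity_correction(self):
        frame = pd.DataFrame({"n_dead": [0, 5], "n_caught": [10, 5]})
        y, v = logit_effects(frame)
        assert y[0] == pytest.approx(np.log((0.5 / 11) / (1 - 0.5 / 11)))
        assert v[0] == pytest.approx(1 / 0.5 + 1 / 10.5)
        assert np.isfinite(y).all()  # zero and full mortality both usable

    def test_dl_tau2_zero_for_homogeneous_effects(self, rng):
        v = np.full(30, 0.2)
        y = rng.normal(0.0, 0.01, size=30)  # far less spread than v implies
        assert dersimonian_laird_tau2(y, v) == 0.0

    def test_dl_tau2_detects_heterogeneity(self, rng):
        v = np.full(200, 0.05)
        y = rng.normal(0.0, 1.0, size=200)
        tau2 = dersimonian_laird_tau2(y, v)
        assert tau2 == pytest.approx(1.0 - 0.05, abs=0.3)


class TestScreening:
    def test_reproducible_for_fixed_seed(self):
        ds, _ = simulate_dataset(SCREEN_CONFIG, seed=0)
        t1 = screen_predictors(ds, candidates=["ocean", "bait_type"], n_boot=5,
                               n_trees=50, seed=3)
        t2 = screen_predictors(ds, candidates=["ocean", "bait_type"], n_boot=5,
                               n_trees=50, seed=3)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_injected_moderator_beats_noise_in_seed_majority(self):
        """A 1.5-logit ocean effect must outrank three pure-noise predictors
        (and the noise must stay under the 10% cut-off) in most replicates."""
        wins, noise_under = 0, 0
        for seed in range(5):
            ds, _ = simulate_dataset(SCREEN_CONFIG, seed=seed)
            frame = with_noise_columns(ds.frame, seed)
            scr = ModeratorScreener(
                candidates=("ocean", "noise_cat3", "noise_num", "noise_cat2"),
                n_boot=15, n_trees=100, seed=seed,
            )
            scr.fit(frame.drop(columns=["n_dead", "n_caught"]),
                    frame[["n_dead", "n_caught"]].to_numpy())
            tab = scr.importance_table_.table.set_index("predictor")["importance"]
            if tab["ocean"] == max(tab):
                wins += 1
            if all(tab[c] < 10.0 for c in ("noise_cat3", "noise_num", "noise_cat2")):
                noise_under += 1
        assert wins >= 3
        assert noise_under >= 3

    def test_duplicated_predictor_shares_importance(self):
        ds, _ = simulate_dataset(SCREEN_CONFIG, seed=1)
        frame = ds.frame.copy()
        frame["ocean_copy"] = frame["ocean"]
        scr = ModeratorScreener(candidates=("ocean", "ocean_copy"), n_boot=10,
                                n_trees=100, seed=0)
        scr.fit(frame.drop(columns=["n_dead", "n_caught"]),
                frame[["n_dead", "n_caught"]].to_numpy())
        tab = scr.importance_table_.table.set_index("predictor")["importance"]
        assert tab["ocean"] > 0 and tab["ocean_copy"] > 0

    def test_single_cluster_rejected(self, fixture_frame):
        frame = fixture_frame.copy()
        frame["study_id"] = "only_one"
        frame["record_id"] = [f"r{i}" for i in range(len(frame))]
        with pytest.raises(ValueError, match="clusters"):
            screen_predictors(AVMDataset(frame), candidates=["ocean"], n_boot=2)

    def test_constant_response_rejected(self, fixture_frame):
        frame = fixture_frame.copy()
        frame["n_dead"] = 0
        frame["n_caught"] = 10
        with pytest.raises(ValueError, match="constant"):
            screen_predictors(AVMDataset(frame), candidates=["ocean"], n_boot=2)

    def test_taxonomic_predictors_excluded_from_model_terms(self):
        ds, _ = simulate_dataset(SCREEN_CONFIG, seed=2)
        table = screen_predictors(
            ds, candidates=["genus", "family", "ocean"], n_boot=10, n_trees=80, seed=1
        )
        chosen = informative_moderators(table, always_include=("hook_shape",))
        assert "genus" not in chosen and "family" not in chosen
        assert "hook_shape" in chosen


class TestImputation:
    def test_complete_dataset_returned_unchanged(self):
        ds, _ = simulate_dataset(SCREEN_CONFIG, seed=3)
        result = impute_missing(ds, seed=0, n_trees=30)
        pd.testing.assert_frame_equal(result.dataset.frame, ds.frame)
        assert result.n_imputed == 0

    def test_observed_cells_never_altered_and_pmm_subset(self):
        cfg = TruthConfig(**{**vars(SCREEN_CONFIG),
                             "miss_hooks_between_floats": 0.04,
                             "miss_soak_duration": 0.14})
        ds, truth = simulate_dataset(cfg, seed=5)
        result = impute_missing(ds, seed=1, n_trees=50)
        out = result.dataset.frame
        for col in ("hooks_between_floats", "soak_duration"):
            obs = ds.frame[col].notna()
            pd.testing.assert_series_equal(out.loc[obs, col], ds.frame.loc[obs, col])
            imputed_vals = out.loc[~obs, col]
            assert imputed_vals.notna().all()
            assert set(imputed_vals) <= set(ds.frame.loc[obs, col])  # PMM contract

    def test_imputation_beats_marginal_mean_baseline(self):
        """RMSE of chained-forest PMM imputations vs the truth must beat a
        marginal-mean imputer on the same MCAR mask."""
        cfg = TruthConfig(**{**vars(SCREEN_CONFIG), "n_studies": 40,
                             "miss_hooks_between_floats": 0.0,
                             "miss_soak_duration": 0.0})
        wins = 0
        for seed in range(3):
            ds, _ = simulate_dataset(cfg, seed=seed)
            frame = ds.frame.copy()
            rng = np.random.default_rng(seed)
            # smooth-driven dependence: hooks relates to the response; mask MCAR
            mask = rng.random(len(frame)) < 0.10
            truth_vals = frame.loc[mask, "hooks_between_floats"].to_numpy()
            frame.loc[mask, "hooks_between_floats"] = np.nan
            result = impute_missing(AVMDataset(frame), seed=seed, n_trees=100)
            imputed = result.dataset.frame.loc[mask, "hooks_between_floats"].to_numpy()
            rmse_rf = np.sqrt(np.mean((imputed - truth_vals) ** 2))
            baseline = frame["hooks_between_floats"].mean()
            rmse_mean = np.sqrt(np.mean((baseline - truth_vals) ** 2))
            wins += rmse_rf <= rmse_mean
        assert wins >= 2

    def test_constant_column_single_missing_filled_with_constant(self):
        ds, _ = simulate_dataset(SCREEN_CONFIG, seed=7)
        frame = ds.frame.copy()
        frame["hooks_between_floats"] = 20.0
        frame.loc[0, "hooks_between_floats"] = np.nan
        result = impute_missing(AVMDataset(frame), seed=0, n_trees=20)
        assert result.dataset.frame.loc[0, "hooks_between_floats"] == 20.0

    def test_fully_missing_column_rejected(self):
        ds, _ = simulate_dataset(SCREEN_CONFIG, seed=8)
        frame = ds.frame.copy()
        frame["soak_duration"] = np.nan
        with pytest.raises(ValueError, match="soak_duration"):
            impute_missing(AVMDataset(frame))

    def test_transformer_get_set_params(self):
        imp = ChainedForestImputer()
        imp.set_params(pmm_donors=3)
        assert imp.get_params()["pmm_donors"] == 3
        with pytest.raises(ValueError):
            imp.set_params(bogus=1)
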
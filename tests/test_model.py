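import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from elasmoavm.data import AVMDataset
from elasmoavm.design import (
    GroupTerm,
    ModelSpec,
    PriorSettings,
    SamplerSettings,
    canonical_spec,
)
from elasmoavm.model import (
    BinomialPhyloMetaRegression,
    compare_models,
    fit_model,
    posterior_predictive_check,
)
from elasmoavm.phylo import CorrMatrix, brownian_correlation, parse_tree_string
from elasmoavm.synthetic import TruthConfig, simulate_dataset


def single_record_frame(x=3, n=8):
    return pd.DataFrame(
        {
            "record_id": ["r1"], "study_id": ["s1"], "research_group_id": ["g1"],
            "species": ["Prionace glauca"], "genus": [""], "family": [""],
            "order": [""], "n_caught": [n], "n_dead": [x],
            "ocean": ["Atlantic"], "hook_shape": ["circle"], "hook_type": ["unknown"],
            "hooks_between_floats": [np.nan], "soak_duration": [np.nan],
            "bait_type": ["squid"], "body_form": ["fusiform"],
            "ventilation_mode": ["ram_obligate"],
        }
    )


class TestConjugateOracle:
    def test_intercept_only_matches_beta_posterior(self):
        """With a flat prior on the response probability and one record of
        3 dead out of 8, the posterior of p is exactly Beta(4, 6)."""
        ds = AVMDataset(single_record_frame())
        spec = ModelSpec(
            priors=PriorSettings(intercept="flat_response"),
            sampler=SamplerSettings(chains=4, draws=2000, warmup=500, seed=7),
        )
        fit = fit_model(ds, spec)
        p = expit(fit.parameter("intercept")[..., 0]).ravel()
        ref = stats.beta(4, 6)
        assert p.mean() == pytest.approx(ref.mean(), abs=0.01)
        assert p.std() == pytest.approx(ref.std(), abs=0.01)
        assert np.quantile(p, 0.9) == pytest.approx(ref.ppf(0.9), abs=0.02)


class TestFitContracts:
    def test_draw_counts_and_diagnostics(self, small_fit):
        ss = small_fit.spec.sampler
        assert small_fit.theta.shape[:2] == (ss.chains, ss.draws)
        diag = small_fit.diagnostics
        assert diag["parameter"].is_unique
        assert (diag["ess_bulk"] > 0).all()

    def test_seed_reproducibility(self):
        ds, _ = simulate_dataset(
            TruthConfig(n_species=4, n_studies=5, records_per_study=(2, 4),
                        miss_hooks_between_floats=0.0, miss_soak_duration=0.0),
            seed=3,
        )
        spec = ModelSpec(
            fixed_effects=["ocean"],
            group_terms=[GroupTerm("study", "study_id")],
            sampler=SamplerSettings(chains=2, draws=150, warmup=150, seed=5),
        )
        f1 = fit_model(ds, spec)
        f2 = fit_model(ds, spec)
        np.testing.assert_array_equal(f1.theta, f2.theta)

    def test_phylo_with_identity_matches_iid_species_effect(self):
        ds, _ = simulate_dataset(
            TruthConfig(n_species=5, n_studies=8, records_per_study=(3, 6),
                        miss_hooks_between_floats=0.0, miss_soak_duration=0.0),
            seed=11,
        )
        species = sorted(ds.frame["species"].unique())
        sampler = SamplerSettings(chains=2, draws=400, warmup=300, seed=9, target_accept=0.9)

        def make(corr):
            return ModelSpec(
                fixed_effects=["ocean"],
                group_terms=[GroupTerm("phylo", "species", corr), GroupTerm("study", "study_id")],
                sampler=sampler,
            )

        f_ident = fit_model(ds, make(CorrMatrix.identity(species)))
        f_iid = fit_model(ds, make(None))
        m1 = expit(f_ident.parameter("intercept")).mean()
        m2 = expit(f_iid.parameter("intercept")).mean()
        assert m1 == pytest.approx(m2, abs=0.05)
        assert f_ident.sigma("phylo").mean() == pytest.approx(
            f_iid.sigma("phylo").mean(), abs=0.1
        )

    def test_dropping_group_term_reduces_parameter_count(self, small_sim):
        ds, truth = small_sim
        tree = parse_tree_string(truth.tree_newick)
        corr = brownian_correlation(tree, sorted(ds.frame["species"].unique()))
        full = canonical_spec(corr, fixed_effects=["ocean"])
        reduced = ModelSpec(
            fixed_effects=["ocean"],
            spline_terms=full.spline_terms,
            group_terms=full.group_terms[:-1],
        )
        assert reduced.n_parameters(ds.frame) < full.n_parameters(ds.frame)

    def test_phylo_requires_two_species(self):
        ds = AVMDataset(single_record_frame())
        corr = CorrMatrix.identity(["Prionace glauca"])
        spec = ModelSpec(group_terms=[GroupTerm("phylo", "species", corr)])
        with pytest.raises(ValueError, match="2 species"):
            fit_model(ds, spec)

    def test_missing_species_in_corr_matrix_rejected(self, small_sim):
        ds, _ = small_sim
        corr = CorrMatrix.identity(["Species_00"])
        spec = ModelSpec(group_terms=[GroupTerm("phylo", "species", corr)],
                         sampler=SamplerSettings(chains=2, draws=50, warmup=50))
        with pytest.raises(ValueError, match="absent"):
            fit_model(ds, spec)


class TestModelSpecSerialization:
    def test_round_trip_through_dict(self, small_sim):
        ds, truth = small_sim
        tree = parse_tree_string(truth.tree_newick)
        corr = brownian_correlation(tree, sorted(ds.frame["species"].unique()))
        spec = canonical_spec(corr, fixed_effects=["ocean", "hook_shape"])
        back = ModelSpec.from_dict(spec.to_dict())
        assert back.fixed_effects == spec.fixed_effects
        assert [g.label for g in back.group_terms] == [g.label for g in spec.group_terms]
        np.testing.assert_allclose(
            back.group_terms[0].corr.values, spec.group_terms[0].corr.values
        )
        assert vars(back.sampler) == vars(spec.sampler)

    def test_yaml_round_trip(self, small_sim, tmp_path):
        import yaml

        ds, truth = small_sim
        tree = parse_tree_string(truth.tree_newick)
        corr = brownian_correlation(tree, sorted(ds.frame["species"].unique()))
        spec = canonical_spec(corr)
        path = tmp_path / "spec.yaml"
        path.write_text(yaml.safe_dump(spec.to_dict()))
        back = ModelSpec.from_dict(yaml.safe_load(path.read_text()))
        assert back.to_dict() == spec.to_dict()


class TestEstimatorInterface:
    def test_fit_predict_round_trip(self):
        ds, _ = simulate_dataset(
            TruthConfig(n_species=4, n_studies=6, records_per_study=(3, 5),
                        miss_hooks_between_floats=0.0, miss_soak_duration=0.0),
            seed=2,
        )
        est = BinomialPhyloMetaRegression(
            ModelSpec(
                fixed_effects=["ocean"],
                group_terms=[GroupTerm("study", "study_id")],
                sampler=SamplerSettings(chains=2, draws=150, warmup=150, seed=1),
            )
        )
        X = ds.frame.drop(columns=["n_dead", "n_caught"])
        y = ds.frame[["n_dead", "n_caught"]].to_numpy()
        est.fit(X, y)
        assert hasattr(est, "result_")
        proba = est.predict_proba(X.head(5))
        assert proba.shape == (5,)
        assert np.all((proba > 0) & (proba < 1))

    def test_get_set_params(self):
        est = BinomialPhyloMetaRegression()
        spec = ModelSpec(fixed_effects=["ocean"])
        est.set_params(spec=spec)
        assert est.get_params()["spec"] is spec

    def test_bad_count_matrix_rejected(self):
        est = BinomialPhyloMetaRegression()
        X = single_record_frame().drop(columns=["n_dead", "n_caught"])
        with pytest.raises(ValueError):
            est.fit(X, np.array([[5, 3]]))  # dead > caught


class TestModelComparison:
    @pytest.fixture(scope="class")
    def paired_fits(self):
        ds, _ = simulate_dataset(
            TruthConfig(
                n_species=5, n_studies=10, records_per_study=(4, 7),
                beta={"ocean[Pacific]": 2.0}, sigma_phylo=0.2, sigma_study=0.3,
                sigma_record=0.2, sigma_research_group=0.0, smooth_amplitude=0.0,
                miss_hooks_between_floats=0.0, miss_soak_duration=0.0,
            ),
            seed=4,
        )
        sampler = SamplerSettings(chains=2, draws=400, warmup=300, seed=21, target_accept=0.9)
        groups = [GroupTerm("study", "study_id"), GroupTerm("record", "__record__")]
        with_ocean = fit_model(ds, ModelSpec(
            fixed_effects=["ocean"], group_terms=groups, sampler=sampler))
        without = fit_model(ds, ModelSpec(
            fixed_effects=[], group_terms=groups, sampler=sampler))
        return with_ocean, without

    def test_identical_fits_tie_with_weights_summing_to_one(self, paired_fits):
        fit, _ = paired_fits
        cmp = compare_models({"a": fit, "b": fit})
        assert cmp["elpd_diff"].abs().max() == pytest.approx(0.0, abs=1e-9)
        assert cmp["stacking_weight"].sum() == pytest.approx(1.0, abs=1e-6)

    def test_true_predictor_model_wins_stacking(self, paired_fits):
        with_ocean, without = paired_fits
        cmp = compare_models({"ocean": with_ocean, "null": without})
        assert cmp.loc["ocean", "stacking_weight"] > 0.5
        assert cmp.loc["ocean", "elpd_loo"] > cmp.loc["null", "elpd_loo"]

    def test_mismatched_observation_sets_rejected(self, paired_fits, small_fit):
        with_ocean, _ = paired_fits
        with pytest.raises(ValueError, match="different observation sets"):
            compare_models({"a": with_ocean, "b": small_fit})

    def test_psis_loo_matches_exact_conjugate_loo(self):
        """Intercept-only flat-prior model is Beta-conjugate, so exact
        leave-one-out predictives are Beta-binomial; PSIS-LOO must agree
        within its standard error."""
        rng = np.random.default_rng(8)
        n = rng.integers(5, 30, size=12)
        x = rng.binomial(n, 0.35)
        frame = single_record_frame().iloc[np.zeros(12)].reset_index(drop=True)
        frame["record_id"] = [f"r{i}" for i in range(12)]
        frame["n_caught"], frame["n_dead"] = n, x
        ds = AVMDataset(frame)
        spec = ModelSpec(
            priors=PriorSettings(intercept="flat_response"),
            sampler=SamplerSettings(chains=4, draws=2500, warmup=500, seed=17),
        )
        fit = fit_model(ds, spec)
        cmp = compare_models({"m": fit})
        a, b = 1 + x.sum(), 1 + (n - x).sum()
        exact = sum(
            stats.betabinom(int(ni), a - int(xi), b - int(ni - xi)).logpmf(int(xi))
            for xi, ni in zip(x, n)
        )
        assert cmp.loc["m", "elpd_loo"] == pytest.approx(exact, abs=2 * cmp.loc["m", "se"])


class TestPosteriorPredictiveCheck:
    def test_contract_shapes_and_bounds(self, small_fit):
        ppc = posterior_predictive_check(small_fit, n_rep=37, seed=1)
        assert ppc.replicated_counts.shape == (37, small_fit.design.n)
        assert (ppc.replicated_counts >= 0).all()
        assert (ppc.replicated_counts <= small_fit.design.trials[None, :]).all()

    def test_self_consistency_of_model_data(self, small_fit):
        ppc = posterior_predictive_check(small_fit, n_rep=300, seed=2)
        # data were generated from the same hierarchical family the model
        # fits: observed species totals should sit inside the central 95%
        assert ppc.species_outside_band(0.99) == []

    def test_outlier_species_detected(self, small_sim):
        ds, _ = small_sim
        frame = ds.frame.copy()
        bad = frame["species"] == "Species_00"
        frame.loc[bad, "n_dead"] = (
            frame.loc[bad, "n_caught"].to_numpy() * 0.99
        ).astype(int)
        spec = ModelSpec(
            fixed_effects=["ocean"],
            group_terms=[GroupTerm("study", "study_id")],
            sampler=SamplerSettings(chains=2, draws=300, warmup=300, seed=31, target_accept=0.9),
        )
        fit = fit_model(AVMDataset(frame), spec)
        # hold out the anomalous species' records at prediction time: compare
        # to the dataset as generated without the outlier
        ppc = posterior_predictive_check(fit, n_rep=300, seed=3)
        # the pooled model cannot reproduce a 99%-mortality species when the
        # rest of the data say ~35%
        assert "Species_00" in ppc.species_outside_band(0.95)

    def test_invalid_rep_count(self, small_fit):
        with pytest.raises(ValueError):
            posterior_predictive_check(small_fit, n_rep=0)
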
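import numpy as np
import pandas as pd
import pytest

from elasmoavm.data import AVMDataset
from elasmoavm.design import SamplerSettings, canonical_spec
from elasmoavm.model import fit_model
from elasmoavm.phylo import brownian_correlation, parse_tree_string
from elasmoavm.synthetic import TruthConfig, simulate_dataset


FIXTURE_ROWS = [
    # record, study, group, species, genus, family, order, caught, dead, ocean, hook
    ("r1", "s1", "g1", "Prionace glauca", "Prionace", "Carcharhinidae", "Carcharhiniformes", 20, 5, "Atlantic", "circle"),
    ("r2", "s1", "g1", "Prionace glauca", "Prionace", "Carcharhinidae", "Carcharhiniformes", 15, 9, "Pacific", "J"),
    ("r3", "s2", "g1", "Isurus oxyrinchus", "Isurus", "Lamnidae", "Lamniformes", 30, 12, "Atlantic", "circle"),
    ("r4", "s2", "g1", "Isurus oxyrinchus", "Isurus", "Lamnidae", "Lamniformes", 10, 4, "Indian", "J"),
    ("r5", "s3", "g2", "Alopias vulpinus", "Alopias", "Alopiidae", "Lamniformes", 25, 20, "Pacific", "circle"),
    ("r6", "s3", "g2", "Alopias vulpinus", "Alopias", "Alopiidae", "Lamniformes", 12, 0, "Atlantic", "unknown"),
]


def make_fixture_frame() -> pd.DataFrame:
    rows = []
    for rec, st, grp, sp, gen, fam, order, n, x, ocean, hook in FIXTURE_ROWS:
        rows.append(
            dict(
                record_id=rec, study_id=st, research_group_id=grp, species=sp,
                genus=gen, family=fam, order=order, n_caught=n, n_dead=x,
                ocean=ocean, hook_shape=hook, hook_type="unknown",
                hooks_between_floats=25.0, soak_duration=8.0,
                bait_type="squid", body_form="fusiform",
                ventilation_mode="ram_obligate",
            )
        )
    return pd.DataFrame(rows)


@pytest.fixture
def fixture_frame():
    return make_fixture_frame()


@pytest.fixture
def fixture_csv(tmp_path, fixture_frame):
    path = tmp_path / "avm.csv"
    fixture_frame.to_csv(path, index=False)
    return path


SMALL_CONFIG = TruthConfig(
    n_species=6,
    n_studies=12,
    records_per_study=(4, 8),
    n_research_groups=4,
    miss_hooks_between_floats=0.0,
    miss_soak_duration=0.0,
)

FAST_SAMPLER = SamplerSettings(chains=2, draws=300, warmup=300, seed=42, target_accept=0.9)


@pytest.fixture(scope="session")
def small_sim():
    """A complete (no missingness) small synthetic dataset with truth."""
    return simulate_dataset(SMALL_CONFIG, seed=7)


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """Canonical phylogenetic fit on the small synthetic dataset, reduced
    sampler profile; shared across summary tests."""
    ds, truth = small_sim
    tree = parse_tree_string(truth.tree_newick)
    corr = brownian_correlation(tree, sorted(ds.frame["species"].unique()))
    spec = canonical_spec(corr, fixed_effects=["ocean"], sampler=FAST_SAMPLER)
    return fit_model(ds, spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
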
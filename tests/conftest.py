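import numpy as np
import pytest

from lncrank.config import BoosterConfig, RunConfig
from lncrank.data_io import FeatureMeta, FeatureTable
from lncrank.simulate import SimulationSpec, simulate_feature_table, simulate_genome_fixture

ALL_RANKS_12 = {c: (1, 2) for c in ("Genomic", "Expression", "Epigenetic", "Network")}


def make_table(values, categories=None, gene_ids=None, names=None):
    """Build a FeatureTable from a raw matrix with minimal metadata."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n)]
    names = names or [f"Gen_f{j}" for j in range(p)]
    categories = categories or ["Genomic"] * p
    return FeatureTable(
        gene_ids, values, [FeatureMeta(nm, c) for nm, c in zip(names, categories)]
    )


@pytest.fixture(scope="session")
def small_benchmark():
    """Moderate planted-signal benchmark: 60 pos, 600 neg, 40 unknown."""
    spec = SimulationSpec(n_pos=60, n_neg=600, n_unknown=40, seed=3)
    return simulate_feature_table(spec)


@pytest.fixture(scope="session")
def genome_fixture():
    """Default planted genome fixture (500 genes per set)."""
    return simulate_genome_fixture(SimulationSpec(seed=11))


@pytest.fixture()
def light_config():
    """Cheap booster for CV tests that exercise plumbing, not accuracy."""
    return RunConfig(
        booster=BoosterConfig(n_estimators=60, max_depth=4, seed=5),
        n_folds=5,
        seed=5,
    )
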
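import numpy as np
import pandas as pd
import pytest

from nutriome.abundance import GenusAbundanceTable
from nutriome.features import default_feature_set
from nutriome.synthetic import (
    SyntheticCohortSpec,
    demo_genus_names,
    generate_reference_cohort,
)


@pytest.fixture(scope="session")
def feature_config():
    """(FeatureSet, genus->phylum) from the packaged roster."""
    return default_feature_set()


@pytest.fixture(scope="session")
def reference_table(feature_config):
    """194-sample synthetic reference with feature-computable genus names."""
    feature_set, phyla = feature_config
    spec = SyntheticCohortSpec(
        n_samples=194,
        n_genera=120,
        seed=1,
        genus_names=tuple(demo_genus_names(120, feature_set)),
    )
    table = generate_reference_cohort(spec)
    table.phylum_of = phyla
    return table


@pytest.fixture
def tiny_counts():
    """3 samples x 4 genera integer counts."""
    return GenusAbundanceTable(
        data=pd.DataFrame(
            [[50, 30, 15, 5], [80, 40, 20, 10], [120, 60, 30, 10]],
            index=["s1", "s2", "s3"],
            columns=["Bacteroides", "Prevotella", "Faecalibacterium", "Escherichia"],
        ),
        mode="counts",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
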
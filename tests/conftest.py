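import numpy as np
import pandas as pd
import pytest

from saltomics.expression import ExperimentDesign, ExpressionTable
from saltomics.features import FeatureSet, FeatureType, GenomicFeature
from saltomics.simulate import SimulationConfig


@pytest.fixture
def design():
    return ExperimentDesign((0.0, 0.5, 2.0, 24.0), 2)


@pytest.fixture
def tiny_features():
    """One mRNA with an overlapping opposite-strand asRNA, plus bystanders."""
    return FeatureSet(
        [
            GenomicFeature("mrna1", FeatureType.mRNA, "chr", 100, 400, "+", gene_id="mrna1"),
            GenomicFeature("as1", FeatureType.asRNA, "chr", 150, 250, "-", gene_id="mrna1"),
            GenomicFeature("mrna2", FeatureType.mRNA, "chr", 1000, 1300, "-", gene_id="mrna2"),
            GenomicFeature("ncr1", FeatureType.sRNA, "chr", 2000, 2100, "+"),
        ]
    )


def make_signal_table(design, values, ids=None):
    """Build an ExpressionTable from an array shaped (features, tp*rep)."""
    values = np.asarray(values, dtype=float)
    ids = ids or [f"f{i}" for i in range(values.shape[0])]
    return ExpressionTable(
        pd.DataFrame(values, index=ids, columns=design.columns()), value_kind="signal"
    )


@pytest.fixture
def small_sim_config():
    """Small but complete synthetic world for fast end-to-end tests."""
    return SimulationConfig(
        n_mrna=80, n_asrna=30, n_srna=10,
        n_pairs_inverse=8, n_pairs_coregulated=7,
        n_proteins=60, n_metabolites=8, seed=7,
    )
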
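import numpy as np
import pandas as pd
import pytest

from hippolink import synth
from hippolink.io import CountMatrix, GeneAnnotation, PeakSet


@pytest.fixture(scope="session")
def small_counts() -> CountMatrix:
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.integers(1, 500, size=(10, 4)),
        index=[f"g{i}" for i in range(10)],
        columns=[f"s{i}" for i in range(4)],
    )
    return CountMatrix(data)


@pytest.fixture(scope="session")
def toy_annotation() -> GeneAnnotation:
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["gA", "gB"],
                "chrom": ["chr1", "chr1"],
                "start": [10_000, 18_000],
                "end": [12_000, 20_001],
                "strand": ["+", "-"],
            }
        )
    )


@pytest.fixture(scope="session")
def toy_peaks() -> PeakSet:
    return PeakSet(
        pd.DataFrame(
            {
                "peak_id": ["p1", "p2", "p3"],
                "chrom": ["chr1"] * 3,
                "start": [8_400, 11_600, 15_000],
                "end": [8_600, 11_700, 15_100],
            }
        )
    )


@pytest.fixture(scope="session")
def two_group_design() -> synth.DesignSpec:
    """3 control vs 3 hpo_RNAi germ libraries at one stage."""
    return synth.DesignSpec(
        replicate_map={
            ("germ", "mid", "control"): 3,
            ("germ", "mid", "hpo_RNAi"): 3,
        },
        n_genes=2000,
    )


def null_truth(n_genes: int, dispersion: float = 0.05) -> pd.DataFrame:
    truth = pd.DataFrame(
        0.0,
        index=pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene_id"),
        columns=list(synth.CONTRASTS),
    )
    truth["class"] = "null"
    truth["dispersion"] = dispersion
    return truth


@pytest.fixture(scope="session")
def default_simulation():
    """One default 48-library simulation shared across tests."""
    counts, meta, truth = synth.make_counts(seed=1234)
    return counts, meta, truth
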
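import numpy as np
import pandas as pd
import pytest

from sweepscape.types import CohortPanel, GenotypeMatrix, MISSING


def make_matrix(dosage, pos=None, chrom="1", gq=None, sample_prefix="s"):
    """Small GenotypeMatrix from a sites x samples dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    if gq is None:
        gq = np.full(dosage.shape, 99, dtype=np.int16)
    rng = np.random.default_rng(0)
    ref = np.full(n_sites, "A", dtype=object)
    alt = np.full(n_sites, "T", dtype=object)
    return GenotypeMatrix(
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref_allele=ref,
        alt_allele=alt,
        dosage=dosage,
        gq=np.asarray(gq, dtype=np.int16),
        sample_ids=[f"{sample_prefix}{k}" for k in range(n_samples)],
    )


def make_panel(sample_ids, cohorts, continents=None, coverage=None):
    n = len(sample_ids)
    if continents is None:
        continents = ["Americas"] * n
    if coverage is None:
        coverage = [20.0] * n
    return CohortPanel(
        pd.DataFrame(
            {"cohort": cohorts, "continent": continents,
             "mean_coverage": coverage},
            index=pd.Index(sample_ids, name="sample"),
        )
    )


@pytest.fixture
def simple_matrix():
    return make_matrix([[0, 1, 2], [0, 0, 1], [2, 2, 2]])


@pytest.fixture
def two_cohort_panel():
    return make_panel(
        ["s0", "s1", "s2"], ["c1", "c1", "c2"],
    )
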
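import numpy as np
import pandas as pd
import pytest

from sikapanel.datatypes import GenotypeMatrix, VariantSite
from sikapanel.simcross import SimulationConfig, simulate_cohort


def make_gm(calls, samples=None, sites=None, spacing=1000, ref="A", alt="C"):
    """Small genotype matrix with auto-generated, well-spaced sites."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    if sites is None:
        sites = [
            VariantSite(contig="chr1", pos=spacing * (j + 1), ref=ref, alt=alt)
            for j in range(m)
        ]
    return GenotypeMatrix(samples, sites, calls)


def two_pop_labels(gm, n_a, pop_a="sika_ref", pop_b="red_ref"):
    return pd.Series(
        [pop_a] * n_a + [pop_b] * (gm.n_samples - n_a), index=gm.samples, name="population"
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Shared noiseless five-generation cohort, modest size for speed."""
    cfg = SimulationConfig(
        n_contigs=2,
        contig_length=200_000,
        n_background_sites=150,
        n_diagnostic_sites=120,
        pop_sizes={"sika_ref": 40, "red_ref": 35, "F1": 12, "F2": 12, "F3": 12},
        master_seed=11,
    )
    return simulate_cohort(cfg)
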
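import numpy as np
import pandas as pd
import pytest

from tmzkit import synthetic_data
from tmzkit.io_formats import CountMatrix


@pytest.fixture
def toy_design():
    """Small library: 6 genes x 3 guides + 40 NTCs, 3 default pathways."""
    return synthetic_data.make_library_design(
        n_genes=6, guides_per_gene=3, n_ntc=40, seed=1, n_pathways=3
    )


@pytest.fixture
def toy_signatures():
    return synthetic_data.make_signature_matrix(n_signatures=5, seed=2)


def make_count_matrix(values: dict, guide_ids, samples_meta) -> CountMatrix:
    """Build a CountMatrix from a column dict and (tp, treat, geno, rep) tuples."""
    counts = pd.DataFrame(values, index=pd.Index(guide_ids, name="guide_id"))
    samples = pd.DataFrame(
        [(name, *meta) for name, meta in samples_meta.items()],
        columns=["sample", "timepoint", "treatment", "genotype", "replicate"],
    ).set_index("sample")
    return CountMatrix(counts, samples)


@pytest.fixture
def paired_counts():
    """Two guides, one treatment, one replicate, PD0/PD20 matched."""
    return make_count_matrix(
        {"PD0_TMZ_R1": np.array([100.0, 100.0]),
         "PD20_TMZ_R1": np.array([25.0, 100.0])},
        ["g1", "g2"],
        {"PD0_TMZ_R1": ("PD0", "TMZ", "WT", 1),
         "PD20_TMZ_R1": ("PD20", "TMZ", "WT", 1)},
    )
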
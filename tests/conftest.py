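import numpy as np
import pandas as pd
import pytest

from dmsfit import (
    DesignRow,
    JointDataset,
    LibraryDesign,
    ModelDesign,
    generate_library,
    variant_table_from_frame,
)


@pytest.fixture
def tiny_table():
    """WT 'ACD' plus three variants, hand-written fitness and errors."""
    df = pd.DataFrame(
        {
            "aa_seq": ["ACD", "AVD", "ACE", "AVE"],
            "fitness": [0.0, 0.5, -0.3, 0.1],
            "sigma": [0.1, 0.1, 0.2, 0.1],
        }
    )
    return variant_table_from_frame(df, wild_type="ACD")


@pytest.fixture
def random_landscape():
    """Complete 3-position biallelic landscape with random phenotypes."""
    lib = LibraryDesign.biallelic(3)
    seqs = generate_library(lib)
    rng = np.random.default_rng(11)
    df = pd.DataFrame(
        {"aa_seq": seqs, "fitness": rng.normal(size=len(seqs)), "sigma": 0.1}
    )
    return variant_table_from_frame(df, wild_type=lib.wild_type)


def linear_joint_dataset(n_positions=6, seed=4, sigma=1e-3, wt_term=0.4):
    """Noiseless additive landscape wrapped as a single-phenotype dataset."""
    lib = LibraryDesign.biallelic(n_positions)
    seqs = generate_library(lib)
    rng = np.random.default_rng(seed)
    coefs = rng.normal(0, 0.8, n_positions)
    wt = lib.wild_type
    y = np.array(
        [wt_term + sum(c for c, (a, w) in zip(coefs, zip(s, wt)) if a != w) for s in seqs]
    )
    table = variant_table_from_frame(
        pd.DataFrame({"aa_seq": seqs, "fitness": y, "sigma": sigma}), wild_type=wt
    )
    design = ModelDesign([DesignRow("assay", ("Trait",), "Linear", "assay.tsv")])
    return JointDataset(design=design, tables=[table]), coefs, wt_term


@pytest.fixture
def linear_dataset():
    return linear_joint_dataset()
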
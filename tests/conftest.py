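import numpy as np
import pandas as pd
import pytest

from mrmediation import (
    HarmonizedPair,
    SummaryStatRecord,
    SummaryStatTable,
    TraitType,
)


def make_table(label, betas, ses, pvals, eafs=None, trait_type=TraitType.CONTINUOUS,
               ids=None, effect_alleles=None, other_alleles=None):
    """Small-table builder used across the suite."""
    k = len(betas)
    ids = ids or [f"rs{i + 1}" for i in range(k)]
    ea = effect_alleles or ["A"] * k
    oa = other_alleles or ["G"] * k
    eafs = eafs if eafs is not None else [0.3] * k
    df = pd.DataFrame({
        "variant_id": ids, "effect_allele": ea, "other_allele": oa,
        "eaf": eafs, "beta": betas, "se": ses, "pval": pvals, "n": 10000.0,
    })
    return SummaryStatTable(label, trait_type, df)


def random_pair(rng, k=10, beta=0.2):
    """A random harmonized set with true slope ``beta`` and no pleiotropy."""
    bx = rng.uniform(0.05, 0.3, k) * rng.choice([-1, 1], k)
    se_x = rng.uniform(0.005, 0.02, k)
    se_y = rng.uniform(0.005, 0.05, k)
    by = beta * bx + rng.normal(0, se_y)
    return HarmonizedPair([f"rs{i}" for i in range(k)], bx, se_x, by, se_y)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def five_row_tsv(tmp_path):
    path = tmp_path / "five.tsv"
    df = pd.DataFrame({
        "SNP": [f"rs{i}" for i in range(1, 6)],
        "effect_allele": ["a", "C", "G", "T", "A"],
        "other_allele": ["g", "T", "A", "C", "C"],
        "eaf": [0.1, 0.2, 0.3, 0.4, 0.25],
        "beta": [0.1, -0.2, 0.05, 0.3, -0.15],
        "se": [0.01, 0.02, 0.01, 0.03, 0.02],
        "pval": [1e-10, 1e-9, 1e-3, 0.5, 1e-12],
        "samplesize": [1000] * 5,
    })
    df.to_csv(path, sep="\t", index=False)
    return path
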
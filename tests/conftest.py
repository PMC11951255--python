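import numpy as np
import pandas as pd
import pytest

from cismr import SD_UNITS, HarmonizedSet, LDMatrix, SummaryStatSet


def make_sumstats(trait_name="trait", trait_scale=SD_UNITS, **columns):
    """Build a SummaryStatSet from keyword column overrides; defaults give a
    well-formed 3-variant table on chromosome 11."""
    base = {
        "variant_id": ["rs1", "rs2", "rs3"],
        "chrom": ["11", "11", "11"],
        "pos": [116_700_000, 116_705_000, 116_710_000],
        "effect_allele": ["A", "C", "G"],
        "other_allele": ["G", "T", "A"],
        "eaf": [0.3, 0.25, 0.4],
        "beta": [0.08, -0.07, 0.09],
        "se": [0.01, 0.01, 0.012],
        "pval": [1e-15, 1e-12, 1e-13],
        "n": [35365.0, 35365.0, 35365.0],
    }
    base.update(columns)
    n = len(base["variant_id"])

    def fit(v):
        if isinstance(v, (list, np.ndarray)):
            v = list(v)
            return (v * (n // len(v) + 1))[:n]
        return [v] * n

    df = pd.DataFrame({k: fit(v) for k, v in base.items()})
    return SummaryStatSet(trait_name, trait_scale, df)


def consistent_harmonized(theta=0.4, j=6, seed=0, se_y=0.05):
    """A HarmonizedSet whose ratios all equal theta exactly (no noise)."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.2, 1.0, j)
    return HarmonizedSet.from_arrays(x, np.full(j, 0.01), theta * x,
                                     np.full(j, se_y))


def noisy_harmonized(theta=0.4, j=20, seed=0, se_y=0.05, se_x=0.01):
    rng = np.random.default_rng(seed)
    x_true = rng.uniform(0.2, 1.0, j)
    x = x_true + rng.normal(0, se_x, j)
    y = theta * x_true + rng.normal(0, se_y, j)
    return HarmonizedSet.from_arrays(x, np.full(j, se_x), y, np.full(j, se_y))


@pytest.fixture
def simple_stats():
    return make_sumstats()


@pytest.fixture
def identity_ld():
    return LDMatrix(["rs1", "rs2", "rs3"], np.eye(3))
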
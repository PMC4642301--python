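import numpy as np
import pandas as pd
import pytest

from rohsurv.io_plink import Dataset
from rohsurv.simulate import SimulationConfig, simulate_cohort


def make_variants(m, chrom="1", spacing=12_000, start=10_000):
    return pd.DataFrame(
        {
            "variant_id": [f"s{i}" for i in range(m)],
            "chrom": chrom,
            "bp": start + spacing * np.arange(m),
            "a1": "A",
            "a2": "G",
        }
    )


def make_dataset(codes, chrom="1", spacing=12_000, groups=None, populations=None):
    codes = np.asarray(codes, dtype=np.int16)
    n, m = codes.shape
    samples = pd.DataFrame(
        {
            "sample_id": [f"ind{i}" for i in range(n)],
            "population": populations if populations is not None else ["pop"] * n,
            "group": groups if groups is not None else ["STS", "LTS"] * (n // 2) + ["STS"] * (n % 2),
        }
    )
    return Dataset(codes=codes, variants=make_variants(m, chrom, spacing), samples=samples)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-sample, 2000-SNP cohort with implanted autozygous segments."""
    cfg = SimulationConfig(
        pop_sizes={"A": (15, 15), "B": (15, 15)},
        m_variants=2000,
        chrom_lengths={"1": 12_000_000, "2": 12_000_000},
        fst=0.01,
        inbreeding_f=0.0,
        roh_rate=(0.8, 0.8),
        roh_length_kb=("uniform", 1200.0, 3000.0),
        missing_rate=0.002,
        seed=42,
    )
    return simulate_cohort(cfg)
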
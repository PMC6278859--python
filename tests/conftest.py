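import numpy as np
import pandas as pd
import pytest

from admixscan.genotype_io import VariantTable


def make_table(calls, chrom="1", spacing=20_000, groups=None):
    """VariantTable from a raw calls matrix with evenly spaced positions."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    variants = pd.DataFrame({
        "chrom": chrom,
        "pos": np.arange(1, m + 1) * spacing,
        "id": [f"snp{j}" for j in range(m)],
        "ref": "A", "alt": "G",
    })
    samples = pd.DataFrame({
        "id": [f"ind{i:03d}" for i in range(n)],
        "group": groups if groups is not None else [""] * n,
    })
    return VariantTable(variants, samples, calls)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-individual cohort on two 80-Mb chromosomes with one seeded
    NAF-deviant region (0.22 -> 0.46) and one injected 2.5-Mb ROH."""
    from admixscan import synthetic as syn

    vt, dt, truth = syn.simulate_cohort(
        60,
        genome={"1": 80_000_000, "2": 80_000_000},
        spacing_bp=40_000,
        seed=20240901,
        deviant_regions=[("1", 30_000_000, 40_000_000, 1, 0.46)],
        roh=[(0, "2", 10_000_000, 12_500_000)],
    )
    return vt, dt, truth
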
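import numpy as np
import pandas as pd
import pytest

from methdiff import BinMatrix, SimConfig, simulate_counts, simulate_genome


def toy_samples(n_pairs: int = 2, subtypes=("simple", "ductal")) -> pd.DataFrame:
    rows = []
    for i in range(n_pairs):
        pid = f"P{i + 1:02d}"
        st = subtypes[i % len(subtypes)]
        rows.append({"sample_id": f"{pid}T", "pair_id": pid, "condition": "tumor", "subtype": st})
        rows.append({"sample_id": f"{pid}N", "pair_id": pid, "condition": "normal", "subtype": st})
    return pd.DataFrame(rows)


def toy_matrix(counts, chrom="chr1", cg=5, samples=None) -> BinMatrix:
    counts = np.asarray(counts, dtype=float)
    n_bins = counts.shape[0]
    if samples is None:
        samples = toy_samples(counts.shape[1] // 2)
    bins = pd.DataFrame(
        {
            "chrom": [chrom] * n_bins if isinstance(chrom, str) else chrom,
            "start": np.arange(n_bins) * 500,
            "end": (np.arange(n_bins) + 1) * 500,
            "cg_count": [cg] * n_bins if np.isscalar(cg) else cg,
        }
    )
    return BinMatrix(bins=bins, samples=samples, counts=counts)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A scaled-down simulation: 4,000 bins, 11 pairs, fast everywhere."""
    return SimConfig(
        n_chromosomes=3,
        chrom_length=1_000_000,
        n_genes=40,
        n_cmt_dmrs=60,
        n_subtype_dmrs=60,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    genome = simulate_genome(small_cfg)
    matrix, truth = simulate_counts(small_cfg, genome)
    return genome, matrix, truth
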
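"""Genome binning, count-matrix handling, filtering, normalization and QC.

Methylation signal is quantified per fixed-width genome window ("bin",
500 bp by default).  The central container is :class:`BinMatrix`: a bin
table (chrom, start, end, CG-dinucleotide count) plus a sample sheet
(sample_id, pair_id, condition, subtype) and a bins x samples count matrix.

Coordinates are 0-based half-open throughout, matching BED.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CONDITIONS = ("tumor", "normal")

__all__ = [
    "BinMatrix",
    "FilterResult",
    "cpg_coverage_profile",
    "filter_bins",
    "make_bins",
    "quantile_normalize",
    "read_chrom_sizes",
    "read_counts_tsv",
    "read_sample_sheet",
    "sample_correlation",
    "write_bedgraph",
]


def read_chrom_sizes(path: str | Path) -> pd.Series:
    """Read a UCSC-style two-column chrom.sizes TSV into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={"chrom": str})
    if df["chrom"].duplicated().any():
        dups = df.loc[df["chrom"].duplicated(), "chrom"].tolist()
        raise ValueError(f"duplicate chromosome names: {dups}")
    return df.set_index("chrom")["size"]


def _count_cg(seq: str) -> int:
    return seq.upper().count("CG")


def make_bins(
    chrom_sizes: Mapping[str, int] | pd.Series,
    window: int,
    sequence: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Tile each chromosome into half-open windows of ``window`` bases.

    The last bin of a chromosome may be shorter; it is kept.  When
    ``sequence`` (a chrom -> string mapping) is given, a ``cg_count``
    column holds the number of CG dinucleotides per bin (a CG straddling
    a bin boundary is attributed to the bin containing its C).

    Parameters
    ----------
    chrom_sizes
        Mapping of chromosome name to length in bases.
    window
        Bin width in bases, > 0.
    sequence
        Optional per-chromosome nucleotide sequence.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if isinstance(chrom_sizes, pd.Series):
        chrom_sizes = chrom_sizes.to_dict()
    names = list(chrom_sizes)
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromosome names")
    rows = []
    for chrom in names:
        size = int(chrom_sizes[chrom])
        if size <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive size")
        starts = np.arange(0, size, window)
        ends = np.minimum(starts + window, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    bins = pd.concat(rows, ignore_index=True)
    if sequence is not None:
        cg = np.empty(len(bins), dtype=np.int64)
        i = 0
        for chrom in names:
            seq = sequence[chrom].upper()
            n = int(np.ceil(len(seq) / window)) if len(seq) else 0
            size = int(chrom_sizes[chrom])
            nbins = int(np.ceil(size / window))
            for j in range(nbins):
                s, e = j * window, min((j + 1) * window, size)
                # +1 so a boundary-straddling CG counts toward the C's bin
                cg[i] = seq[s : min(e + 1, size)].count("CG")
                i += 1
        bins["cg_count"] = cg
    return bins


@dataclass
class BinMatrix:
    """Bins x samples count matrix with bin and sample metadata.

    Attributes
    ----------
    bins : DataFrame with columns chrom, start, end and optionally cg_count.
    samples : DataFrame with columns sample_id, pair_id, condition, subtype.
    counts : float array, shape (n_bins, n_samples), non-negative.
    """

    bins: pd.DataFrame
    samples: pd.DataFrame
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.bins), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.bins)} bins x {len(self.samples)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self._check_samples()

    def _check_samples(self) -> None:
        s = self.samples
        required = {"sample_id", "pair_id", "condition", "subtype"}
        missing = required - set(s.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        bad = set(s["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        for pair_id, grp in s.groupby("pair_id"):
            conds = sorted(grp["condition"])
            if conds != ["normal", "tumor"]:
                raise ValueError(f"pair {pair_id} must have exactly one tumor and one normal")
            if grp["subtype"].nunique() != 1:
                raise ValueError(f"pair {pair_id} members must share a subtype")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, condition: str | None = None, subtype: str | None = None) -> np.ndarray:
        mask = np.ones(self.n_samples, dtype=bool)
        if condition is not None:
            mask &= (self.samples["condition"] == condition).to_numpy()
        if subtype is not None:
            mask &= (self.samples["subtype"] == subtype).to_numpy()
        return np.flatnonzero(mask)

    def paired_columns(self) -> tuple[np.ndarray, np.ndarray, list]:
        """Column indices of (tumor, normal) members, aligned by pair."""
        s = self.samples.reset_index(drop=True)
        pairs = sorted(s["pair_id"].unique())
        t_idx, n_idx = [], []
        for p in pairs:
            grp = s[s["pair_id"] == p]
            t_idx.append(grp.index[grp["condition"] == "tumor"][0])
            n_idx.append(grp.index[grp["condition"] == "normal"][0])
        return np.array(t_idx), np.array(n_idx), pairs

    def log2_values(self, pseudocount: float = 1.0) -> np.ndarray:
        """log2(count + pseudocount); the working scale for all statistics."""
        return np.log2(self.counts + pseudocount)

    def subset_bins(self, index: np.ndarray | list) -> "BinMatrix":
        idx = np.asarray(index)
        return BinMatrix(
            bins=self.bins.iloc[idx].reset_index(drop=True),
            samples=self.samples.copy(),
            counts=self.counts[idx],
        )

    # ------------------------------------------------------------------ IO
    def to_tsv(self, path: str | Path) -> None:
        df = self.bins.copy()
        for sid, col in zip(self.samples["sample_id"], self.counts.T):
            df[sid] = col
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path: str | Path, sample_sheet: str | Path | pd.DataFrame) -> "BinMatrix":
        df = pd.read_csv(counts_path, sep="\t", dtype={"chrom": str})
        if isinstance(sample_sheet, (str, Path)):
            samples = read_sample_sheet(sample_sheet)
        else:
            samples = sample_sheet.copy()
        meta_cols = [c for c in ("chrom", "start", "end", "cg_count") if c in df.columns]
        bins = df[meta_cols]
        counts = df[list(samples["sample_id"])].to_numpy(dtype=float)
        return cls(bins=bins.reset_index(drop=True), samples=samples.reset_index(drop=True), counts=counts)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def read_counts_tsv(counts_path: str | Path, sample_sheet: str | Path | pd.DataFrame) -> BinMatrix:
    return BinMatrix.from_tsv(counts_path, sample_sheet)


def write_bedgraph(m: BinMatrix, sample_id: str, path: str | Path) -> None:
    """Write one sample's per-bin signal as bedGraph (IGV-loadable)."""
    j = list(m.samples["sample_id"]).index(sample_id)
    df = m.bins[["chrom", "start", "end"]].copy()
    df["value"] = m.counts[:, j]
    df.to_csv(path, sep="\t", index=False, header=False)


@dataclass
class FilterResult:
    """Filtered matrix plus per-filter removal tallies.

    Removed bins are attributed to the first failing filter, checked in
    the order: dropped chromosome, no CG dinucleotide, low total signal.
    """

    matrix: BinMatrix
    removed_chrom: int = 0
    removed_no_cg: int = 0
    removed_low_signal: int = 0
    kept: int = 0

    @property
    def removed_total(self) -> int:
        return self.removed_chrom + self.removed_no_cg + self.removed_low_signal

    def as_dict(self) -> dict:
        return {
            "kept": self.kept,
            "removed_chrom": self.removed_chrom,
            "removed_no_cg": self.removed_no_cg,
            "removed_low_signal": self.removed_low_signal,
            "removed_total": self.removed_total,
        }


def filter_bins(
    m: BinMatrix,
    min_total: int = 20,
    drop_chroms: Iterable[str] = ("chrX",),
    require_cg: bool = True,
) -> FilterResult:
    """Apply the standard bin filters to a raw count matrix.

    A bin is retained when its chromosome is not in ``drop_chroms``, it
    contains at least one CG dinucleotide (when ``require_cg``), and the
    sum of its raw counts across all samples is >= ``min_total``.  Bin
    order is preserved; an empty result is allowed.
    """
    drop = set(drop_chroms)
    chrom_bad = m.bins["chrom"].isin(drop).to_numpy()
    if require_cg:
        if "cg_count" not in m.bins.columns:
            raise ValueError("require_cg=True but bins carry no cg_count column")
        cg_bad = (m.bins["cg_count"].to_numpy() < 1) & ~chrom_bad
    else:
        cg_bad = np.zeros(m.n_bins, dtype=bool)
    totals = m.counts.sum(axis=1)
    low_bad = (totals < min_total) & ~chrom_bad & ~cg_bad
    keep = ~(chrom_bad | cg_bad | low_bad)
    return FilterResult(
        matrix=m.subset_bins(np.flatnonzero(keep)),
        removed_chrom=int(chrom_bad.sum()),
        removed_no_cg=int(cg_bad.sum()),
        removed_low_signal=int(low_bad.sum()),
        kept=int(keep.sum()),
    )


def quantile_normalize(m: BinMatrix) -> BinMatrix:
    """Force every sample's bin-count distribution onto the common
    reference distribution of across-sample order-statistic means.

    Tied values within a column receive the mean of the reference values
    their ranks span, so the map is well defined.  On tie-free input the
    map is exactly idempotent; tie-averaging makes repeated application
    agree only approximately, since averaged ties perturb the column
    multisets.
    """
    if m.n_samples < 2:
        warnings.warn("quantile normalization with a single sample is the identity")
        out = BinMatrix.__new__(BinMatrix)
        out.bins, out.samples, out.counts = m.bins, m.samples, m.counts.copy()
        return out
    x = m.counts
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # average reference values over ties
        out[:, j] = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
    return replace(m, counts=out)


def cpg_coverage_profile(
    m: BinMatrix,
    depth_grid: Iterable[int] = (0, 1, 2, 5, 10, 20),
) -> pd.DataFrame:
    """Per sample and depth threshold, the fraction of bins (and of genome
    bases, weighting each bin by its width) whose count strictly exceeds
    the threshold.

    Returns a long-format table with columns sample_id, depth,
    fraction_bins, fraction_bases.
    """
    widths = (m.bins["end"] - m.bins["start"]).to_numpy(dtype=float)
    total_bases = widths.sum()
    rows = []
    for j, sid in enumerate(m.samples["sample_id"]):
        col = m.counts[:, j]
        for d in depth_grid:
            above = col > d
            rows.append(
                {
                    "sample_id": sid,
                    "depth": d,
                    "fraction_bins": above.mean() if m.n_bins else 0.0,
                    "fraction_bases": widths[above].sum() / total_bases if total_bases else 0.0,
                }
            )
    return pd.DataFrame(rows)


def sample_correlation(m: BinMatrix) -> pd.DataFrame:
    """Pearson correlation between samples over all bins."""
    r = np.corrcoef(m.counts, rowvar=False)
    r = np.atleast_2d(r)
    ids = list(m.samples["sample_id"])
    return pd.DataFrame(r, index=ids, columns=ids)
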
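"""Methylation-expression integration and targeted-bisulfite validation.

Expression is a gene x sample FPKM table over the same paired design as
the methylation data; contrasts are paired t-tests on log2(FPKM + 1).  A
gene with DMRs is called anti-correlated when its expression shifts
significantly in the direction opposite to its methylation change
(hypermethylated & down, or hypomethylated & up).

Targeted bisulfite validation works on per-CG C/T read counts: the
methylation level of a site in a sample is 100 * C / (C + T), and paired
t-tests across tumor/normal pairs are run per site, per region (pair-wise
mean over sites), or per region within each subtype.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "bs_methylation_ratio",
    "bs_region_test",
    "call_anticorrelation",
    "expression_contrast",
    "read_bs_table",
    "read_expression_tsv",
]


def read_expression_tsv(path) -> pd.DataFrame:
    """Gene x sample FPKM table; first column is the gene id."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])


def read_bs_table(path) -> pd.DataFrame:
    """Long-format BS counts: chrom, pos, sample_id, pair_id, condition,
    subtype, c_count, t_count."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def _paired_t(tumor: np.ndarray, normal: np.ndarray) -> float:
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_rel(tumor, normal)
    p = float(res.pvalue)
    return 1.0 if not np.isfinite(p) else p


def expression_contrast(
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-gene tumor-vs-normal contrast on log2(FPKM + 1).

    ``samples`` is the standard sample sheet; only pairs with both members
    in the expression table are used.  Returns gene_id, log2fc (difference
    of pair-mean log2 values), p_value (paired t), q_value (BH).
    """
    from statsmodels.stats.multitest import multipletests

    s = samples.set_index("sample_id")
    pairs = []
    for pid, grp in samples.groupby("pair_id"):
        t = grp.loc[grp["condition"] == "tumor", "sample_id"].iloc[0]
        n = grp.loc[grp["condition"] == "normal", "sample_id"].iloc[0]
        if t in expression.columns and n in expression.columns:
            pairs.append((t, n))
    if len(pairs) < min_pairs:
        warnings.warn(f"only {len(pairs)} complete pairs in the expression table")
    if not pairs:
        return pd.DataFrame(columns=["gene_id", "log2fc", "p_value", "q_value"])
    log2 = np.log2(expression + 1.0)
    tum = log2[[t for t, _ in pairs]].to_numpy()
    nor = log2[[n for _, n in pairs]].to_numpy()
    log2fc = tum.mean(axis=1) - nor.mean(axis=1)
    if len(pairs) >= min_pairs:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_rel(tum, nor, axis=1)
        p = np.asarray(res.pvalue)
        p[~np.isfinite(p)] = 1.0
    else:
        p = np.full(len(log2fc), np.nan)
    out = pd.DataFrame(
        {
            "gene_id": expression.index,
            "log2fc": log2fc,
            "p_value": p,
        }
    )
    finite = np.isfinite(out["p_value"])
    out["q_value"] = np.nan
    if finite.any():
        out.loc[finite, "q_value"] = multipletests(out.loc[finite, "p_value"], method="fdr_bh")[1]
    return out


def call_anticorrelation(
    dmg_directions: pd.DataFrame,
    contrasts: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify each DMG's methylation-expression relationship.

    ``dmg_directions`` needs gene_id and meth_direction (the majority
    direction over the gene's DMRs; a tie is passed in as "indeterminate").
    A gene is ``anti_correlated`` when its expression fold change is
    significant (p < alpha) and opposite in sign to the methylation
    direction, ``correlated`` when significant and same-signed, otherwise
    ``indeterminate``.  Genes missing from the contrasts are flagged.
    """
    c = contrasts.set_index("gene_id")
    rows = []
    for _, r in dmg_directions.iterrows():
        gid, direction = r["gene_id"], r["meth_direction"]
        if gid not in c.index:
            rows.append({"gene_id": gid, "meth_direction": direction, "call": "missing_expression",
                         "expr_log2fc": np.nan, "expr_p": np.nan})
            continue
        fc = float(c.loc[gid, "log2fc"])
        p = float(c.loc[gid, "p_value"])
        if direction not in ("hyper", "hypo") or not np.isfinite(p) or p >= alpha or fc == 0:
            call = "indeterminate"
        else:
            meth_sign = 1 if direction == "hyper" else -1
            call = "anti_correlated" if np.sign(fc) == -meth_sign else "correlated"
        rows.append({"gene_id": gid, "meth_direction": direction, "call": call,
                     "expr_log2fc": fc, "expr_p": p})
    return pd.DataFrame(rows)


def majority_direction(records: pd.DataFrame, gene_col: str = "gene_id") -> pd.DataFrame:
    """Majority hyper/hypo direction per gene over its DMRs (tie ->
    indeterminate)."""
    rows = []
    for gid, grp in records.groupby(gene_col):
        n_hyper = int((grp["direction"] == "hyper").sum())
        n_hypo = int((grp["direction"] == "hypo").sum())
        if n_hyper > n_hypo:
            d = "hyper"
        elif n_hypo > n_hyper:
            d = "hypo"
        else:
            d = "indeterminate"
        rows.append({"gene_id": gid, "meth_direction": d, "n_hyper": n_hyper, "n_hypo": n_hypo})
    return pd.DataFrame(rows)


def bs_methylation_ratio(t: pd.DataFrame) -> pd.DataFrame:
    """Per-site, per-sample methylation percent: 100 * C / (C + T).

    Sites with zero coverage get a missing ratio and are excluded
    downstream.
    """
    out = t.copy()
    total = out["c_count"] + out["t_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = 100.0 * out["c_count"] / total
    out["ratio"] = np.where(total > 0, ratio, np.nan)
    return out


def _pairs_of(df: pd.DataFrame) -> list[tuple[str, str]]:
    pairs = []
    for pid, grp in df.groupby("pair_id"):
        conds = set(grp["condition"])
        if {"tumor", "normal"} <= conds:
            pairs.append(pid)
    return sorted(pairs)


def bs_region_test(
    t: pd.DataFrame,
    grouping: str = "per_site",
    alpha: float = 0.05,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Paired tumor/normal tests on bisulfite methylation ratios.

    ``per_site``: one paired t-test per CG across pairs; ``per_region``:
    pair-wise mean over all sites, one test; ``per_subtype``: the region
    test within each subtype.  Output rows carry mean_diff (tumor -
    normal, percentage points), p_value, significant (p < alpha) and
    direction (hyper when mean_diff > 0).
    """
    ratios = bs_methylation_ratio(t).dropna(subset=["ratio"])

    def _test(sub: pd.DataFrame) -> tuple[float, float, int]:
        wide = sub.pivot_table(index="pair_id", columns="condition", values="ratio", aggfunc="mean")
        wide = wide.dropna(subset=["tumor", "normal"])
        n = len(wide)
        if n < min_pairs:
            warnings.warn(f"fewer than {min_pairs} complete pairs; p set to missing")
            return np.nan, float(wide["tumor"].mean() - wide["normal"].mean()) if n else np.nan, n
        diff = float(wide["tumor"].mean() - wide["normal"].mean())
        return _paired_t(wide["tumor"].to_numpy(), wide["normal"].to_numpy()), diff, n

    rows = []
    if grouping == "per_site":
        for (chrom, pos), sub in ratios.groupby(["chrom", "pos"]):
            p, diff, n = _test(sub)
            rows.append({"chrom": chrom, "pos": pos, "n_pairs": n, "mean_diff": diff, "p_value": p})
    elif grouping == "per_region":
        # pair-wise mean over sites first
        site_means = ratios.groupby(["pair_id", "condition", "sample_id"], as_index=False)["ratio"].mean()
        p, diff, n = _test(site_means)
        rows.append({"region": "all_sites", "n_pairs": n, "mean_diff": diff, "p_value": p})
    elif grouping == "per_subtype":
        for subtype, sub in ratios.groupby("subtype"):
            site_means = sub.groupby(["pair_id", "condition", "sample_id"], as_index=False)["ratio"].mean()
            p, diff, n = _test(site_means)
            rows.append({"subtype": subtype, "n_pairs": n, "mean_diff": diff, "p_value": p})
    else:
        raise ValueError("grouping must be per_site, per_region or per_subtype")
    out = pd.DataFrame(rows)
    out["significant"] = (out["p_value"] < alpha) & np.isfinite(out["p_value"])
    out["direction"] = np.where(out["mean_diff"] > 0, "hyper", "hypo")
    return out
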
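"""Variance-prioritized DMR classification for paired tumor/normal designs.

Each retained bin is scored under two grouping schemes of the same samples:
condition (tumor vs adjacent normal) and histological subtype (e.g. simple /
ductal / complex).  The score is the one-way random-effects between-group
variance component estimated by the ANOVA method of moments on
log2(normalized count + 1):

    sigma_b^2 = max(0, (MSB - MSW) / n0)

with n0 the standard unbalanced-design coefficient
(N - sum n_i^2 / N) / (k - 1).  Ranking uses the noise-standardized
priority MSB / MSW rather than the raw component: the raw component's
sampling noise scales with a bin's total variance, so high-variance bins
would be over-selected under a label-permutation null, while the ratio is
pivotal for null bins (an F statistic) and makes priorities comparable
across bins with different signal levels.  Bins are ranked per scheme in
descending order of the priority; the top fraction q (0.05 strict, 0.10
lenient) of each scheme are DMR candidates.  A bin in only one scheme's top set takes
that class; a bin in both takes the scheme where its percentile rank is
smaller (better priority), with an exact percentile tie going to the
condition class.  Everything else is "none".  The two classes are mutually
exclusive by construction.

Per-DMR statistics use the pairing of the design: condition DMRs get a
paired t-test across (tumor, normal) log2 values and a tumor/normal fold
change; subtype DMRs get a most-extreme-subtype-versus-rest contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from methdiff.binning import BinMatrix

__all__ = [
    "CutoffPolicy",
    "between_group_variance",
    "classification_counts",
    "classify_dmrs",
    "dmr_statistics",
    "group_variance_components",
    "group_variance_priority",
    "hierarchical_clustering",
    "pca_embedding",
    "rank_bins",
    "shuffle_condition_labels",
]


def between_group_variance(values, groups) -> float:
    """One-way random-effects variance component (method of moments).

    Parameters
    ----------
    values
        One observation per sample (log2 scale in pipeline use).
    groups
        Group label per sample; >= 2 distinct labels required.

    Returns
    -------
    max(0, (MSB - MSW) / n0), a non-negative scalar.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("between_group_variance requires at least 2 groups")
    comp = group_variance_components(values[None, :], groups)
    return float(comp[0])


def _anova_mean_squares(values: np.ndarray, groups) -> tuple[np.ndarray, np.ndarray, float]:
    """Row-wise one-way ANOVA: (MSB, MSW, n0) for each bin."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("need >= 2 groups")
    n = values.shape[1]
    sizes = np.array([(groups == g).sum() for g in labels], dtype=float)
    if (sizes < 1).any():
        raise ValueError("every group needs >= 1 observation")
    ind = np.stack([(groups == g).astype(float) for g in labels], axis=1)  # (n, k)
    gmean = (values @ ind) / sizes
    grand = values.mean(axis=1, keepdims=True)
    ssb = ((gmean - grand) ** 2 * sizes).sum(axis=1)
    ssw = (values**2).sum(axis=1) - (gmean**2 * sizes).sum(axis=1)
    msb = ssb / (k - 1)
    dof_w = n - k
    msw = ssw / dof_w if dof_w > 0 else np.zeros_like(msb)
    n0 = (n - (sizes**2).sum() / n) / (k - 1)
    return msb, np.maximum(msw, 0.0), n0


def group_variance_components(values: np.ndarray, groups) -> np.ndarray:
    """Vectorized MoM variance component for many bins at once.

    ``values`` has shape (n_bins, n_samples); returns one component per bin.
    """
    msb, msw, n0 = _anova_mean_squares(values, groups)
    return np.maximum((msb - msw) / n0, 0.0)


def group_variance_priority(values: np.ndarray, groups) -> np.ndarray:
    """Noise-standardized between-group priority MSB / MSW per bin.

    Pivotal for null bins (F-distributed under exchangeable labels), so
    ranking by it is calibrated across bins with unequal signal levels.
    A zero MSW is floored at a tiny epsilon.
    """
    msb, msw, _ = _anova_mean_squares(values, groups)
    return msb / np.maximum(msw, 1e-12)


def rank_bins(m: BinMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Score every bin under both grouping schemes and rank them.

    Returns a table with one row per bin: the MoM variance components
    (var_condition, var_subtype), the noise-standardized priorities
    (priority_condition, priority_subtype) that drive the ranking, dense
    descending ranks (ties broken by genomic order, which is the input
    row order), and percentile ranks rank/n in (0, 1].  Sample order does
    not affect the result.
    """
    for field in ("condition", "subtype"):
        if field not in m.samples.columns or m.samples[field].isna().any():
            bad = m.samples.loc[m.samples.get(field, pd.Series(dtype=str)).isna(), "sample_id"].tolist() \
                if field in m.samples.columns else list(m.samples["sample_id"])
            raise ValueError(f"missing {field} metadata for samples: {bad}")
    values = m.log2_values(pseudocount)
    cond = m.samples["condition"].to_numpy()
    sub = m.samples["subtype"].to_numpy()
    var_c = group_variance_components(values, cond)
    var_s = group_variance_components(values, sub)
    pri_c = group_variance_priority(values, cond)
    pri_s = group_variance_priority(values, sub)
    n = len(var_c)
    out = m.bins[["chrom", "start", "end"]].copy()
    out["bin_id"] = np.arange(n)
    out["var_condition"] = var_c
    out["var_subtype"] = var_s
    out["priority_condition"] = pri_c
    out["priority_subtype"] = pri_s
    for name, v in (("condition", pri_c), ("subtype", pri_s)):
        order = np.argsort(-v, kind="mergesort")  # stable: genomic order breaks ties
        rank = np.empty(n, dtype=np.int64)
        rank[order] = np.arange(1, n + 1)
        out[f"rank_{name}"] = rank
        out[f"pct_{name}"] = rank / n
    return out


def shuffle_condition_labels(
    samples: pd.DataFrame,
    rng: np.random.Generator | int | None = None,
    balanced: bool = True,
) -> pd.DataFrame:
    """Permutation-null sample sheet: swap tumor/normal labels within pairs.

    With ``balanced=True`` (default) exactly half the pairs (rounding
    either way at random) are swapped.  Fully random swaps include
    near-identity assignments under which planted signal genuinely
    survives; balanced swaps guarantee the condition axis is destroyed,
    which is what a calibration check needs in a small paired design.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = samples.copy()
    pairs = sorted(out["pair_id"].unique())
    if balanced:
        k = len(pairs) // 2 + (int(rng.integers(0, 2)) if len(pairs) % 2 else 0)
        swap = set(rng.choice(pairs, size=k, replace=False))
    else:
        swap = {p for p in pairs if rng.random() < 0.5}
    flip = {"tumor": "normal", "normal": "tumor"}
    for pid in swap:
        idx = out.index[out["pair_id"] == pid]
        out.loc[idx, "condition"] = out.loc[idx, "condition"].map(flip)
    return out


@dataclass
class CutoffPolicy:
    """Top-fraction cutoff: q = 0.05 is the strict setting, 0.10 lenient."""

    q: float = 0.05
    scope: str = "both"

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        if self.scope not in ("condition", "subtype", "both"):
            raise ValueError("scope must be condition, subtype or both")


def classify_dmrs(v: pd.DataFrame, policy: CutoffPolicy | float = 0.05) -> pd.DataFrame:
    """Mutually exclusive assignment into condition-DMRs vs subtype-DMRs.

    Candidates are the top ``q`` fraction of bins by each scheme's variance
    component.  A bin selected by exactly one scheme takes that class; one
    selected by both takes the scheme with the smaller percentile rank
    (exact tie -> condition); unselected bins are "none".
    """
    if not isinstance(policy, CutoffPolicy):
        policy = CutoffPolicy(q=float(policy))
    n = len(v)
    k = int(np.floor(policy.q * n))
    if k < 1:
        raise ValueError(f"q*n = {policy.q * n:.3f} < 1: no bins can be selected")
    in_c = v["rank_condition"].to_numpy() <= k
    in_s = v["rank_subtype"].to_numpy() <= k
    if policy.scope == "condition":
        in_s = np.zeros(n, dtype=bool)
    elif policy.scope == "subtype":
        in_c = np.zeros(n, dtype=bool)
    cls = np.full(n, "none", dtype=object)
    cls[in_c & ~in_s] = "condition"
    cls[in_s & ~in_c] = "subtype"
    both = in_c & in_s
    pc = v["pct_condition"].to_numpy()
    ps = v["pct_subtype"].to_numpy()
    cls[both & (pc <= ps)] = "condition"
    cls[both & (pc > ps)] = "subtype"
    out = v.copy()
    out["dmr_class"] = cls
    out["cutoff_used"] = policy.q
    return out


def classification_counts(records: pd.DataFrame) -> dict:
    """Counts report: bins per class and the combined DMR total."""
    n_condition = int((records["dmr_class"] == "condition").sum())
    n_subtype = int((records["dmr_class"] == "subtype").sum())
    return {
        "n_condition": n_condition,
        "n_subtype": n_subtype,
        "n_dmr_total": n_condition + n_subtype,
        "n_none": int((records["dmr_class"] == "none").sum()),
        "n_bins": int(len(records)),
    }


def _log2_ratio_of_means(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    """log2(mean_a / mean_b); a pseudocount of 1 is added to both means
    only when either is zero, keeping the noise-free ratio exact."""
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    zero = (mean_a <= 0) | (mean_b <= 0)
    a = np.where(zero, mean_a + 1.0, mean_a)
    b = np.where(zero, mean_b + 1.0, mean_b)
    return np.log2(a / b)


def dmr_statistics(
    m: BinMatrix,
    records: pd.DataFrame,
    pseudocount: float = 1.0,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Attach direction, fold change and p/q-values to classified bins.

    Condition DMRs: paired t-test of tumor vs normal log2 values across
    pairs; log2fc of tumor vs normal mean normalized counts; direction
    hyper iff log2fc > 0.  Subtype DMRs: the most extreme subtype (largest
    absolute mean contrast vs the rest on the log2 scale) is tested against
    the remaining samples with Welch's t-test.  Benjamini-Hochberg
    adjustment is applied within each class.
    """
    from statsmodels.stats.multitest import multipletests

    rec = records.copy()
    values = m.log2_values(pseudocount)
    t_idx, n_idx, pairs = m.paired_columns()
    counts = m.counts

    log2fc = np.zeros(len(rec))
    pvals = np.full(len(rec), np.nan)
    direction = np.array(["none"] * len(rec), dtype=object)
    extreme_subtype = np.array([""] * len(rec), dtype=object)

    cond_rows = np.flatnonzero((rec["dmr_class"] == "condition").to_numpy())
    if len(cond_rows):
        bin_ids = rec["bin_id"].to_numpy()[cond_rows]
        tum = values[np.ix_(bin_ids, t_idx)]
        nor = values[np.ix_(bin_ids, n_idx)]
        if len(pairs) < min_pairs:
            warnings.warn(f"fewer than {min_pairs} complete pairs; p-values set to missing")
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                res = stats.ttest_rel(tum, nor, axis=1)
            p = np.asarray(res.pvalue)
            p[~np.isfinite(p)] = 1.0  # zero-variance differences: no evidence
            pvals[cond_rows] = p
        fc = _log2_ratio_of_means(counts[np.ix_(bin_ids, t_idx)].mean(axis=1),
                                  counts[np.ix_(bin_ids, n_idx)].mean(axis=1))
        log2fc[cond_rows] = fc
        direction[cond_rows] = np.where(fc > 0, "hyper", "hypo")

    sub_rows = np.flatnonzero((rec["dmr_class"] == "subtype").to_numpy())
    if len(sub_rows):
        bin_ids = rec["bin_id"].to_numpy()[sub_rows]
        subtypes = pd.unique(m.samples["subtype"])
        cols_by_sub = {s: m.sample_index(subtype=s) for s in subtypes}
        vals = values[bin_ids]
        # contrast per subtype: mean(subtype) - mean(rest), pick the extreme
        contrasts = np.stack(
            [
                vals[:, cols_by_sub[s]].mean(axis=1)
                - vals[:, np.setdiff1d(np.arange(m.n_samples), cols_by_sub[s])].mean(axis=1)
                for s in subtypes
            ],
            axis=1,
        )
        best = np.abs(contrasts).argmax(axis=1)
        for i, (row, bin_id) in enumerate(zip(sub_rows, bin_ids)):
            s = subtypes[best[i]]
            cols = cols_by_sub[s]
            rest = np.setdiff1d(np.arange(m.n_samples), cols)
            with np.errstate(invalid="ignore", divide="ignore"):
                res = stats.ttest_ind(values[bin_id, cols], values[bin_id, rest], equal_var=False)
            p = float(res.pvalue)
            pvals[row] = 1.0 if not np.isfinite(p) else p
            fc = float(
                _log2_ratio_of_means(counts[bin_id, cols].mean(), counts[bin_id, rest].mean())
            )
            log2fc[row] = fc
            direction[row] = "hyper" if fc > 0 else "hypo"
            extreme_subtype[row] = s

    rec["log2fc"] = log2fc
    rec["direction"] = direction
    rec["p_value"] = pvals
    rec["extreme_subtype"] = extreme_subtype
    qvals = np.full(len(rec), np.nan)
    for rows in (cond_rows, sub_rows):
        ok = rows[np.isfinite(pvals[rows])] if len(rows) else rows
        if len(ok):
            qvals[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    rec["q_value"] = qvals
    return rec


def pca_embedding(
    m: BinMatrix,
    records: pd.DataFrame,
    dmr_class: str = "condition",
    n_components: int = 2,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project the samples on principal components of the selected DMR
    submatrix (bins standardized across samples).

    Returns (coordinates DataFrame indexed by sample_id with PC columns,
    explained-variance-ratio array).
    """
    bin_ids = records.loc[records["dmr_class"] == dmr_class, "bin_id"].to_numpy()
    if len(bin_ids) == 0:
        raise ValueError(f"no bins of class {dmr_class!r}")
    x = m.log2_values(pseudocount)[bin_ids]  # (bins, samples)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = ((x - mu) / sd).T  # samples x bins
    k = min(n_components, z.shape[0] - 1, z.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(z)
    df = pd.DataFrame(
        coords,
        index=list(m.samples["sample_id"]),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return df, pca.explained_variance_ratio_


def hierarchical_clustering(
    m: BinMatrix,
    records: pd.DataFrame,
    dmr_class: str = "condition",
    method: str = "average",
    metric: str = "euclidean",
    pseudocount: float = 1.0,
):
    """Agglomerative clustering of samples over z-scored DMR rows.

    Returns a dict with the scipy linkage matrix, leaf order (sample ids),
    and a Newick string of the tree.
    """
    bin_ids = records.loc[records["dmr_class"] == dmr_class, "bin_id"].to_numpy()
    if len(bin_ids) == 0:
        raise ValueError(f"no bins of class {dmr_class!r}")
    x = m.log2_values(pseudocount)[bin_ids]
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = ((x - mu) / sd).T  # samples x bins
    link = hierarchy.linkage(z, method=method, metric=metric)
    ids = list(m.samples["sample_id"])
    order = [ids[i] for i in hierarchy.leaves_list(link)]
    tree = hierarchy.to_tree(link)

    def _newick(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        left = _newick(node.left, node.dist)
        right = _newick(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    newick = f"({_newick(tree.left, tree.dist)},{_newick(tree.right, tree.dist)});"
    return {"linkage": link, "leaf_order": order, "newick": newick}
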
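"""Synthetic data with planted ground truth for the whole pipeline.

The generator emulates the statistical structure the analysis assumes: a
paired tumor/normal MBD-seq design (11 pairs in three histological
subtypes, 4/4/3), negative-binomial bin counts with per-sample library
scale jitter, planted condition-effect and subtype-effect bins, random
genomes whose genes have promoters/exons/introns with CpG islands and
repeats, motif instances planted into hypermethylated intron DMR bins,
expression anti-correlated with planted gene methylation, and per-CG
bisulfite C/T counts.

All generators are pure functions of (config, seed): the master seed
spawns a fixed per-stage stream, so each stage is independently
reproducible.  One chromosome is named "chrX" and never receives planted
effects, exercising the sex-chromosome filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from methdiff.annotation import GenomeAnnotation
from methdiff.binning import BinMatrix, make_bins

__all__ = [
    "GroundTruth",
    "SimConfig",
    "sample_sheet",
    "simulate_bs_counts",
    "simulate_counts",
    "simulate_expression",
    "simulate_genome",
    "simulate_sequences",
]

# fixed per-stage rng streams derived from the master seed
_STAGE = {"genome": 1, "counts": 2, "sequences": 3, "expression": 4, "bs": 5}

PAX5_CONSENSUS = "GCAGCCAAGCGTGACC"


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    The defaults are the conditions the analysis is designed for: 11
    tumor/normal pairs split 4/4/3 across simple/ductal/complex subtypes,
    500-bp windows, negative-binomial counts around a mean of 50 with
    moderate overdispersion, 200 planted condition bins and 200 planted
    subtype bins at a log2 effect of 1.5, two thirds of planted condition
    bins hypermethylated.
    """

    n_pairs: int = 11
    subtype_sizes: dict = field(default_factory=lambda: {"simple": 4, "ductal": 4, "complex": 3})
    n_chromosomes: int = 4  # last one is chrX
    chrom_length: int = 2_500_000
    window: int = 500
    n_genes: int = 150
    nb_mean: float = 50.0
    nb_dispersion: float = 10.0  # NB size parameter; larger = less overdispersed
    bin_mean_sigma: float = 0.5  # log-normal spread of per-bin baseline means
    libsize_sigma: float = 0.2  # log-normal spread of per-sample scale factors
    n_cmt_dmrs: int = 200
    n_subtype_dmrs: int = 200
    effect_log2fc: float = 1.5
    frac_hyper: float = 0.66
    frac_cmt_in_introns: float = 0.5
    frac_anticorrelated: float = 0.8
    expr_effect_log2fc: float = 2.0
    expr_baseline_fpkm: float = 10.0
    expr_sigma: float = 0.4
    motif_consensus: str = PAX5_CONSENSUS
    motif_plant_rate_target: float = 0.30
    motif_plant_rate_background: float = 0.05
    bs_n_sites: int = 16
    bs_n_planted: int = 12
    bs_n_pairs: int = 14
    bs_depth: int = 1000
    bs_baseline: float = 0.4
    bs_shift: float = 0.3
    bs_sample_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if sum(self.subtype_sizes.values()) != self.n_pairs:
            raise ValueError("subtype sizes must sum to n_pairs")
        for name in ("frac_hyper", "frac_cmt_in_introns", "frac_anticorrelated",
                     "motif_plant_rate_target", "motif_plant_rate_background"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_chromosomes < 2:
            raise ValueError("need at least one autosome plus chrX")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STAGE[stage]])

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes - 1)] + ["chrX"]


@dataclass
class GroundTruth:
    """Planted effects: where they are and what direction they have."""

    cmt_dmr_bins: pd.DataFrame  # bin_id, chrom, start, end, direction, intron_gene
    subtype_dmr_bins: pd.DataFrame  # bin_id, chrom, start, end, subtype, direction
    anticorrelated_genes: pd.DataFrame  # gene_id, direction (of methylation)
    gene_ids: list


def sample_sheet(cfg: SimConfig) -> pd.DataFrame:
    """The paired design: one tumor and one normal sample per pair, pairs
    assigned to subtypes in the configured block sizes."""
    rows = []
    i = 0
    for subtype, k in cfg.subtype_sizes.items():
        for _ in range(k):
            i += 1
            pid = f"P{i:02d}"
            rows.append({"sample_id": f"{pid}T", "pair_id": pid, "condition": "tumor", "subtype": subtype})
            rows.append({"sample_id": f"{pid}N", "pair_id": pid, "condition": "normal", "subtype": subtype})
    return pd.DataFrame(rows)


def simulate_genome(cfg: SimConfig) -> GenomeAnnotation:
    """Random gene models, CpG islands and repeats on cfg.n_chromosomes
    chromosomes (the last named chrX).

    Genes are laid head-to-tail with random intergenic gaps; each gene has
    3-8 exons so introns always exist.  CGIs cover ~60% of promoters plus
    occasional intragenic islands; repeats occupy a fraction of intergenic
    gaps.  Raises if the chromosomes cannot hold the requested gene count.
    """
    rng = cfg.rng("genome")
    chroms = cfg.chrom_names
    sizes = pd.Series({c: cfg.chrom_length for c in chroms})
    per_chrom = np.full(len(chroms), cfg.n_genes // len(chroms))
    per_chrom[: cfg.n_genes % len(chroms)] += 1

    genes, exons, cgis, repeats = [], [], [], []
    gi = 0
    for chrom, n_target in zip(chroms, per_chrom):
        pos = int(rng.integers(2000, 6000))
        placed = 0
        while placed < n_target:
            n_ex = int(rng.integers(3, 9))
            ex_lens = rng.integers(150, 1200, size=n_ex)
            in_lens = rng.integers(800, 6000, size=n_ex - 1)
            glen = int(ex_lens.sum() + in_lens.sum())
            if pos + glen + 2000 > cfg.chrom_length:
                break
            gid = f"gene{gi:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            start = pos
            end = pos + glen
            genes.append({"gene_id": gid, "chrom": chrom, "strand": strand, "start": start, "end": end})
            p = start
            for j in range(n_ex):
                exons.append({"gene_id": gid, "start": p, "end": p + int(ex_lens[j])})
                p += int(ex_lens[j])
                if j < n_ex - 1:
                    p += int(in_lens[j])
            tss = start if strand == "+" else end
            if rng.random() < 0.6:
                cgis.append({"chrom": chrom, "start": max(tss - 500, 0), "end": tss + 500})
            if rng.random() < 0.2:  # intragenic island
                c = int(rng.integers(start, end - 300))
                cgis.append({"chrom": chrom, "start": c, "end": c + 300})
            gap = int(rng.integers(3000, 12000))
            if rng.random() < 0.5:
                rstart = end + int(rng.integers(200, max(gap - 1200, 400)))
                repeats.append({"chrom": chrom, "start": rstart, "end": rstart + int(rng.integers(200, 1000))})
            pos = end + gap
            gi += 1
            placed += 1
        if placed < n_target:
            raise ValueError(
                f"chromosome {chrom} (length {cfg.chrom_length}) too short for "
                f"{n_target} genes; placed {placed}"
            )
    return GenomeAnnotation(
        chrom_sizes=sizes,
        genes=pd.DataFrame(genes),
        exons=pd.DataFrame(exons),
        cgis=pd.DataFrame(cgis, columns=["chrom", "start", "end"]),
        repeats=pd.DataFrame(repeats, columns=["chrom", "start", "end"]),
    )


def _intron_bin_ids(cfg: SimConfig, annotation: GenomeAnnotation, bins: pd.DataFrame) -> pd.DataFrame:
    """Bins fully inside an intron of an autosomal gene."""
    introns = annotation.introns()
    introns = introns[introns["chrom"] != "chrX"]
    rows = []
    by_chrom = {c: g.sort_values("start") for c, g in introns.groupby("chrom")}
    starts = bins["start"].to_numpy()
    for chrom, grp in by_chrom.items():
        mask = (bins["chrom"] == chrom).to_numpy()
        ids = np.flatnonzero(mask)
        s = starts[ids]
        for _, iv in grp.iterrows():
            inside = ids[(s >= iv["start"]) & (s + cfg.window <= iv["end"])]
            for b in inside:
                rows.append({"bin_id": int(b), "gene_id": iv["gene_id"]})
    df = pd.DataFrame(rows, columns=["bin_id", "gene_id"])
    return df.drop_duplicates(subset="bin_id")


def simulate_counts(cfg: SimConfig, annotation: GenomeAnnotation) -> tuple[BinMatrix, GroundTruth]:
    """Negative-binomial bin counts with planted effects.

    Per-bin baseline means are log-normal around ``nb_mean``; per-sample
    library factors are log-normal (sigma ``libsize_sigma``), which makes
    quantile normalization non-trivial.  Planted condition bins shift the
    tumor mean by 2**(+/- effect_log2fc) in every pair; planted subtype
    bins shift both members of every pair of one subtype.  chrX gets no
    planted effects.
    """
    rng = cfg.rng("counts")
    bins = make_bins(annotation.chrom_sizes, cfg.window)
    samples = sample_sheet(cfg)
    n_bins, n_samp = len(bins), len(samples)
    autosomal = np.flatnonzero((bins["chrom"] != "chrX").to_numpy())
    if cfg.n_cmt_dmrs + cfg.n_subtype_dmrs > len(autosomal):
        raise ValueError(
            f"requested {cfg.n_cmt_dmrs + cfg.n_subtype_dmrs} planted bins but only "
            f"{len(autosomal)} autosomal bins exist"
        )

    intron_bins = _intron_bin_ids(cfg, annotation, bins)
    n_intron_planted = min(int(round(cfg.n_cmt_dmrs * cfg.frac_cmt_in_introns)), len(intron_bins))
    chosen_intron = rng.choice(intron_bins["bin_id"].to_numpy(), size=n_intron_planted, replace=False) \
        if n_intron_planted else np.array([], dtype=int)
    remaining = np.setdiff1d(autosomal, chosen_intron)
    chosen_other = rng.choice(remaining, size=cfg.n_cmt_dmrs - n_intron_planted, replace=False)
    cmt_ids = np.concatenate([chosen_intron, chosen_other]).astype(int)
    rng.shuffle(cmt_ids)
    n_hyper = int(round(cfg.frac_hyper * len(cmt_ids)))
    directions = np.array(["hyper"] * n_hyper + ["hypo"] * (len(cmt_ids) - n_hyper))
    rng.shuffle(directions)

    remaining = np.setdiff1d(autosomal, cmt_ids)
    sub_ids = rng.choice(remaining, size=cfg.n_subtype_dmrs, replace=False).astype(int)
    subtypes = list(cfg.subtype_sizes)
    sub_assign = np.array(subtypes)[rng.integers(0, len(subtypes), size=len(sub_ids))]
    sub_dir = np.where(rng.random(len(sub_ids)) < 0.5, "hyper", "hypo")

    # mean matrix
    mu_bin = cfg.nb_mean * rng.lognormal(0.0, cfg.bin_mean_sigma, size=n_bins)
    lib = rng.lognormal(0.0, cfg.libsize_sigma, size=n_samp)
    mu = np.outer(mu_bin, lib)
    eff = 2.0 ** cfg.effect_log2fc
    tumor_cols = np.flatnonzero((samples["condition"] == "tumor").to_numpy())
    for b, d in zip(cmt_ids, directions):
        mu[b, tumor_cols] *= eff if d == "hyper" else 1.0 / eff
    for b, s, d in zip(sub_ids, sub_assign, sub_dir):
        cols = np.flatnonzero((samples["subtype"] == s).to_numpy())
        mu[b, cols] *= eff if d == "hyper" else 1.0 / eff

    r = cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(float)

    intron_map = intron_bins.set_index("bin_id")["gene_id"]
    cmt_df = bins.iloc[cmt_ids][["chrom", "start", "end"]].copy()
    cmt_df.insert(0, "bin_id", cmt_ids)
    cmt_df["direction"] = directions
    cmt_df["intron_gene"] = [intron_map.get(b, "") for b in cmt_ids]
    cmt_df = cmt_df.reset_index(drop=True)

    sub_df = bins.iloc[sub_ids][["chrom", "start", "end"]].copy()
    sub_df.insert(0, "bin_id", sub_ids)
    sub_df["subtype"] = sub_assign
    sub_df["direction"] = sub_dir
    sub_df = sub_df.reset_index(drop=True)

    # genes owning planted intron bins -> candidate anti-correlated genes
    gene_dirs: dict[str, str] = {}
    for _, row in cmt_df.iterrows():
        if row["intron_gene"]:
            gene_dirs.setdefault(row["intron_gene"], row["direction"])
    gene_list = sorted(gene_dirs)
    n_ac = int(round(cfg.frac_anticorrelated * len(gene_list)))
    ac_genes = list(rng.choice(gene_list, size=n_ac, replace=False)) if n_ac else []
    ac_df = pd.DataFrame(
        {"gene_id": ac_genes, "direction": [gene_dirs[g] for g in ac_genes]},
        columns=["gene_id", "direction"],
    )

    truth = GroundTruth(
        cmt_dmr_bins=cmt_df,
        subtype_dmr_bins=sub_df,
        anticorrelated_genes=ac_df,
        gene_ids=list(annotation.genes["gene_id"]),
    )
    return BinMatrix(bins=bins, samples=samples, counts=counts), truth


def simulate_sequences(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    cfg: SimConfig,
) -> dict[str, str]:
    """Uniform-random chromosome sequences with the motif consensus planted
    into hypermethylated intron condition-DMR bins at the target rate and
    into every other bin at the background rate.

    Planted instances land at a random in-bin offset on a random strand.
    Raises if the motif is longer than the window.
    """
    from methdiff.motifs import reverse_complement

    motif = cfg.motif_consensus.upper()
    if len(motif) > cfg.window:
        raise ValueError("motif longer than the bin window")
    rng = cfg.rng("sequences")
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs: dict[str, np.ndarray] = {}
    for chrom in cfg.chrom_names:
        size = int(annotation.chrom_sizes[chrom])
        seqs[chrom] = bases[rng.integers(0, 4, size=size)].copy()

    bins = make_bins(annotation.chrom_sizes, cfg.window)
    target_mask = np.zeros(len(bins), dtype=bool)
    t = truth.cmt_dmr_bins
    target_ids = t.loc[(t["direction"] == "hyper") & (t["intron_gene"] != ""), "bin_id"].to_numpy()
    target_mask[target_ids] = True

    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    chroms = bins["chrom"].to_numpy()
    w = len(motif)
    motif_fwd = np.frombuffer(motif.encode(), dtype=np.uint8)
    motif_rev = np.frombuffer(reverse_complement(motif).encode(), dtype=np.uint8)
    for i in range(len(bins)):
        rate = cfg.motif_plant_rate_target if target_mask[i] else cfg.motif_plant_rate_background
        if rng.random() >= rate:
            continue
        width = ends[i] - starts[i]
        if width < w:
            continue
        off = int(rng.integers(0, width - w + 1))
        ins = motif_fwd if rng.random() < 0.5 else motif_rev
        arr = seqs[chroms[i]]
        arr[starts[i] + off : starts[i] + off + w] = ins
    return {c: a.tobytes().decode() for c, a in seqs.items()}


def simulate_expression(
    truth: GroundTruth,
    cfg: SimConfig,
    samples: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Gene x sample FPKM table with expression shifted opposite to the
    planted methylation direction in the anti-correlated genes.

    Baseline FPKM is log-normal around ``expr_baseline_fpkm`` per gene with
    log-normal per-sample noise; hypermethylated anti-correlated genes are
    downshifted in tumors by 2**expr_effect_log2fc (hypomethylated genes
    upshifted).  Values are non-negative by construction.
    """
    rng = cfg.rng("expression")
    samples = sample_sheet(cfg) if samples is None else samples
    gene_ids = truth.gene_ids
    n_g, n_s = len(gene_ids), len(samples)
    base = cfg.expr_baseline_fpkm * rng.lognormal(0.0, 1.0, size=n_g)
    noise = rng.lognormal(0.0, cfg.expr_sigma, size=(n_g, n_s))
    fpkm = base[:, None] * noise
    tumor_cols = np.flatnonzero((samples["condition"] == "tumor").to_numpy())
    shift = 2.0 ** cfg.expr_effect_log2fc
    ac = truth.anticorrelated_genes.set_index("gene_id")["direction"]
    for i, gid in enumerate(gene_ids):
        if gid in ac.index:
            mult = 1.0 / shift if ac.loc[gid] == "hyper" else shift
            fpkm[i, tumor_cols] *= mult
    return pd.DataFrame(fpkm, index=pd.Index(gene_ids, name="gene_id"),
                        columns=list(samples["sample_id"]))


def simulate_bs_counts(
    cfg: SimConfig,
    region: tuple[str, int] = ("chr1", 100_000),
    planted_sites: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-CG bisulfite C/T counts for a targeted validation amplicon.

    ``bs_n_sites`` CG positions are spaced along the amplicon;
    ``bs_n_planted`` of them get a tumor methylation probability raised by
    ``bs_shift`` above the shared baseline.  Per-sample biological noise
    (sd ``bs_sample_sigma`` on the probability scale) sits on top; C
    counts are binomial out of ``bs_depth`` reads.

    Returns (long-format table with chrom, pos, sample_id, pair_id,
    condition, subtype, c_count, t_count; array of planted positions).
    """
    rng = cfg.rng("bs")
    chrom, start = region
    positions = start + 25 * np.arange(cfg.bs_n_sites)
    if planted_sites is None:
        planted_sites = rng.choice(cfg.bs_n_sites, size=cfg.bs_n_planted, replace=False)
    planted_sites = np.sort(np.asarray(planted_sites))
    subtypes = list(cfg.subtype_sizes)
    rows = []
    site_base = np.clip(cfg.bs_baseline + rng.normal(0, 0.05, size=cfg.bs_n_sites), 0.05, 0.95)
    for i in range(cfg.bs_n_pairs):
        pid = f"V{i + 1:02d}"
        subtype = subtypes[i % len(subtypes)]
        for condition in ("tumor", "normal"):
            sid = f"{pid}{'T' if condition == 'tumor' else 'N'}"
            for j in range(cfg.bs_n_sites):
                p = site_base[j]
                if condition == "tumor" and j in planted_sites:
                    p = p + cfg.bs_shift
                p = float(np.clip(p + rng.normal(0, cfg.bs_sample_sigma), 0.0, 1.0))
                c = int(rng.binomial(cfg.bs_depth, p))
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": int(positions[j]),
                        "sample_id": sid,
                        "pair_id": pid,
                        "condition": condition,
                        "subtype": subtype,
                        "c_count": c,
                        "t_count": cfg.bs_depth - c,
                    }
                )
    return pd.DataFrame(rows), positions[planted_sites]
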
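"""Genomic-feature annotation of bins and DMG categorization.

Gene models provide strand-aware promoters ([TSS-1500, TSS+500) by
default), exons, introns (transcript minus exons) and a TTS window
(TES +/- 500).  CpG islands define shores (+/- 2 kb flanks minus any CGI).
A bin is labeled with every genic feature it overlaps by >= 1 bp
(multi-label, no precedence), a single CGI class with precedence
CGI > shore > nonCGI, a repeat flag, and its nearest gene by
midpoint-to-TSS distance.

Genes hit by condition-DMRs (differentially methylated genes, DMGs) are
categorized by the subset of {promoter, exon, intron} their DMRs occupy:
the seven non-empty subsets P, E, I, PE, PI, EI, PEI (canonical letter
order P < E < I).  A TTS-only hit keeps the gene in the DMG list but
contributes no letter; such genes are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomeAnnotation",
    "annotate_bins",
    "composition_summary",
    "derive_features",
    "group_dmgs",
    "group_percentage_rollup",
    "read_bed",
    "write_bed",
]

GROUP_ORDER = ["I", "EI", "P", "E", "PI", "PEI", "PE"]


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    return df[["chrom", "start", "end"]]


def write_bed(df: pd.DataFrame, path: str | Path, extra_cols: Iterable[str] = ()) -> None:
    cols = ["chrom", "start", "end", *extra_cols]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


@dataclass
class GenomeAnnotation:
    """Chromosome sizes, gene models, CpG islands and repeats.

    genes: DataFrame with gene_id, chrom, strand (+/-), start, end.
    exons: DataFrame with gene_id, start, end (sorted, non-overlapping
    within a gene, inside the transcript bounds).
    cgis / repeats: interval DataFrames with chrom, start, end.
    """

    chrom_sizes: pd.Series
    genes: pd.DataFrame
    exons: pd.DataFrame
    cgis: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"]))
    repeats: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"]))

    def __post_init__(self) -> None:
        bad = set(self.genes["strand"]) - {"+", "-"}
        if bad:
            raise ValueError(f"unknown strand values: {sorted(bad)}")
        for gid, grp in self.exons.groupby("gene_id"):
            ex = grp.sort_values("start")
            if (ex["start"].to_numpy()[1:] < ex["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping exons in gene {gid}")

    def introns(self) -> pd.DataFrame:
        """Transcript minus exons, per gene."""
        rows = []
        gene_idx = self.genes.set_index("gene_id")
        for gid, grp in self.exons.groupby("gene_id"):
            ex = grp.sort_values("start")
            g = gene_idx.loc[gid]
            prev_end = None
            for _, e in ex.iterrows():
                if prev_end is not None and e["start"] > prev_end:
                    rows.append({"gene_id": gid, "chrom": g["chrom"], "start": prev_end, "end": e["start"]})
                prev_end = e["end"]
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def _clip(df: pd.DataFrame, chrom_sizes: pd.Series) -> pd.DataFrame:
    df = df.copy()
    sizes = df["chrom"].map(chrom_sizes)
    df["start"] = np.maximum(df["start"], 0)
    df["end"] = np.minimum(df["end"], sizes)
    return df[df["end"] > df["start"]].reset_index(drop=True)


def derive_features(
    a: GenomeAnnotation,
    promoter_up: int = 1500,
    promoter_down: int = 500,
    tts_flank: int = 500,
    shore_width: int = 2000,
) -> dict:
    """Build the feature interval tables used by :func:`annotate_bins`.

    Promoter = [TSS - up, TSS + down) in the transcription direction; the
    TTS window is [TES - flank, TES + flank); introns complement exons
    within the transcript; shores are CGI +/- ``shore_width`` minus the
    CGI union.  All intervals are clipped to chromosome bounds.

    Returns a dict of DataFrames: promoter, exon, intron, tts (each with
    gene_id, chrom, start, end), cgi, shore, repeat.
    """
    genes = a.genes
    plus = genes["strand"] == "+"
    tss = np.where(plus, genes["start"], genes["end"])
    tes = np.where(plus, genes["end"], genes["start"])
    prom = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "chrom": genes["chrom"],
            "start": np.where(plus, tss - promoter_up, tss - promoter_down),
            "end": np.where(plus, tss + promoter_down, tss + promoter_up),
        }
    )
    tts = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "chrom": genes["chrom"],
            "start": tes - tts_flank,
            "end": tes + tts_flank,
        }
    )
    exon = a.exons.merge(genes[["gene_id", "chrom"]], on="gene_id")[["gene_id", "chrom", "start", "end"]]
    intron = a.introns()

    cgi = a.cgis.copy()
    shore_rows = []
    cgi_trees = _build_trees(cgi)
    for _, c in cgi.iterrows():
        for s, e in ((c["start"] - shore_width, c["start"]), (c["end"], c["end"] + shore_width)):
            if e <= s:
                continue
            shore_rows.append({"chrom": c["chrom"], "start": s, "end": e})
    shore = pd.DataFrame(shore_rows, columns=["chrom", "start", "end"])
    # subtract the CGI union from shores
    if len(shore) and len(cgi):
        kept = []
        for _, r in shore.iterrows():
            pieces = [(r["start"], r["end"])]
            tree = cgi_trees.get(r["chrom"])
            if tree is not None:
                for iv in sorted(tree.overlap(r["start"], r["end"])):
                    new = []
                    for s, e in pieces:
                        if iv.end <= s or iv.begin >= e:
                            new.append((s, e))
                        else:
                            if s < iv.begin:
                                new.append((s, iv.begin))
                            if iv.end < e:
                                new.append((iv.end, e))
                    pieces = new
            for s, e in pieces:
                kept.append({"chrom": r["chrom"], "start": s, "end": e})
        shore = pd.DataFrame(kept, columns=["chrom", "start", "end"])

    sizes = a.chrom_sizes
    return {
        "promoter": _clip(prom, sizes),
        "exon": _clip(exon, sizes),
        "intron": _clip(intron, sizes),
        "tts": _clip(tts, sizes),
        "cgi": _clip(cgi, sizes),
        "shore": _clip(shore, sizes),
        "repeat": _clip(a.repeats.copy(), sizes),
        "tss_table": pd.DataFrame({"gene_id": genes["gene_id"], "chrom": genes["chrom"], "tss": tss}),
    }


def _build_trees(df: pd.DataFrame, id_col: str | None = None) -> dict:
    trees: dict = {}
    for _, r in df.iterrows():
        if r["end"] <= r["start"]:
            continue
        tree = trees.setdefault(r["chrom"], IntervalTree())
        tree.addi(int(r["start"]), int(r["end"]), r[id_col] if id_col else None)
    return trees


def annotate_bins(bins: pd.DataFrame, features: dict, known_chroms: Iterable[str] | None = None) -> pd.DataFrame:
    """Annotate intervals with genic features, CGI class, repeat flag and
    nearest gene.

    ``bins`` needs chrom/start/end columns (a DMR record table works); the
    result preserves all input columns and adds: genic_features (sorted
    comma-joined subset of promoter,exon,intron,tts), feature gene-id
    columns (promoter_genes, ...), intergenic flag, cgi_class in
    {CGI, shore, nonCGI}, repeat_flag, nearest_gene and
    nearest_gene_distance (signed, bin midpoint minus TSS).
    """
    if known_chroms is not None:
        unknown = sorted(set(bins["chrom"]) - set(known_chroms))
        if unknown:
            raise ValueError(f"unknown chromosomes: {unknown}")
    genic_names = ("promoter", "exon", "intron", "tts")
    trees = {name: _build_trees(features[name], id_col="gene_id") for name in genic_names}
    cgi_trees = _build_trees(features["cgi"])
    shore_trees = _build_trees(features["shore"])
    rep_trees = _build_trees(features["repeat"])
    tss = features["tss_table"]

    out_rows = []
    for _, b in bins.iterrows():
        chrom, s, e = b["chrom"], int(b["start"]), int(b["end"])
        row = {}
        hit_features = []
        for name in genic_names:
            tree = trees[name].get(chrom)
            genes = sorted({iv.data for iv in tree.overlap(s, e)}) if tree is not None else []
            row[f"{name}_genes"] = ",".join(genes)
            if genes:
                hit_features.append(name)
        row["genic_features"] = ",".join(hit_features)
        row["intergenic"] = not hit_features
        if chrom in cgi_trees and cgi_trees[chrom].overlap(s, e):
            row["cgi_class"] = "CGI"
        elif chrom in shore_trees and shore_trees[chrom].overlap(s, e):
            row["cgi_class"] = "shore"
        else:
            row["cgi_class"] = "nonCGI"
        row["repeat_flag"] = bool(chrom in rep_trees and rep_trees[chrom].overlap(s, e))
        cand = tss[tss["chrom"] == chrom]
        if len(cand):
            mid = (s + e) // 2
            dist = mid - cand["tss"].to_numpy()
            order = np.lexsort((cand["gene_id"].to_numpy(), np.abs(dist)))
            best = order[0]
            row["nearest_gene"] = cand["gene_id"].to_numpy()[best]
            row["nearest_gene_distance"] = int(dist[best])
        else:
            row["nearest_gene"] = ""
            row["nearest_gene_distance"] = np.nan
        out_rows.append(row)
    ann = pd.DataFrame(out_rows, index=bins.index)
    return pd.concat([bins, ann], axis=1)


def group_dmgs(calls: pd.DataFrame, dmr_class: str = "condition") -> pd.DataFrame:
    """Categorize DMGs by the {promoter, exon, intron} subsets their DMRs hit.

    ``calls`` is an annotated DMR table (output of :func:`annotate_bins`
    on classified records).  Only rows of ``dmr_class`` contribute.  The
    group string concatenates the letters P, E, I (in that order) for the
    features present anywhere among the gene's DMRs; genes whose DMRs touch
    only the TTS get group "TTS_only".

    Returns a table with gene_id, group, n_dmrs, and per-feature DMR counts.
    """
    rows = calls[calls["dmr_class"] == dmr_class] if "dmr_class" in calls.columns else calls
    per_gene: dict[str, dict] = {}
    letter = {"promoter": "P", "exon": "E", "intron": "I"}
    for idx, r in rows.iterrows():
        for feature in ("promoter", "exon", "intron", "tts"):
            genes = r.get(f"{feature}_genes", "")
            if not isinstance(genes, str) or not genes:
                continue
            for gid in genes.split(","):
                d = per_gene.setdefault(gid, {"features": set(), "dmr_ids": set(), "n_per": {}})
                d["dmr_ids"].add(idx)
                d["features"].add(feature)
                d["n_per"][feature] = d["n_per"].get(feature, 0) + 1
    out = []
    for gid, d in sorted(per_gene.items()):
        letters = "".join(letter[f] for f in ("promoter", "exon", "intron") if f in d["features"])
        out.append(
            {
                "gene_id": gid,
                "group": letters if letters else "TTS_only",
                "n_dmrs": len(d["dmr_ids"]),
                "n_promoter": d["n_per"].get("promoter", 0),
                "n_exon": d["n_per"].get("exon", 0),
                "n_intron": d["n_per"].get("intron", 0),
                "n_tts": d["n_per"].get("tts", 0),
            }
        )
    return pd.DataFrame(out, columns=["gene_id", "group", "n_dmrs", "n_promoter", "n_exon", "n_intron", "n_tts"])


def group_percentage_rollup(per_group: Mapping[str, float]) -> dict:
    """Sum per-group percentages by feature membership.

    Given a mapping of DMG group labels (subsets of P/E/I) to percentages,
    return the total percentage of groups containing each feature letter —
    e.g. intron-containing = I + EI + PI + PEI.  This is the roll-up used
    when comparing how many cancer-pathway DMGs involve intron vs promoter
    vs exon DMRs.
    """
    out = {"promoter_containing": 0.0, "exon_containing": 0.0, "intron_containing": 0.0}
    for group, pct in per_group.items():
        if "P" in group:
            out["promoter_containing"] += pct
        if "E" in group and group != "TTS_only":
            out["exon_containing"] += pct
        if "I" in group:
            out["intron_containing"] += pct
    return {k: round(v, 10) for k, v in out.items()}


def composition_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Per DMR class and genic/intergenic stratum: counts, hyper fraction,
    CGI-class fractions and repeat fraction.

    ``calls`` is an annotated, statistics-bearing DMR table (needs
    dmr_class, direction, intergenic, cgi_class, repeat_flag).
    """
    rows = []
    df = calls[calls["dmr_class"] != "none"] if "dmr_class" in calls.columns else calls
    for cls, grp in df.groupby("dmr_class"):
        for stratum, sub in (("genic", grp[~grp["intergenic"]]), ("intergenic", grp[grp["intergenic"]]), ("all", grp)):
            n = len(sub)
            if n == 0:
                rows.append({"dmr_class": cls, "stratum": stratum, "n": 0})
                continue
            rows.append(
                {
                    "dmr_class": cls,
                    "stratum": stratum,
                    "n": n,
                    "hyper_fraction": float((sub["direction"] == "hyper").mean()),
                    "cgi_fraction": float((sub["cgi_class"] == "CGI").mean()),
                    "shore_fraction": float((sub["cgi_class"] == "shore").mean()),
                    "noncgi_fraction": float((sub["cgi_class"] == "nonCGI").mean()),
                    "repeat_fraction": float(sub["repeat_flag"].mean()),
                }
            )
    return pd.DataFrame(rows)
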
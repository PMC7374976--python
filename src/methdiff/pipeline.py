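"""End-to-end orchestration: simulate (or load) inputs, run every stage,
and write a manifest of all outputs.

Stages: binning (filter + quantile normalization + QC) -> DMR ranking and
classification -> feature annotation and DMG grouping -> motif enrichment
in hyper- vs hypomethylated intron DMR bins -> expression anti-correlation
and bisulfite validation.  A single master seed derives a fixed stream per
stage, so a rerun with the same config is bit-identical, and ``resume``
skips stages whose outputs already exist with matching hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from methdiff import annotation as ann_mod
from methdiff import binning, dmr, motifs, synthetic, validation

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures", "write_fasta", "read_fasta"]


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with the standard defaults."""

    out_dir: str = "methdiff_out"
    window: int = 500
    min_total: int = 20
    drop_chroms: tuple = ("chrX",)
    q_strict: float = 0.05
    q_lenient: float = 0.10
    promoter_up: int = 1500
    promoter_down: int = 500
    tts_flank: int = 500
    shore_width: int = 2000
    alpha: float = 0.05
    motif_consensus: str = synthetic.PAX5_CONSENSUS
    seed: int = 0
    sim: dict = field(default_factory=dict)  # overrides for SimConfig

    def sim_config(self) -> synthetic.SimConfig:
        return synthetic.SimConfig(seed=self.seed, window=self.window, **self.sim)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "drop_chroms" in data:
            data["drop_chroms"] = tuple(data["drop_chroms"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["drop_chroms"] = list(self.drop_chroms)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Run the full synthetic-data analysis and write all stage outputs.

    Returns the manifest (also written to ``<out_dir>/manifest.json``):
    config, per-stage row counts, and a sha256 per output file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    old_manifest = json.loads(manifest_path.read_text()) if (resume and manifest_path.exists()) else {}
    old_hashes = old_manifest.get("files", {})
    manifest: dict = {"config": {**asdict(config), "drop_chroms": list(config.drop_chroms)},
                      "stages": {}, "files": {}}
    stage_rows: dict = manifest["stages"]

    def _stage_done(names: list[str]) -> bool:
        return resume and all(
            (out / n).exists() and old_hashes.get(n) == _sha256(out / n) for n in names
        )

    cfg = config.sim_config()

    # ---- stage: simulate -------------------------------------------------
    genome = synthetic.simulate_genome(cfg)
    matrix, truth = synthetic.simulate_counts(cfg, genome)
    seqs = synthetic.simulate_sequences(genome, truth, cfg)
    sim_files = ["genome.fa", "counts.tsv", "samples.tsv", "truth_cmt.bed", "truth_subtype.bed"]
    if not _stage_done(sim_files):
        write_fasta(seqs, out / "genome.fa")
        matrix.to_tsv(out / "counts.tsv")
        matrix.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
        truth.cmt_dmr_bins.to_csv(out / "truth_cmt.bed", sep="\t", index=False)
        truth.subtype_dmr_bins.to_csv(out / "truth_subtype.bed", sep="\t", index=False)
    stage_rows["simulate"] = {"bins": matrix.n_bins, "samples": matrix.n_samples,
                              "planted_condition": len(truth.cmt_dmr_bins),
                              "planted_subtype": len(truth.subtype_dmr_bins)}

    # ---- stage: binning --------------------------------------------------
    matrix.bins = binning.make_bins(genome.chrom_sizes, config.window, sequence=seqs)
    filt = binning.filter_bins(matrix, min_total=config.min_total, drop_chroms=config.drop_chroms)
    norm = binning.quantile_normalize(filt.matrix)
    qc = binning.cpg_coverage_profile(norm)
    corr = binning.sample_correlation(norm)
    if not _stage_done(["normalized.tsv", "qc_coverage.tsv", "qc_correlation.tsv"]):
        norm.to_tsv(out / "normalized.tsv")
        qc.to_csv(out / "qc_coverage.tsv", sep="\t", index=False)
        corr.to_csv(out / "qc_correlation.tsv", sep="\t")
    stage_rows["binning"] = {"kept": filt.kept, **{k: v for k, v in filt.as_dict().items() if k != "kept"}}

    # ---- stage: dmr ------------------------------------------------------
    ranks = dmr.rank_bins(norm)
    records = dmr.classify_dmrs(ranks, dmr.CutoffPolicy(q=config.q_strict))
    records = dmr.dmr_statistics(norm, records)
    counts_report = dmr.classification_counts(records)
    if not _stage_done(["dmrs.tsv"]):
        records.to_csv(out / "dmrs.tsv", sep="\t", index=False)
    stage_rows["dmr"] = counts_report

    # ---- stage: annotation ----------------------------------------------
    features = ann_mod.derive_features(
        genome, promoter_up=config.promoter_up, promoter_down=config.promoter_down,
        tts_flank=config.tts_flank, shore_width=config.shore_width,
    )
    dmr_rows = records[records["dmr_class"] != "none"].copy()
    calls = ann_mod.annotate_bins(dmr_rows, features, known_chroms=genome.chrom_sizes.index)
    dmgs = ann_mod.group_dmgs(calls, dmr_class="condition")
    composition = ann_mod.composition_summary(calls)
    if not _stage_done(["dmr_annotation.tsv", "dmgs.tsv", "composition.tsv"]):
        calls.to_csv(out / "dmr_annotation.tsv", sep="\t", index=False)
        dmgs.to_csv(out / "dmgs.tsv", sep="\t", index=False)
        composition.to_csv(out / "composition.tsv", sep="\t", index=False)
    stage_rows["annotation"] = {"annotated_dmrs": len(calls), "dmgs": len(dmgs),
                                "group_counts": dmgs["group"].value_counts().to_dict()}

    # ---- stage: motifs ---------------------------------------------------
    motif = motifs.parse_motif(config.motif_consensus, name="PAX5-like")
    cond = calls[calls["dmr_class"] == "condition"]
    intron = cond[cond["intron_genes"].astype(str) != ""]
    results = []
    norm_key = {(c, int(s)) for c, s in zip(norm.bins["chrom"], norm.bins["start"])}

    def _bin_seq(row) -> str:
        return seqs[row["chrom"]][int(row["start"]) : int(row["end"])]

    non_dmr_intron = []
    intron_feature = features["intron"]
    dmr_keys = {(c, int(s)) for c, s in zip(dmr_rows["chrom"], dmr_rows["start"])}
    for _, iv in intron_feature.iterrows():
        start = (int(iv["start"]) // config.window + 1) * config.window
        for s in range(start, int(iv["end"]) - config.window, config.window):
            key = (iv["chrom"], s)
            if key not in dmr_keys and key in norm_key:
                non_dmr_intron.append({"chrom": iv["chrom"], "start": s, "end": s + config.window})
    pool = {f"bg{i}": _bin_seq(r) for i, r in enumerate(pd.DataFrame(non_dmr_intron).drop_duplicates().to_dict("records"))}
    for direction in ("hyper", "hypo"):
        sub = intron[intron["direction"] == direction]
        if len(sub) == 0 or not pool:
            continue
        targets = {f"{direction}{i}": _bin_seq(r) for i, (_, r) in enumerate(sub.iterrows())}
        bg = motifs.matched_background(targets, pool, size=min(len(pool), 4 * len(targets)),
                                       rng=np.random.default_rng([config.seed, 9]))
        results.append(motifs.enrichment_test(motif, targets, bg, direction_set=direction))
    enrich = motifs.enrichment_table(results)
    if not _stage_done(["motif_enrichment.tsv"]):
        enrich.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)
    stage_rows["motifs"] = {"tests": len(enrich), "target_bins_hyper": int((intron["direction"] == "hyper").sum()),
                            "background_pool": len(pool)}

    # ---- stage: integration / validation ---------------------------------
    expr = synthetic.simulate_expression(truth, cfg)
    contrasts = validation.expression_contrast(expr, matrix.samples)
    gene_dirs = validation.majority_direction(
        intron.assign(gene_id=intron["intron_genes"].str.split(",").str[0])
    )
    ac_calls = validation.call_anticorrelation(gene_dirs, contrasts, alpha=config.alpha)
    bs_table, planted_pos = synthetic.simulate_bs_counts(cfg)
    bs_sites = validation.bs_region_test(bs_table, grouping="per_site", alpha=config.alpha)
    bs_region = validation.bs_region_test(bs_table, grouping="per_region", alpha=config.alpha)
    if not _stage_done(["expression.tsv", "anticorrelation.tsv", "bs_sites.tsv"]):
        expr.to_csv(out / "expression.tsv", sep="\t")
        ac_calls.to_csv(out / "anticorrelation.tsv", sep="\t", index=False)
        bs_sites.to_csv(out / "bs_sites.tsv", sep="\t", index=False)
    stage_rows["validation"] = {
        "genes_tested": len(contrasts),
        "anti_correlated": int((ac_calls["call"] == "anti_correlated").sum()),
        "bs_significant_sites": int(bs_sites["significant"].sum()),
        "bs_region_p": float(bs_region["p_value"].iloc[0]),
    }

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest


def make_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write the small toy datasets used across the documentation examples:
    a 4-bin count matrix with 2 pairs, a 4-pair bisulfite table whose first
    site is the 80 % ratio example, and consensus-bearing sequences."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    samples = pd.DataFrame(
        {
            "sample_id": ["P01T", "P01N", "P02T", "P02N"],
            "pair_id": ["P01", "P01", "P02", "P02"],
            "condition": ["tumor", "normal", "tumor", "normal"],
            "subtype": ["simple", "simple", "ductal", "ductal"],
        }
    )
    bins = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chrX"],
            "start": [0, 500, 1000, 0],
            "end": [500, 1000, 1500, 500],
            "cg_count": [5, 0, 8, 3],
        }
    )
    counts = np.array([[40, 10, 44, 12], [100, 90, 110, 95], [3, 4, 5, 2], [50, 50, 50, 50]], dtype=float)
    m = binning.BinMatrix(bins=bins, samples=samples, counts=counts)
    paths["counts"] = out / "toy_counts.tsv"
    m.to_tsv(paths["counts"])
    paths["samples"] = out / "toy_samples.tsv"
    samples.to_csv(paths["samples"], sep="\t", index=False)

    rows = []
    for i, (ct, tt) in enumerate([(8, 2), (30, 70), (55, 45), (90, 10)]):
        rows.append({"chrom": "chr1", "pos": 100 + 25 * i, "sample_id": "V01T", "pair_id": "V01",
                     "condition": "tumor", "subtype": "simple", "c_count": ct, "t_count": tt})
        rows.append({"chrom": "chr1", "pos": 100 + 25 * i, "sample_id": "V01N", "pair_id": "V01",
                     "condition": "normal", "subtype": "simple", "c_count": tt, "t_count": ct})
    paths["bs"] = out / "toy_bs.tsv"
    pd.DataFrame(rows).to_csv(paths["bs"], sep="\t", index=False)

    consensus = synthetic.PAX5_CONSENSUS
    seqs = {
        "with_motif": "ACGTACGTAC" + consensus + "TTTTGGGGCCAA",
        "with_rc": "AAAA" + motifs.reverse_complement(consensus) + "CCCC",
        "plain": "A" * 60,
    }
    paths["fasta"] = out / "toy_sequences.fa"
    write_fasta(seqs, paths["fasta"])

    paths["motifs"] = out / "toy_motifs.tsv"
    (out / "toy_motifs.tsv").write_text(
        "PAX5\tGCAGCCAAGCGTGACC\nPAX6\tNGTGTTCAVTSAAGCGKAAA\n"
    )
    return paths
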
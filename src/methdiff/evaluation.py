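"""Recovery, calibration and power metrics on synthetic data.

These functions run the full analysis on generated data with planted
ground truth and measure how well the planted structure is recovered:
condition-DMR sensitivity and class accuracy under the study conditions,
recovery under a balanced label-permutation null, motif-enrichment power
at planted rates, and targeted-bisulfite site recovery.  They are the
package's regression harness: the numbers they return are computed from
scratch on every call.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from methdiff import binning, dmr, motifs, synthetic, validation

__all__ = [
    "bs_validation_metrics",
    "dmr_recovery_metrics",
    "motif_enrichment_power",
    "null_recovery_rate",
    "run_dmr_analysis",
]


def run_dmr_analysis(cfg: synthetic.SimConfig, q: float = 0.05):
    """Simulate counts, filter, normalize, rank and classify.

    Returns (normalized BinMatrix, classified record table, GroundTruth).
    """
    genome = synthetic.simulate_genome(cfg)
    matrix, truth = synthetic.simulate_counts(cfg, genome)
    filt = binning.filter_bins(matrix, require_cg=False)
    norm = binning.quantile_normalize(filt.matrix)
    records = dmr.classify_dmrs(dmr.rank_bins(norm), q)
    return norm, records, truth


def _planted_classes(norm, records, truth) -> tuple[np.ndarray, np.ndarray]:
    """Assigned class of every planted condition / subtype bin ('absent'
    when the bin was filtered out)."""
    key = dict(zip(zip(norm.bins["chrom"], norm.bins["start"]), records["dmr_class"]))
    cmt = np.array([key.get((c, s), "absent")
                    for c, s in zip(truth.cmt_dmr_bins["chrom"], truth.cmt_dmr_bins["start"])])
    sub = np.array([key.get((c, s), "absent")
                    for c, s in zip(truth.subtype_dmr_bins["chrom"], truth.subtype_dmr_bins["start"])])
    return cmt, sub


def dmr_recovery_metrics(cfg: synthetic.SimConfig, q: float = 0.05) -> dict:
    """Planted-bin recovery under the study conditions.

    sensitivity: fraction of planted condition bins classified condition.
    class_accuracy: among planted bins recovered as *some* DMR class, the
    fraction assigned their true class.
    mutual_exclusivity_ok: no bin carries both classes (guaranteed by
    construction, verified here).
    """
    norm, records, truth = run_dmr_analysis(cfg, q)
    cmt, sub = _planted_classes(norm, records, truth)
    recovered = np.concatenate([cmt[cmt != "none"], sub[sub != "none"]])
    correct = np.concatenate([
        cmt[(cmt == "condition") | (cmt == "subtype")] == "condition",
        sub[(sub == "condition") | (sub == "subtype")] == "subtype",
    ])
    counts = dmr.classification_counts(records)
    return {
        "sensitivity_condition": float((cmt == "condition").mean()),
        "sensitivity_subtype": float((sub == "subtype").mean()),
        "class_accuracy": float(correct.mean()) if len(correct) else float("nan"),
        "n_planted_condition": int(len(cmt)),
        "n_planted_subtype": int(len(sub)),
        "mutual_exclusivity_ok": bool(counts["n_dmr_total"] == counts["n_condition"] + counts["n_subtype"]),
        "counts": counts,
    }


def null_recovery_rate(
    cfg: synthetic.SimConfig,
    q: float = 0.05,
    n_shuffles: int = 3,
    shuffle_seed: int = 0,
) -> dict:
    """Planted-condition-bin recovery after balanced within-pair label
    swaps: the mean rate should sit at the chance level q."""
    genome = synthetic.simulate_genome(cfg)
    matrix, truth = synthetic.simulate_counts(cfg, genome)
    norm = binning.quantile_normalize(binning.filter_bins(matrix, require_cg=False).matrix)
    rng = np.random.default_rng(shuffle_seed)
    rates = []
    for _ in range(n_shuffles):
        shuffled = dataclasses.replace(norm, samples=dmr.shuffle_condition_labels(norm.samples, rng))
        records = dmr.classify_dmrs(dmr.rank_bins(shuffled), q)
        cmt, _ = _planted_classes(shuffled, records, truth)
        rates.append(float((cmt == "condition").mean()))
    se = float(np.sqrt(q * (1 - q) / len(truth.cmt_dmr_bins)))
    return {"rates": rates, "mean_rate": float(np.mean(rates)), "chance": q,
            "bound": q + 3 * se, "n_planted": int(len(truth.cmt_dmr_bins))}


def motif_enrichment_power(
    n_target: int = 500,
    n_background: int = 2000,
    length: int = 500,
    rate_target: float = 0.30,
    rate_background: float = 0.05,
    consensus: str = synthetic.PAX5_CONSENSUS,
    seed: int = 0,
) -> motifs.EnrichmentResult:
    """Enrichment p-value with the motif planted at the stated rates into
    random sequences of the stated length."""
    rng = np.random.default_rng([seed, 17])
    motif = motifs.parse_motif(consensus, name="planted")
    bases = np.array(list("ACGT"))

    def make_set(n, rate, prefix):
        out = {}
        for i in range(n):
            arr = bases[rng.integers(0, 4, size=length)]
            if rng.random() < rate:
                off = int(rng.integers(0, length - motif.width + 1))
                ins = consensus if rng.random() < 0.5 else motifs.reverse_complement(consensus)
                arr[off : off + motif.width] = list(ins)
            out[f"{prefix}{i}"] = "".join(arr)
        return out

    targets = make_set(n_target, rate_target, "t")
    background = make_set(n_background, rate_background, "b")
    return motifs.enrichment_test(motif, targets, background, direction_set="hyper")


def bs_validation_metrics(cfg: synthetic.SimConfig, n_seeds: int = 20) -> dict:
    """Targeted-bisulfite site recovery over repeated simulations.

    For each seed: simulate per-CG counts with the configured planted
    shift, run the per-site paired tests, count recovered planted sites
    (significant and hypermethylated) and false-positive unplanted sites.
    Returns the medians across seeds.
    """
    true_pos, false_pos = [], []
    for s in range(n_seeds):
        c = dataclasses.replace(cfg, seed=int(cfg.seed) + s)
        table, planted_pos = synthetic.simulate_bs_counts(c)
        res = validation.bs_region_test(table, grouping="per_site")
        planted = res["pos"].isin(planted_pos)
        true_pos.append(int((res.loc[planted, "significant"]
                             & (res.loc[planted, "direction"] == "hyper")).sum()))
        false_pos.append(int(res.loc[~planted, "significant"].sum()))
    return {
        "median_true_positives": float(np.median(true_pos)),
        "median_false_positives": float(np.median(false_pos)),
        "n_planted": int(cfg.bs_n_planted),
        "n_sites": int(cfg.bs_n_sites),
        "true_positives": true_pos,
        "false_positives": false_pos,
    }
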
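"""The synthetic-data generator: determinism, planted structure, and the
statistical behaviour the downstream analysis assumes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdiff import (
    SimConfig,
    make_bins,
    scan,
    parse_motif,
    simulate_bs_counts,
    simulate_counts,
    simulate_expression,
    simulate_genome,
    simulate_sequences,
)
from methdiff.synthetic import sample_sheet


def tiny_cfg(**kw) -> SimConfig:
    base = dict(n_chromosomes=2, chrom_length=300_000, n_genes=8,
                n_cmt_dmrs=10, n_subtype_dmrs=10, seed=3)
    base.update(kw)
    return SimConfig(**base)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_pairs=1, subtype_sizes={"simple": 1})
        with pytest.raises(ValueError):
            SimConfig(subtype_sizes={"simple": 3})  # does not sum to 11
        with pytest.raises(ValueError):
            SimConfig(frac_hyper=1.5)
        with pytest.raises(ValueError):
            SimConfig(window=0)

    def test_sample_sheet_structure(self):
        s = sample_sheet(SimConfig())
        assert len(s) == 22
        assert s.groupby("pair_id").size().eq(2).all()
        assert s["subtype"].value_counts().to_dict() == {"simple": 8, "ductal": 8, "complex": 6}


class TestSimulateGenome:
    def test_deterministic(self):
        cfg = tiny_cfg()
        a, b = simulate_genome(cfg), simulate_genome(cfg)
        pd.testing.assert_frame_equal(a.genes, b.genes)
        pd.testing.assert_frame_equal(a.exons, b.exons)
        pd.testing.assert_frame_equal(a.cgis, b.cgis)

    def test_exon_intron_arithmetic(self):
        ann = simulate_genome(tiny_cfg())
        introns = ann.introns()
        for gid, grp in ann.exons.groupby("gene_id"):
            n_intr = (introns["gene_id"] == gid).sum()
            assert n_intr == len(grp) - 1  # n exons -> n-1 introns

    def test_every_gene_has_at_least_two_exons(self):
        ann = simulate_genome(tiny_cfg())
        assert ann.exons.groupby("gene_id").size().min() >= 2

    def test_gene_intervals_within_bounds_random_configs(self):
        rng = np.random.default_rng(33)
        for trial in range(25):
            cfg = tiny_cfg(
                chrom_length=int(rng.integers(200_000, 600_000)),
                n_genes=int(rng.integers(2, 10)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            ann = simulate_genome(cfg)
            merged = ann.genes.merge(ann.exons, on="gene_id", suffixes=("_g", "_e"))
            assert (ann.genes["start"] >= 0).all()
            assert (ann.genes["end"] <= cfg.chrom_length).all()
            assert (merged["start_e"] >= merged["start_g"]).all()
            assert (merged["end_e"] <= merged["end_g"]).all(), f"trial {trial}"

    def test_chromosome_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            simulate_genome(tiny_cfg(chrom_length=30_000, n_genes=50))

    def test_last_chromosome_is_chrx(self):
        cfg = tiny_cfg()
        assert cfg.chrom_names[-1] == "chrX"
        ann = simulate_genome(cfg)
        assert "chrX" in ann.chrom_sizes.index


class TestSimulateCounts:
    def test_deterministic(self):
        cfg = tiny_cfg()
        ann = simulate_genome(cfg)
        (m1, t1), (m2, t2) = simulate_counts(cfg, ann), simulate_counts(cfg, ann)
        np.testing.assert_array_equal(m1.counts, m2.counts)
        pd.testing.assert_frame_equal(t1.cmt_dmr_bins, t2.cmt_dmr_bins)

    def test_planted_sets_disjoint_and_autosomal(self):
        cfg = tiny_cfg()
        _, truth = simulate_counts(cfg, simulate_genome(cfg))
        cmt = set(truth.cmt_dmr_bins["bin_id"])
        sub = set(truth.subtype_dmr_bins["bin_id"])
        assert not cmt & sub
        assert (truth.cmt_dmr_bins["chrom"] != "chrX").all()
        assert (truth.subtype_dmr_bins["chrom"] != "chrX").all()

    def test_zero_effect_indistinguishable_from_null(self):
        cfg = tiny_cfg(chrom_length=600_000, n_cmt_dmrs=200, n_subtype_dmrs=10,
                       effect_log2fc=0.0, seed=5)
        m, truth = simulate_counts(cfg, simulate_genome(cfg))
        tumor = (m.samples["condition"] == "tumor").to_numpy()
        diffs = m.counts[:, tumor].mean(axis=1) - m.counts[:, ~tumor].mean(axis=1)
        planted = np.zeros(m.n_bins, dtype=bool)
        planted[truth.cmt_dmr_bins["bin_id"]] = True
        rng = np.random.default_rng(0)
        unplanted = rng.choice(np.flatnonzero(~planted), 200, replace=False)
        p = stats.mannwhitneyu(diffs[planted], diffs[unplanted]).pvalue
        assert p > 0.01

    def test_hyper_bins_elevated_at_effect_two(self):
        cfg = tiny_cfg(chrom_length=600_000, n_cmt_dmrs=100, effect_log2fc=2.0,
                       nb_mean=50, seed=6)
        m, truth = simulate_counts(cfg, simulate_genome(cfg))
        tumor = (m.samples["condition"] == "tumor").to_numpy()
        hyper = truth.cmt_dmr_bins.query("direction == 'hyper'")["bin_id"].to_numpy()
        t_mean = m.counts[np.ix_(hyper, np.flatnonzero(tumor))].mean(axis=1)
        n_mean = m.counts[np.ix_(hyper, np.flatnonzero(~tumor))].mean(axis=1)
        assert (t_mean > n_mean).mean() >= 0.95

    def test_hyper_fraction_matches_config(self):
        cfg = tiny_cfg(n_cmt_dmrs=100)
        _, truth = simulate_counts(cfg, simulate_genome(cfg))
        frac = (truth.cmt_dmr_bins["direction"] == "hyper").mean()
        assert frac == pytest.approx(0.66, abs=0.005)

    def test_oversized_request_raises(self):
        cfg = tiny_cfg(n_cmt_dmrs=10**6)
        with pytest.raises(ValueError, match="planted"):
            simulate_counts(cfg, simulate_genome(cfg))


class TestSimulateSequences:
    def test_deterministic(self):
        cfg = tiny_cfg()
        ann = simulate_genome(cfg)
        _, truth = simulate_counts(cfg, ann)
        s1 = simulate_sequences(ann, truth, cfg)
        s2 = simulate_sequences(ann, truth, cfg)
        assert s1 == s2

    def test_plant_rate_one_places_motif_in_every_target_bin(self):
        cfg = tiny_cfg(motif_plant_rate_target=1.0, motif_plant_rate_background=0.0,
                       n_cmt_dmrs=20, frac_cmt_in_introns=1.0)
        ann = simulate_genome(cfg)
        _, truth = simulate_counts(cfg, ann)
        seqs = simulate_sequences(ann, truth, cfg)
        motif = parse_motif(cfg.motif_consensus)
        targets = truth.cmt_dmr_bins.query("direction == 'hyper' and intron_gene != ''")
        assert len(targets) > 0
        for _, row in targets.iterrows():
            window = seqs[row["chrom"]][row["start"] : row["end"]]
            assert len(scan(window, motif)) >= 1

    def test_zero_plant_rate_hit_rate_matches_chance(self):
        cfg = tiny_cfg(motif_plant_rate_target=0.0, motif_plant_rate_background=0.0,
                       motif_consensus="ACGTACGT", chrom_length=400_000)
        ann = simulate_genome(cfg)
        _, truth = simulate_counts(cfg, ann)
        seqs = simulate_sequences(ann, truth, cfg)
        motif = parse_motif(cfg.motif_consensus)
        n_offsets = n_hits = 0
        for seq in seqs.values():
            n_offsets += len(seq) - motif.width + 1
            n_hits += len(scan(seq, motif))
        expected = 2 * 0.25**motif.width
        se = np.sqrt(expected / n_offsets)
        assert abs(n_hits / n_offsets - expected) < 4 * se + 1e-9

    def test_motif_longer_than_window_raises(self):
        cfg = tiny_cfg(window=10)
        ann = simulate_genome(cfg)
        _, truth = simulate_counts(cfg, ann)
        with pytest.raises(ValueError, match="window"):
            simulate_sequences(ann, truth, cfg)

    def test_sequences_match_chromosome_sizes(self):
        cfg = tiny_cfg()
        ann = simulate_genome(cfg)
        _, truth = simulate_counts(cfg, ann)
        seqs = simulate_sequences(ann, truth, cfg)
        for chrom, size in ann.chrom_sizes.items():
            assert len(seqs[chrom]) == size
        bins = make_bins(ann.chrom_sizes, cfg.window, sequence=seqs)
        assert (bins["cg_count"] >= 0).all()


class TestSimulateExpression:
    def test_deterministic(self):
        cfg = tiny_cfg()
        _, truth = simulate_counts(cfg, simulate_genome(cfg))
        pd.testing.assert_frame_equal(simulate_expression(truth, cfg), simulate_expression(truth, cfg))

    def test_values_non_negative(self):
        cfg = tiny_cfg()
        _, truth = simulate_counts(cfg, simulate_genome(cfg))
        assert (simulate_expression(truth, cfg) >= 0).all().all()

    def test_hyper_gene_downshifted_in_tumors(self):
        hits = 0
        trials = 0
        for seed in range(10):
            cfg = tiny_cfg(seed=seed, expr_effect_log2fc=2.0, frac_anticorrelated=1.0)
            _, truth = simulate_counts(cfg, simulate_genome(cfg))
            expr = simulate_expression(truth, cfg)
            samples = sample_sheet(cfg)
            tumor = samples.loc[samples["condition"] == "tumor", "sample_id"]
            normal = samples.loc[samples["condition"] == "normal", "sample_id"]
            log2 = np.log2(expr + 1)
            for _, row in truth.anticorrelated_genes.iterrows():
                trials += 1
                diff = log2.loc[row["gene_id"], tumor].mean() - log2.loc[row["gene_id"], normal].mean()
                if (diff < 0) == (row["direction"] == "hyper"):
                    hits += 1
        assert trials > 20
        assert hits / trials >= 0.95

    def test_no_planted_genes_symmetric(self):
        cfg = tiny_cfg(frac_anticorrelated=0.0, seed=9)
        _, truth = simulate_counts(cfg, simulate_genome(cfg))
        assert len(truth.anticorrelated_genes) == 0
        expr = simulate_expression(truth, cfg)
        samples = sample_sheet(cfg)
        tumor = samples.loc[samples["condition"] == "tumor", "sample_id"]
        normal = samples.loc[samples["condition"] == "normal", "sample_id"]
        log2 = np.log2(expr + 1)
        diffs = log2[list(tumor)].mean(axis=1) - log2[list(normal)].mean(axis=1)
        assert abs(np.median(diffs)) < 0.2


class TestSimulateBsCounts:
    def test_deterministic(self):
        cfg = tiny_cfg()
        t1, p1 = simulate_bs_counts(cfg)
        t2, p2 = simulate_bs_counts(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        np.testing.assert_array_equal(p1, p2)

    def test_degenerate_probability_one_all_c(self):
        cfg = tiny_cfg(bs_baseline=1.0, bs_shift=0.0, bs_sample_sigma=0.0)
        # site_base jitter is clipped into [0.05, 0.95]; force exact 1.0 via shift
        cfg = tiny_cfg(bs_baseline=0.95, bs_shift=0.05, bs_sample_sigma=0.0,
                       bs_n_planted=16)
        t, _ = simulate_bs_counts(cfg)
        tumor = t[t["condition"] == "tumor"]
        # planted tumor sites sit at baseline-cap 0.95 + 0.05 = 1.0 when the
        # site jitter hits the cap; at minimum all counts are heavily methylated
        assert (tumor["c_count"] / (tumor["c_count"] + tumor["t_count"])).min() > 0.7

    def test_binomial_concentration_at_half(self):
        cfg = tiny_cfg(bs_baseline=0.5, bs_shift=0.0, bs_sample_sigma=0.0,
                       bs_depth=10_000, bs_n_planted=0)
        # remove per-site jitter by overriding with many sites averaged
        t, _ = simulate_bs_counts(cfg)
        ratio = (t["c_count"] / (t["c_count"] + t["t_count"])).to_numpy()
        site_base_spread = 0.05 * 3  # site baselines jitter with sd 0.05
        assert np.all(np.abs(ratio - 0.5) < site_base_spread + 0.02)

    def test_planted_sites_are_shifted(self):
        cfg = tiny_cfg()
        t, planted_pos = simulate_bs_counts(cfg)
        ratios = t.assign(ratio=t["c_count"] / (t["c_count"] + t["t_count"]))
        diffs = ratios.pivot_table(index="pos", columns="condition", values="ratio")
        gap = diffs["tumor"] - diffs["normal"]
        assert gap.loc[list(planted_pos)].min() > 0.2
        unplanted = [p for p in diffs.index if p not in set(planted_pos)]
        assert abs(gap.loc[unplanted]).max() < 0.1
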
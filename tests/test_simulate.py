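import numpy as np
import pandas as pd
import pytest

from methylcap.peaks import dedup_fragments
from methylcap.simulate import (MethylomeTruth, SimulationParams,
                                generate_genome, generate_methylome,
                                simulate_methylcap, simulate_rnaseq,
                                simulate_rrbs, simulate_study, stage_rng,
                                truth_tables)


class TestGenerateGenome:
    def test_no_genes_means_all_intergenic(self):
        g = generate_genome(n_chrom=1, chrom_len=100_000, n_genes=0,
                            desert_chroms=(), seed=0)
        assert g.genes == []
        assert g.n_cpg > 0

    def test_requested_desert_is_present(self):
        g = generate_genome(n_chrom=1, chrom_len=2_000_000, n_genes=50,
                            desert_chroms=("chr1",), seed=0)
        s, e = g.desert_intervals["chr1"]
        assert e - s > 500_000
        for gene in g.genes:
            assert gene.span.end <= s or gene.span.start >= e

    def test_cpg_positions_strictly_increasing_within_bounds(self):
        g = generate_genome(n_chrom=2, chrom_len=300_000, n_genes=20,
                            desert_chroms=(), seed=3)
        for chrom, pos in g.cpg_positions.items():
            assert (np.diff(pos) >= 2).all()
            assert pos[-1] <= g.chrom_lengths[chrom] - 2

    def test_island_to_background_rate_ratio(self):
        """Promoter CpG density / background density approximates the ratio
        of the two generating rates (Monte-Carlo over several genomes)."""
        from methylcap.simulate import promoter_window
        island, background = 0.05, 0.005
        isl_counts = isl_len = bg_counts = bg_len = 0
        for seed in range(15):
            g = generate_genome(n_chrom=1, chrom_len=400_000, n_genes=20,
                                island_density=island,
                                background_density=background,
                                desert_chroms=(), seed=seed)
            pos = g.cpg_positions["chr1"]
            mask = np.zeros(g.chrom_lengths["chr1"], bool)
            for gene in g.genes:
                s, e = promoter_window(gene)
                mask[s:e] = True
            in_island = mask[pos]
            isl_counts += in_island.sum()
            isl_len += mask.sum()
            bg_counts += (~in_island).sum()
            bg_len += (~mask).sum()
        ratio = (isl_counts / isl_len) / (bg_counts / bg_len)
        assert 8.0 <= ratio <= 12.0  # 10 within 20%

    def test_too_many_genes_error(self):
        with pytest.raises(ValueError, match="cannot fit"):
            generate_genome(n_chrom=1, chrom_len=100_000, n_genes=50,
                            desert_chroms=(), seed=0)


class TestGenerateMethylome:
    def test_delta_one_is_identity(self):
        g = generate_genome(n_chrom=1, chrom_len=200_000, n_genes=10,
                            desert_chroms=(), seed=1)
        m = generate_methylome(g, n_regulated=5, delta=1.0, cellline_sd=0.0, seed=1)
        np.testing.assert_array_equal(
            m.condition("L1", "control")["chr1"], m.condition("L1", "treated")["chr1"])

    def test_degenerate_baseline_at_zero(self):
        g = generate_genome(n_chrom=1, chrom_len=200_000, n_genes=10,
                            desert_chroms=(), seed=1)
        m = generate_methylome(g, baseline_mix=(1.0, 0.0, 0.0), n_regulated=0,
                               cellline_sd=0.0, seed=1)
        for cond in m.degrees.values():
            assert (cond["chr1"] == 0).all()

    def test_multiplicative_delta_on_affected_cpgs(self):
        """Affected promoter CpGs at baseline 0.8 under delta 0.25 average
        to 0.2 (closed-form mean; point-mass baseline, no cell-line noise)."""
        g = generate_genome(n_chrom=1, chrom_len=400_000, n_genes=30,
                            desert_chroms=(), seed=3)
        m = generate_methylome(g, baseline_mix=(0.0, 0.8, 0.8), n_regulated=30,
                               delta=0.25, cellline_sd=0.0, seed=3)
        aff = m.affected["chr1"]
        assert aff.sum() > 500
        treated = m.condition("L1", "treated")["chr1"][aff]
        control = m.condition("L1", "control")["chr1"][aff]
        assert control.mean() == pytest.approx(0.8, abs=1e-12)
        assert treated.mean() == pytest.approx(0.2, abs=1e-12)

    def test_unaffected_cpgs_identical_across_treatments(self):
        g = generate_genome(n_chrom=1, chrom_len=200_000, n_genes=10,
                            desert_chroms=(), seed=4)
        m = generate_methylome(g, n_regulated=3, delta=0.3, seed=4)
        un = ~m.affected["chr1"]
        np.testing.assert_allclose(
            m.condition("L2", "control")["chr1"][un],
            m.condition("L2", "treated")["chr1"][un])

    def test_too_many_regulated_errors(self):
        g = generate_genome(n_chrom=1, chrom_len=200_000, n_genes=5,
                            desert_chroms=(), seed=1)
        with pytest.raises(ValueError):
            generate_methylome(g, n_regulated=6, seed=1)


def _flat_methylome(genome, level_by_window):
    """Point-degree methylome: dict of (start, end) -> degree on chr1."""
    pos = genome.cpg_positions["chr1"]
    deg = np.zeros(len(pos))
    for (s, e), level in level_by_window.items():
        deg[(pos >= s) & (pos < e)] = level
    return MethylomeTruth({("L1", "control"): {"chr1": deg}}, frozenset(),
                          {"chr1": np.zeros(len(pos), bool)}, 1.0)


class TestSimulateMethylcap:
    def test_zero_depth_is_empty(self):
        g = generate_genome(n_chrom=1, chrom_len=100_000, n_genes=0,
                            desert_chroms=(), seed=1)
        m = _flat_methylome(g, {(0, 100_000): 1.0})
        fs = simulate_methylcap(g, m, SimulationParams(capture_depth=0),
                                ("L1", "control"), seed=0)
        assert len(fs) == 0

    def test_duplicate_injection_rate(self):
        g = generate_genome(n_chrom=1, chrom_len=100_000, n_genes=0,
                            desert_chroms=(), seed=1)
        m = _flat_methylome(g, {(0, 100_000): 1.0})
        fs = simulate_methylcap(
            g, m, SimulationParams(capture_depth=10_000, dup_rate=0.5),
            ("L1", "control"), seed=0)
        n_total = len(fs)
        n_unique = len(fs.frame.drop_duplicates(["chrom", "start", "end"]))
        n_injected = round(0.5 * n_total)
        # after dedup, count is close to the number of fresh originals
        assert n_total - n_unique == pytest.approx(n_injected, rel=0.15)
        dd = dedup_fragments(fs)
        assert len(dd) == n_unique

    def test_fragment_lengths_within_bounds(self):
        g = generate_genome(n_chrom=1, chrom_len=100_000, n_genes=0,
                            desert_chroms=(), seed=1)
        m = _flat_methylome(g, {(0, 100_000): 1.0})
        fs = simulate_methylcap(g, m, SimulationParams(capture_depth=5_000),
                                ("L1", "control"), seed=0)
        lens = fs.frame.end - fs.frame.start
        assert lens.max() <= 400
        # right-edge clipping can shorten, but the bulk respects the minimum
        assert (lens >= 50).mean() > 0.99

    def test_capture_increases_with_methylation_degree(self):
        """Fragment counts in a 1-kb window rise monotonically with the
        window's methylation degree (fully methylated anchor elsewhere keeps
        total intensity fixed; noise floor near zero)."""
        g = generate_genome(n_chrom=1, chrom_len=100_000, n_genes=0,
                            desert_chroms=(), seed=1)
        means = []
        for level in (0.0, 0.25, 0.5, 0.75, 1.0):
            total = 0
            for seed in range(15):
                m = _flat_methylome(g, {(50_000, 51_000): 1.0,
                                        (10_000, 11_000): level})
                fs = simulate_methylcap(
                    g, m, SimulationParams(capture_depth=3_000,
                                           capture_noise_floor=1e-4,
                                           dup_rate=0.0),
                    ("L1", "control"), seed=seed)
                fr = fs.frame
                total += int(((fr.start < 11_000) & (fr.end > 10_000)).sum())
            means.append(total / 15)
        assert all(b > a for a, b in zip(means, means[1:]))
        assert means[-1] > 50 * max(means[0], 1e-9)  # ratio >> 1 vs unmethylated


class TestSimulateRrbs:
    def test_degree_extremes(self):
        g = generate_genome(n_chrom=1, chrom_len=100_000, n_genes=0,
                            desert_chroms=(), seed=2)
        ones = _flat_methylome(g, {(0, 100_000): 1.0})
        t = simulate_rrbs(ones, g, covered_fraction=1.0, seed=0)
        assert (t["n_unmeth"] == 0).all()
        zeros = _flat_methylome(g, {})
        t0 = simulate_rrbs(zeros, g, covered_fraction=1.0, seed=0)
        assert (t0["n_meth"] == 0).all()

    def test_pooled_degree_matches_truth(self):
        g = generate_genome(n_chrom=1, chrom_len=500_000, n_genes=0,
                            desert_chroms=(), seed=2)
        m = _flat_methylome(g, {(0, 500_000): 0.6})
        t = simulate_rrbs(m, g, rrbs_mean_cov=60, covered_fraction=1.0, seed=1)
        tot = (t["n_meth"] + t["n_unmeth"]).sum()
        pooled = t["n_meth"].sum() / tot
        se = np.sqrt(0.6 * 0.4 / tot)
        assert abs(pooled - 0.6) < 3 * se

    def test_covered_fraction_controls_site_count(self):
        g = generate_genome(n_chrom=1, chrom_len=500_000, n_genes=0,
                            desert_chroms=(), seed=2)
        m = _flat_methylome(g, {(0, 500_000): 0.5})
        t = simulate_rrbs(m, g, covered_fraction=0.11, seed=1)
        frac = len(t) / g.n_cpg
        assert 0.08 < frac < 0.14


class TestSimulateRnaseq:
    def test_beta_zero_means_equal_across_conditions(self):
        g = generate_genome(n_chrom=1, chrom_len=300_000, n_genes=15,
                            desert_chroms=(), seed=5)
        m = generate_methylome(g, n_regulated=10, delta=0.1, cellline_sd=0.0, seed=5)
        params = SimulationParams(expr_beta=0.0, nb_dispersion=0.0,
                                  rnaseq_depth=5e5)
        c = simulate_rnaseq(g, m, params, ("L1", "control"), seed=0)
        t = simulate_rnaseq(g, m, params, ("L1", "treated"), seed=0)
        # Poisson counts around identical means: totals agree to MC error
        assert abs(np.log2(t.sum() / c.sum())) < 0.02

    def test_zero_depth_zero_counts(self):
        g = generate_genome(n_chrom=1, chrom_len=300_000, n_genes=15,
                            desert_chroms=(), seed=5)
        m = generate_methylome(g, n_regulated=0, seed=5)
        c = simulate_rnaseq(g, m, SimulationParams(rnaseq_depth=0.0),
                            ("L1", "control"), seed=0)
        assert (c == 0).all()

    def test_log_fold_change_closed_form(self):
        """Promoter degree 0.8 -> 0.2 with beta 2 gives expected log2 fold
        change 2*0.6/ln 2 ~ 1.73; Monte-Carlo mean within 3 s.e."""
        g = generate_genome(n_chrom=1, chrom_len=300_000, n_genes=15,
                            desert_chroms=(), seed=6)
        pos = g.cpg_positions["chr1"]
        hi = {"chr1": np.full(len(pos), 0.8)}
        lo = {"chr1": np.full(len(pos), 0.2)}
        m = MethylomeTruth({("L1", "control"): hi, ("L1", "treated"): lo},
                           frozenset(), {"chr1": np.zeros(len(pos), bool)}, 0.25)
        params = SimulationParams(rnaseq_depth=1e6, expr_beta=2.0,
                                  nb_dispersion=0.0)
        lfc = []
        for seed in range(60):
            c = simulate_rnaseq(g, m, params, ("L1", "control"), seed=seed)
            t = simulate_rnaseq(g, m, params, ("L1", "treated"), seed=seed)
            lfc.append(np.log2(t.sum() / c.sum()))
        expected = 2 * 0.6 / np.log(2)
        se = np.std(lfc, ddof=1) / np.sqrt(len(lfc))
        assert abs(np.mean(lfc) - expected) < max(3 * se, 0.01)


class TestDeterminism:
    def test_same_seed_same_study(self):
        a = simulate_study(genome_kwargs=dict(n_chrom=1, chrom_len=200_000,
                                              n_genes=10, desert_chroms=()),
                           methylome_kwargs=dict(n_regulated=3), seed=9)
        b = simulate_study(genome_kwargs=dict(n_chrom=1, chrom_len=200_000,
                                              n_genes=10, desert_chroms=()),
                           methylome_kwargs=dict(n_regulated=3), seed=9)
        pd.testing.assert_frame_equal(a.rrbs, b.rrbs)
        pd.testing.assert_frame_equal(a.rnaseq, b.rnaseq)
        for sid in a.capture:
            pd.testing.assert_frame_equal(a.capture[sid].frame, b.capture[sid].frame)

    def test_stage_rngs_are_independent_streams(self):
        assert stage_rng(1, "a").random() != stage_rng(1, "b").random()
        assert stage_rng(1, "a").random() == stage_rng(1, "a").random()

    def test_truth_tables_exported(self, tiny_study):
        tables = truth_tables(tiny_study)
        assert set(tables) == {"regulated_genes", "cpg_truth"}
        assert len(tables["regulated_genes"]) == 8
        assert tables["cpg_truth"]["affected"].sum() > 0
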
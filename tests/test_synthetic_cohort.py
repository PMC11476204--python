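"""Generator correctness: determinism, planted structure, conservation."""

import numpy as np
import pandas as pd
import pytest

from cardiosplice import (
    SimConfig,
    compute_psi,
    plant_splice_effects,
    simulate_carrier_status,
    simulate_cohort,
    simulate_expression,
    simulate_gene_models,
    simulate_junction_counts,
    simulate_variants,
)
from cardiosplice.splice_outliers import genes_to_frame, frame_to_genes


class TestGeneModels:
    def test_same_seed_identical(self):
        cfg = SimConfig(seed=1, n_genes=10)
        g1 = genes_to_frame(simulate_gene_models(cfg))
        g2 = genes_to_frame(simulate_gene_models(cfg))
        pd.testing.assert_frame_equal(g1, g2)

    def test_zero_tier1(self):
        cfg = SimConfig(seed=2, n_genes=40, frac_tier1=0.0)
        genes = simulate_gene_models(cfg)
        assert all(g.tier != 1 for g in genes)

    def test_junction_count_and_order(self):
        cfg = SimConfig(seed=3, n_genes=5, exons_per_gene=(3, 3))
        for g in simulate_gene_models(cfg):
            assert len(g.junctions) == 2
            for donor, acceptor in g.junctions:
                assert donor < acceptor

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, n_genes=0)
        with pytest.raises(ValueError):
            SimConfig(seed=1, exons_per_gene=(0, 2))

    def test_nonoverlapping_within_chromosome(self):
        genes = simulate_gene_models(SimConfig(seed=4, n_genes=50))
        by_chrom: dict[str, list] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g.span)
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2

    def test_tier2_pli_straddles_threshold(self):
        genes = simulate_gene_models(SimConfig(seed=5, n_genes=200))
        t2 = [g.pli for g in genes if g.tier == 2]
        assert any(p >= 0.9 for p in t2) and any(p < 0.9 for p in t2)

    def test_frame_roundtrip(self):
        genes = simulate_gene_models(SimConfig(seed=6, n_genes=8))
        back = frame_to_genes(genes_to_frame(genes))
        assert [g.exons for g in back] == [g.exons for g in genes]
        assert [g.tier for g in back] == [g.tier for g in genes]


class TestExpression:
    def test_sigma_zero_degenerate(self):
        cfg = SimConfig(seed=1, n_genes=20, expr_lognormal_params=(1.0, 0.0))
        genes = simulate_gene_models(cfg)
        tpm, _ = simulate_expression(genes, 10, cfg)
        assert np.allclose(tpm.std(axis=0), 0.0)

    def test_reproducible(self):
        cfg = SimConfig(seed=2, n_genes=15)
        genes = simulate_gene_models(cfg)
        t1, c1 = simulate_expression(genes, 8, cfg)
        t2, c2 = simulate_expression(genes, 8, cfg)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(c1, c2)

    def test_median_of_medians_matches_lognormal(self):
        # Monte-Carlo: the median of per-gene median TPM should sit near
        # exp(mu) of the log-TPM distribution (the low-expression subset
        # barely moves a median at 10%).
        cfg = SimConfig(seed=3, n_genes=400, expr_lognormal_params=(1.0, 0.5))
        genes = simulate_gene_models(cfg)
        tpm, _ = simulate_expression(genes, 50, cfg)
        med = np.median(tpm.median(axis=0))
        # 3 SEs of the median of 400 lognormal(1, 1.2) gene medians
        se = np.exp(1.0) * cfg.gene_mu_spread * 1.2533 / np.sqrt(400)
        assert abs(med - np.exp(1.0)) < 3 * se

    def test_low_expression_fraction_present(self):
        cfg = SimConfig(seed=4, n_genes=200)
        genes = simulate_gene_models(cfg)
        tpm, _ = simulate_expression(genes, 30, cfg)
        assert (tpm.median(axis=0) < 1).mean() >= cfg.frac_low_expr / 2


class TestVariants:
    def test_causal_enrichment_direction(self, small_cohort):
        # with coefficients (+, +, -) causal variants have larger max delta
        # and are depleted from repeat regions
        truth = small_cohort.truth
        var = small_cohort.variants.set_index("variant_id")
        var = var.loc[var["consequence"] == "splice_candidate"]
        causal = truth.loc[var.index, "causal"]
        assert causal.sum() >= 20
        maxd = var[["delta_ag", "delta_al", "delta_dg", "delta_dl"]].max(axis=1)
        assert maxd[causal].mean() > maxd[~causal].mean()
        assert var.loc[causal, "in_repeat"].mean() < var.loc[~causal, "in_repeat"].mean()
        log_tpm = np.log(small_cohort.tpm.median(axis=0) + 0.01)
        gene_ltpm = var["gene_id"].map(log_tpm)
        assert gene_ltpm[causal].mean() > gene_ltpm[~causal].mean()

    def test_null_case_excess(self):
        cfg = SimConfig(seed=5, n_case_samples=20, n_control_samples=20, n_genes=40,
                        variants_per_sample=30, synonymous_rate=0, case_excess_rate=0.0)
        genes = simulate_gene_models(cfg)
        tpm, _ = simulate_expression(genes, 20, cfg)
        cases = [f"CASE{i:03d}" for i in range(20)]
        ctrls = [f"CTRL{i:03d}" for i in range(20)]
        variants, truth = simulate_variants(genes, cases, ctrls, tpm, cfg)
        merged = variants.set_index("variant_id").join(truth)
        per_sample = merged.groupby(merged["sample"].str.split(",").str[0])["causal"].sum()
        n_case = per_sample.reindex(cases).fillna(0).sum()
        n_ctrl = per_sample.reindex(ctrls).fillna(0).sum()
        # equal cohort sizes, no excess: counts should be comparable
        assert abs(n_case - n_ctrl) < 4 * np.sqrt(n_case + n_ctrl + 1)

    def test_impossible_causality_yields_none(self):
        cfg = SimConfig(seed=6, n_case_samples=10, n_control_samples=0, n_genes=20,
                        variants_per_sample=30, synonymous_rate=0,
                        causal_logit_coefs=(-1e9, 0.0, 0.0, 0.0), case_excess_rate=0.0)
        genes = simulate_gene_models(cfg)
        tpm, _ = simulate_expression(genes, 10, cfg)
        _, truth = simulate_variants(genes, [f"CASE{i:03d}" for i in range(10)], [], tpm, cfg)
        assert truth["causal"].sum() == 0

    def test_deltas_screenable(self, small_cohort):
        var = small_cohort.variants
        cand = var.loc[var["consequence"] == "splice_candidate"]
        deltas = cand[["delta_ag", "delta_al", "delta_dg", "delta_dl"]]
        assert ((deltas >= 0) & (deltas <= 1)).all().all()
        assert (deltas.max(axis=1) >= 0.2).all()


class TestPlantedEffects:
    def test_zero_dpsi_identity(self):
        cfg = SimConfig(seed=7, n_case_samples=10, n_control_samples=0, n_genes=20,
                        variants_per_sample=20, synonymous_rate=0, planted_delta_psi=0.0,
                        nmd_shift=0.0)
        genes = simulate_gene_models(cfg)
        cases = [f"CASE{i:03d}" for i in range(10)]
        tpm, counts = simulate_expression(genes, 10, cfg)
        jcs = simulate_junction_counts(genes, cases, cfg)
        variants, truth = simulate_variants(genes, cases, [], tpm, cfg)
        perturbed, counts2, _ = plant_splice_effects(variants, truth, jcs, cfg,
                                                     gene_counts=counts)
        pd.testing.assert_frame_equal(perturbed.split_counts, jcs.split_counts)
        pd.testing.assert_frame_equal(counts2, counts)

    def test_planted_shift_recoverable_from_counts(self, small_cohort):
        # recompute ψ5 from the perturbed counts: the carrier sample at a
        # planted junction should sit ≈ planted_delta_psi below baseline
        c = small_cohort
        psi = compute_psi(c.junction_counts, "psi5")
        carriers = c.variants.set_index("variant_id")["sample"].str.split(",").str[0]
        planted = c.truth.loc[c.truth["perturbed_junction"].notna() & ~c.truth["clipped"]]
        assert len(planted) >= 10
        diffs = []
        for vid, row in planted.iterrows():
            s = carriers[vid]
            j = row["perturbed_junction"]
            others = psi.psi[j].drop(index=s).mean()
            diffs.append(others - psi.psi[j][s])
        # average observed shift within 0.05 of the planted magnitude
        assert abs(np.mean(diffs) - c.config.planted_delta_psi) < 0.05

    def test_donor_totals_conserved(self, small_cohort, small_config):
        baseline = simulate_junction_counts(
            small_cohort.genes,
            small_cohort.case_samples,
            small_config,
            np.random.default_rng(np.random.SeedSequence([small_config.seed, 3])),
        )
        key = baseline.junctions["gene_id"] + ":" + baseline.junctions["donor"].astype(str)
        tot_before = baseline.split_counts.T.groupby(key).sum().T
        tot_after = small_cohort.junction_counts.split_counts.T.groupby(key).sum().T
        pd.testing.assert_frame_equal(tot_before, tot_after)

    def test_nmd_reduces_carrier_counts(self, small_cohort):
        c = small_cohort
        nmd = c.truth.loc[c.truth["nmd_applied"]]
        assert len(nmd) > 0


class TestStarReader:
    def test_roundtrip_star_style_table(self, tmp_path, toy_gene):
        rows_s1 = [("chr1", 201, 300, 1, 1, 1, 30, 2, 20),
                   ("chr1", 401, 500, 1, 1, 1, 12, 0, 20)]
        rows_s2 = [("chr1", 201, 300, 1, 1, 1, 18, 1, 20)]
        paths = {}
        for name, rows in (("S1", rows_s1), ("S2", rows_s2)):
            p = tmp_path / f"{name}.SJ.out.tab"
            pd.DataFrame(rows).to_csv(p, sep="\t", header=False, index=False)
            paths[name] = p
        from cardiosplice.synthetic_cohort import read_star_junctions
        jcs = read_star_junctions(paths, [toy_gene])
        # intron 201-300 -> donor 200, acceptor 301 (toy_gene's first junction)
        jid = "chr1:200-301"
        assert jcs.junctions.loc[jid, "gene_id"] == "GX"
        assert jcs.split_counts.loc["S1", jid] == 30
        assert jcs.split_counts.loc["S2", jid] == 18
        assert jcs.split_counts.loc["S2", "chr1:400-501"] == 0  # absent: zero


class TestLabelRecoveryMonotonicity:
    def test_confirmed_sensitivity_grows_with_planted_effect(self):
        # the confirmed label recovers latent causality better the larger
        # the planted Δψ (3-point grid, averaged over seeds)
        from cardiosplice import (annotate_features, find_splice_outliers,
                                  label_variants, screen_variants)

        def sensitivity(dpsi, seed):
            cfg = SimConfig(seed=seed, n_case_samples=30, n_control_samples=0,
                            n_genes=60, variants_per_sample=40, synonymous_rate=0,
                            case_excess_rate=0.0, planted_delta_psi=dpsi)
            c = simulate_cohort(cfg)
            events = find_splice_outliers(c.junction_counts)
            scr = annotate_features(screen_variants(c.variants), c.genes, c.tpm)
            lab = label_variants(scr, events).set_index("variant_id")
            causal = c.truth.loc[lab.index, "causal"]
            evaluable = lab["label"] != "indeterminate"
            conf = lab["label"] == "confirmed"
            sens = (conf & causal & evaluable).sum() / max(1, (causal & evaluable).sum())
            spec = (~conf & ~causal & evaluable).sum() / max(1, (~causal & evaluable).sum())
            return sens, spec

        grid = [0.15, 0.25, 0.4]
        sens = []
        for dpsi in grid:
            vals = [sensitivity(dpsi, s) for s in (0, 1, 2)]
            sens.append(np.mean([v[0] for v in vals]))
            assert np.mean([v[1] for v in vals]) > 0.99
        # non-decreasing across the grid, strictly higher at the top
        # (recovery saturates once Δψ clears the |Δψ| >= 0.2 threshold)
        assert sens[0] <= sens[1] <= sens[2]
        assert sens[0] < sens[2]


class TestDeterminismAndCarriers:
    def test_full_cohort_determinism(self, small_config, small_cohort):
        c2 = simulate_cohort(small_config)
        pd.testing.assert_frame_equal(small_cohort.variants, c2.variants)
        pd.testing.assert_frame_equal(small_cohort.truth, c2.truth)
        pd.testing.assert_frame_equal(
            small_cohort.junction_counts.split_counts, c2.junction_counts.split_counts
        )
        pd.testing.assert_frame_equal(small_cohort.gene_counts, c2.gene_counts)

    def test_carrier_status_rates(self):
        rng = np.random.default_rng(0)
        ca, co = simulate_carrier_status(100000, 100000, carrier_rate=0.3, case_or=1.3, rng=rng)
        assert abs(co / 100000 - 0.3) < 0.01
        odds = 0.3 / 0.7 * 1.3
        assert abs(ca / 100000 - odds / (1 + odds)) < 0.01
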
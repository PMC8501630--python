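"""Cis-gene criterion, Z-transform and gene-set enrichment."""

import numpy as np
import pandas as pd
import pytest

from ascopy import (
    GeneAnnotation,
    call_cis_genes,
    cis_test,
    enrich_gene_sets,
    match_gene_copynumber,
    pvals_to_z,
)

from conftest import make_profile
from oracles import bh_adjust, hypergeom_tail

MB = 1_000_000


class TestZTransform:
    @pytest.mark.parametrize("p, z", [(0.05, 1.64), (0.5, 0.0), (0.025, 1.96)])
    def test_reference_quantiles(self, p, z):
        assert pvals_to_z(p) == pytest.approx(z, abs=0.005)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            pvals_to_z(bad)

    def test_antisymmetry_and_monotonicity(self, rng):
        ps = rng.uniform(0.001, 0.999, 50)
        for p in ps:
            assert pvals_to_z(p) + pvals_to_z(1 - p) == pytest.approx(0.0, abs=1e-9)
        zs = [pvals_to_z(p) for p in sorted(ps)]
        assert all(z1 > z2 for z1, z2 in zip(zs, zs[1:]))

    def test_p_below_005_iff_z_above_164(self, rng):
        for p in rng.uniform(0.001, 0.2, 200):
            assert (p < 0.05) == (pvals_to_z(p) > pvals_to_z(0.05))


def dosage_gene(rng, n=100, beta=1.0, sd=0.5):
    """Copy numbers 1/2/3 around diploid with expression = beta*(c-2) + noise."""
    c = rng.choice([1.0, 2.0, 3.0], size=n, p=[0.25, 0.5, 0.25])
    e = beta * (c - 2.0) + rng.normal(0, sd, n)
    calls = np.where(c > 2.5, "gain", np.where(c < 1.5, "loss", "normal"))
    return c, e, calls


class TestCisTest:
    def test_true_dosage_gene_is_cis(self, rng):
        c, e, calls = dosage_gene(rng)
        rec = cis_test(c, e, calls, gene="G")
        assert rec.cis
        assert rec.r > 0.7
        assert min(rec.p_loss, rec.p_gain) < 0.05
        assert rec.z == pytest.approx(pvals_to_z(rec.min_p))

    def test_constant_copy_number_not_cis(self, rng):
        c = np.full(50, 2.0)
        e = rng.normal(0, 1, 50)
        rec = cis_test(c, e, ["normal"] * 50, gene="G")
        assert not rec.cis and np.isnan(rec.r)

    def test_group_difference_without_correlation_fails_compound_rule(self, rng):
        # expression dips in both gain AND loss: r ~ 0 but normal-vs-gain
        # t-test is significant, so the compound rule must reject
        c = np.repeat([1.0, 2.0, 3.0], 20)
        e = np.where(c == 2.0, 1.0, 0.0) + rng.normal(0, 0.2, 60)
        calls = np.where(c == 3.0, "gain", np.where(c == 1.0, "loss", "normal"))
        rec = cis_test(c, e, calls, gene="G")
        assert rec.r <= 0.4
        assert rec.min_p < 0.05
        assert not rec.cis

    def test_small_arm_yields_missing_p(self, rng):
        c, e, calls = dosage_gene(rng, n=40)
        calls = np.where(calls == "loss", "normal", calls)  # no loss group
        rec = cis_test(c, e, calls, gene="G")
        assert np.isnan(rec.p_loss)
        assert rec.min_p == rec.p_gain

    def test_flag_invariant_under_affine_expression_transform(self, rng):
        c, e, calls = dosage_gene(rng)
        base = cis_test(c, e, calls)
        shifted = cis_test(c, 3.5 * e + 10.0, calls)
        assert base.cis == shifted.cis
        assert base.r == pytest.approx(shifted.r)
        assert base.min_p == pytest.approx(shifted.min_p)

    def test_missing_pairs_excluded(self, rng):
        c, e, calls = dosage_gene(rng, n=30)
        c[:5] = np.nan
        rec = cis_test(c, e, calls)
        assert rec.n == 25


class TestMatchGeneCopyNumber:
    def test_midpoint_decides(self):
        profile = make_profile(
            [("1", 1, 10 * MB, 2, 1), ("1", 10 * MB + 1, 20 * MB, 1, 1)], "S1")
        inside = GeneAnnotation("G1", "1", 4 * MB, 6 * MB)
        assert match_gene_copynumber(inside, [profile])["S1"] == 3.0
        # gene spans the breakpoint; midpoint at 10.5 Mb falls right of it
        spanning = GeneAnnotation("G2", "1", 9 * MB, 12 * MB)
        assert match_gene_copynumber(spanning, [profile])["S1"] == 2.0

    def test_coverage_gap_is_missing(self):
        profile = make_profile([("1", 1, 10 * MB, 1, 1)], "S1")
        gene = GeneAnnotation("G", "1", 11 * MB, 12 * MB)
        assert np.isnan(match_gene_copynumber(gene, [profile])["S1"])

    def test_absent_chromosome_all_missing(self):
        profile = make_profile([("1", 1, 10 * MB, 1, 1)], "S1")
        gene = GeneAnnotation("G", "9", 1, MB)
        assert match_gene_copynumber(gene, [profile]).isna().all()


class TestCallCisGenes:
    def test_no_shared_samples_is_error(self, demo_cohort):
        expr = demo_cohort.expression.rename(columns=lambda s: s + "_x")
        genes = [GeneAnnotation("G00000", "1", 1, MB)]
        with pytest.raises(ValueError, match="share no sample"):
            call_cis_genes(expr, demo_cohort.profiles, genes)

    def test_null_cohort_calls_at_most_two_percent(self, layout_no_y):
        from ascopy import GroupSpec, generate_cohort, synthetic_gene_annotation

        annotation = synthetic_gene_annotation(layout_no_y, n_genes=400, seed=11)
        spec = GroupSpec("null", 60, ploidy_means=(2.0,), ploidy_weights=(1.0,),
                         arm_event_rate=8.0, focal_event_rate=4.0,
                         focal_complex_rate=1.0, loh_rate=2.0, asym_rate=2.0)
        cohort = generate_cohort(layout_no_y, [spec], annotation,
                                 cis_fraction=0.0, seed=11)
        records = call_cis_genes(cohort.expression, cohort.profiles, annotation)
        frac = np.mean([r.cis for r in records])
        assert frac <= 0.02

    def test_recurrent_region_flag(self, demo_cohort):
        from ascopy.recurrence import RecurrentRegion

        genes = [GeneAnnotation("G_in", "1", 1, MB), GeneAnnotation("G_out", "2", 1, MB)]
        expr = pd.DataFrame(
            np.random.default_rng(0).normal(7, 1, size=(2, len(demo_cohort.profiles))),
            index=["G_in", "G_out"],
            columns=[p.sample for p in demo_cohort.profiles],
        )
        regions = [RecurrentRegion("1", 1, 2 * MB, "gain", 0.5, 0.4)]
        records = call_cis_genes(expr, demo_cohort.profiles, genes, regions)
        flags = {r.gene: r.in_recurrent_region for r in records}
        assert flags == {"G_in": True, "G_out": False}


class TestEnrichment:
    def test_matches_hypergeometric_tail(self):
        universe = [f"g{i}" for i in range(100)]
        gene_set = {"SET": universe[:10]}
        cis = universe[:8] + universe[50:62]  # overlap 8, cis count 20
        res = enrich_gene_sets(cis, universe, gene_set)[0]
        assert res.overlap == 8 and res.set_size == 10 and res.cis_count == 20
        assert res.p_raw == pytest.approx(hypergeom_tail(8, 10, 20, 100), rel=1e-9)

    def test_zero_overlap_is_depleted(self):
        universe = [f"g{i}" for i in range(100)]
        res = enrich_gene_sets(universe[20:40], universe, {"S": universe[:5]})[0]
        assert res.overlap == 0
        assert res.p_raw >= 0.5

    def test_bh_step_up_hand_example(self):
        universe = [f"g{i}" for i in range(200)]
        # three sets engineered to give distinct raw Ps, then check BH math
        cis = universe[:30]
        sets = {
            "A": universe[:12] + universe[100:108],
            "B": universe[:10] + universe[100:110],
            "C": universe[:8] + universe[100:112],
        }
        res = enrich_gene_sets(cis, universe, sets)
        raw = [r.p_raw for r in res]
        expected = bh_adjust(raw)
        for r, e in zip(res, expected):
            assert r.p_adjusted == pytest.approx(e, rel=1e-9)

    def test_bh_printed_arithmetic(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        assert list(np.round(adj, 10)) == [0.03, 0.03, 0.04]
        assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_random_tables_match_oracle(self, rng):
        for _ in range(40):
            universe_n = int(rng.integers(10, 200))
            universe = [f"g{i}" for i in range(universe_n)]
            set_n = int(rng.integers(1, universe_n))
            cis_n = int(rng.integers(1, universe_n))
            gene_set = {"S": list(rng.choice(universe, size=set_n, replace=False))}
            cis = list(rng.choice(universe, size=cis_n, replace=False))
            res = enrich_gene_sets(cis, universe, gene_set)[0]
            assert res.p_raw == pytest.approx(
                hypergeom_tail(res.overlap, set_n, cis_n, universe_n), rel=1e-9)

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError):
            enrich_gene_sets(["a"], [], {"S": ["a"]})
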
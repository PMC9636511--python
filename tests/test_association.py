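import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from mirsnp import association as assoc
from mirsnp.io_model import (
    GenotypeMatrix,
    MISSING,
    PipelineConfig,
    SampleRecord,
    Status,
    VariantRecord,
)
from mirsnp.simulate import SimulationSpec, simulate_cohort, simulate_panel

GC = assoc.GenotypeCounts


class TestHWE:
    def test_control_counts_reproduce_reported_p(self):
        # published control genotype distributions of two 3'UTR variants
        assert assoc.hwe_test(GC(73, 111, 25)).p == pytest.approx(0.079, abs=5e-4)
        assert assoc.hwe_test(GC(61, 110, 28)).p == pytest.approx(0.054, abs=5e-4)

    def test_exact_hw_proportions_give_zero_chi2(self):
        res = assoc.hwe_test(GC(25, 50, 25))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_expected_counts_sum_to_total(self):
        res = assoc.hwe_test(GC(73, 111, 25))
        assert sum(res.expected) == pytest.approx(209, abs=1e-9)

    def test_monomorphic_flagged_undefined(self):
        res = assoc.hwe_test(GC(0, 0, 120))  # the all-homozygote scenario
        assert not res.defined
        assert "monomorphic" in res.note

    def test_invariant_under_hom_class_swap(self):
        a = assoc.hwe_test(GC(73, 111, 25))
        b = assoc.hwe_test(GC(25, 111, 73))
        assert a.chi2 == pytest.approx(b.chi2)
        assert a.p == pytest.approx(b.p)

    def test_type_one_error_calibrated(self, rng):
        # genotypes simulated under HW: n=200, MAF 0.3, 2000 replicates
        n, maf, reps = 200, 0.3, 2000
        rejections = 0
        for _ in range(reps):
            g = rng.binomial(1, maf, size=(n, 2)).sum(axis=1)
            counts = GC(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
            if counts.monomorphic:
                continue
            if assoc.hwe_test(counts).p < 0.05:
                rejections += 1
        lo, hi = st.binom.interval(0.99, reps, 0.05)
        assert lo <= rejections <= hi


class TestAlleleCountsAndModels:
    def test_published_allele_counts(self):
        assert assoc.allele_counts(GC(72, 102, 31)) == (246, 164)
        assert assoc.allele_counts(GC(74, 98, 34)) == (246, 166)

    def test_all_alt_hom(self):
        assert assoc.allele_counts(GC(0, 0, 12)) == (0, 24)

    def test_published_dominant_cells(self):
        t = assoc.model_table(GC(72, 102, 31), GC(73, 111, 25), "dominant")
        np.testing.assert_array_equal(t.table, [[133, 72], [136, 73]])

    def test_published_overdominant_cells(self):
        t = assoc.model_table(GC(74, 98, 34), GC(61, 110, 28), "overdominant")
        np.testing.assert_array_equal(t.table, [[98, 108], [110, 89]])

    def test_symmetric_groups_identical_rows(self):
        c = GC(30, 40, 30)
        for model in ("dominant", "recessive", "overdominant", "allelic"):
            t = assoc.model_table(c, c, model)
            np.testing.assert_array_equal(t.table[0], t.table[1])

    def test_cell_sums_equal_group_totals(self):
        case, control = GC(72, 102, 31), GC(73, 111, 25)
        for model in ("dominant", "recessive", "overdominant"):
            t = assoc.model_table(case, control, model)
            assert t.table[0].sum() == case.total
            assert t.table[1].sum() == control.total
        t = assoc.model_table(case, control, "allelic")
        assert t.table[0].sum() == 2 * case.total
        assert t.table[1].sum() == 2 * control.total

    def test_codominant_pairs_use_named_classes_only(self):
        case, control = GC(72, 102, 31), GC(73, 111, 25)
        t = assoc.model_table(case, control, "codominant", ("ref_hom", "alt_hom"))
        np.testing.assert_array_equal(t.table, [[31, 72], [25, 73]])


class TestCrudeOR:
    def test_allelic_cross_product(self):
        res = assoc.crude_or(np.array([[164, 246], [161, 257]]))
        assert res.or_point == pytest.approx(1.064, abs=5e-4)

    def test_unit_or(self):
        res = assoc.crude_or(np.array([[10, 10], [10, 10]]))
        assert res.or_point == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_haldane_correction_applied_and_flagged(self):
        res = assoc.crude_or(np.array([[0, 202], [6, 190]]))
        expected = (0.5 * 190.5) / (202.5 * 6.5)
        assert res.corrected
        assert res.or_point == pytest.approx(expected)

    def test_zero_margin_undefined(self):
        res = assoc.crude_or(np.array([[0, 10], [0, 12]]))
        assert not res.defined

    def test_exposure_inversion_reciprocal(self, rng):
        for _ in range(10):
            t = rng.integers(1, 60, size=(2, 2))
            a = assoc.crude_or(t)
            b = assoc.crude_or(t[:, ::-1])
            assert b.or_point == pytest.approx(1 / a.or_point)
            assert b.ci_low == pytest.approx(1 / a.ci_high)
            assert b.ci_high == pytest.approx(1 / a.ci_low)


class TestLogistic:
    def test_saturated_identity_with_crude_or(self, rng):
        # binary exposure only: exp(beta) equals cross-product OR
        x = rng.binomial(1, 0.4, size=400)
        y = rng.binomial(1, np.where(x == 1, 0.6, 0.4))
        if y.min() == y.max():
            pytest.skip("degenerate draw")
        res = assoc.adjusted_or(y, x)
        a = int(((x == 1) & (y == 1)).sum())
        b = int(((x == 0) & (y == 1)).sum())
        c = int(((x == 1) & (y == 0)).sum())
        d = int(((x == 0) & (y == 0)).sum())
        crude = (a * d) / (b * c)
        assert res.or_point == pytest.approx(crude, abs=1e-6)

    def test_simulation_recovery(self, rng):
        n, beta = 5000, math.log(1.5)
        x = rng.binomial(1, 0.4, size=n)
        p = 1 / (1 + np.exp(-(-0.5 + beta * x)))
        y = rng.binomial(1, p)
        fit = assoc.logistic_fit(y, x[:, None], names=["x"])
        assert fit.params[1] == pytest.approx(beta, abs=0.15)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.binomial(1, 0.5, size=100).astype(float)
        X = np.column_stack([x, x * 2])
        y = rng.binomial(1, 0.5, size=100)
        with pytest.raises(ValueError, match="rank deficient"):
            assoc.logistic_fit(y, X, names=["a", "a_doubled"])

    def test_complete_separation_flagged(self):
        x = np.array([0.0] * 25 + [1.0] * 25)
        y = np.array([0.0] * 25 + [1.0] * 25)
        res = assoc.adjusted_or(y, x)
        assert not res.defined
        assert "separation" in res.note

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            assoc.logistic_fit(np.ones(10), np.arange(10.0)[:, None])

    def test_wald_type_one_error_calibrated(self, rng):
        # null simulation: beta = 0, 500 replicates at n = 1000
        reps, n = 500, 1000
        rejections = 0
        for _ in range(reps):
            x = rng.binomial(1, 0.4, size=n).astype(float)
            y = rng.binomial(1, 0.5, size=n).astype(float)
            res = assoc.adjusted_or(y, x)
            if res.defined and res.p < 0.05:
                rejections += 1
        lo, hi = st.binom.interval(0.99, reps, 0.05)
        assert lo <= rejections <= hi


def fisher_enumeration(table):
    """Independent two-sided Fisher oracle by full hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    p_obs = st.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = st.hypergeom.pmf(x, n, r1, c1)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


class TestExactAndChi2:
    def test_fisher_hand_case(self):
        two, one = assoc.fisher_exact(np.array([[5, 1], [1, 5]]))
        assert two == pytest.approx(0.0801, abs=5e-4)
        assert one <= two

    def test_fisher_zero_margin(self):
        assert assoc.fisher_exact(np.array([[0, 0], [3, 4]])) == (1.0, 1.0)

    def test_fisher_matches_enumeration_oracle(self, rng):
        for _ in range(100):
            t = rng.integers(0, 12, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            two, _ = assoc.fisher_exact(t)
            assert two == pytest.approx(fisher_enumeration(t), abs=1e-9)

    def test_pearson_hand_case(self):
        chi2, df, p = assoc.pearson_chi2(np.array([[10, 20], [20, 10]]))
        assert chi2 == pytest.approx(6.667, abs=1e-3)
        assert df == 1
        assert p == pytest.approx(0.0098, abs=2e-4)

    def test_pearson_table_equal_to_expected(self):
        chi2, _, p = assoc.pearson_chi2(np.array([[10, 10], [10, 10]]))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_pearson_row_swap_invariance(self, rng):
        t = rng.integers(1, 30, size=(2, 4))
        a = assoc.pearson_chi2(t)
        b = assoc.pearson_chi2(t[::-1])
        assert a == pytest.approx(b)

    def test_pearson_zero_expected_suggests_fisher(self):
        with pytest.raises(ValueError, match="[Ff]isher"):
            assoc.pearson_chi2(np.array([[0, 5], [0, 7]]))


def make_gm(codes):
    codes = np.asarray(codes, dtype=np.int8)
    variants = [VariantRecord("rsA", "chr1", 100, "G", "A"),
                VariantRecord("rsB", "chr1", 200, "G", "A")]
    return GenotypeMatrix([f"S{i}" for i in range(codes.shape[0])], variants, codes)


class TestCumulativeGenotypes:
    def test_single_class_frequency_one(self):
        gm = make_gm(np.zeros((10, 2)))
        groups = {"g": np.ones(10, dtype=bool)}
        cum = assoc.cumulative_genotypes(gm, 0, 1, groups)
        assert cum.genotype_freqs.loc["GG/GG", "g"] == pytest.approx(1.0)
        assert cum.genotype_freqs["g"].sum() == pytest.approx(1.0)

    def test_frequencies_recover_known_joint_distribution(self, rng):
        spec = SimulationSpec(n_variants=2, mafs=[0.4, 0.4],
                              target_ld=[(0, 1, 0.8)], rng_seed=3)
        panel = simulate_panel(spec, n_chromosomes=10_000)  # 5,000 individuals
        codes = (panel.alleles[:, 0::2] + panel.alleles[:, 1::2]).T
        gm = make_gm(codes)
        n = codes.shape[0]
        groups = {"a": np.arange(n) < n // 2, "b": np.arange(n) >= n // 2}
        cum = assoc.cumulative_genotypes(gm, 0, 1, groups)
        # both halves drawn from the same distribution: frequencies agree
        np.testing.assert_allclose(
            cum.genotype_freqs["a"], cum.genotype_freqs["b"], atol=0.04
        )
        for g in ("a", "b"):
            assert cum.genotype_freqs[g].sum() == pytest.approx(1.0, abs=1e-6)
            assert cum.hap_freqs[g].sum() == pytest.approx(1.0, abs=1e-6)

    def test_empty_group_excluded_with_warning(self):
        gm = make_gm(np.zeros((6, 2)))
        groups = {"full": np.ones(6, dtype=bool), "empty": np.zeros(6, dtype=bool)}
        with pytest.warns(UserWarning, match="no complete cases"):
            cum = assoc.cumulative_genotypes(gm, 0, 1, groups)
        assert cum.excluded_groups == ["empty"]

    def test_complete_case_denominator(self):
        codes = np.zeros((8, 2), dtype=np.int8)
        codes[0, 1] = MISSING
        gm = make_gm(codes)
        cum = assoc.cumulative_genotypes(gm, 0, 1, {"g": np.ones(8, dtype=bool)})
        assert cum.group_sizes["g"] == 7


def cohort(spec):
    panel = simulate_panel(spec, n_chromosomes=max(1000, 2 * spec.n_individuals))
    return simulate_cohort(spec, panel)


class TestSuite:
    def test_deterministic_rerun(self):
        spec = SimulationSpec(n_individuals=200, n_variants=2, rng_seed=5)
        gm, samples, _ = cohort(spec)
        a = assoc.run_association_suite(gm, samples)
        b = assoc.run_association_suite(gm, samples)
        for key in a:
            pd.testing.assert_frame_equal(a[key], b[key])

    def test_monomorphic_variant_flagged_not_crashing(self):
        spec = SimulationSpec(n_individuals=120, n_variants=2, rng_seed=5)
        gm, samples, _ = cohort(spec)
        gm.codes[:, 1] = 2  # plant an all-homozygote variant
        tables = assoc.run_association_suite(gm, samples)
        rows = tables["association"]
        flagged = rows[(rows.variant == gm.variants[1].id)]
        assert (flagged.note == "monomorphic: not analyzable").any()
        hwe_rows = tables["hwe"][tables["hwe"].variant == gm.variants[1].id]
        assert (~hwe_rows.defined).all()

    def test_dominant_effect_recovered_in_suite(self):
        spec = SimulationSpec(n_individuals=4000, n_variants=1, mafs=[0.35],
                              effects=[(0, "dominant", 2.0)], rng_seed=17)
        gm, samples, _ = cohort(spec)
        tables = assoc.run_association_suite(gm, samples)
        row = tables["association"].query(
            "contrast == 'crc_vs_control' and model == 'dominant'"
        ).iloc[0]
        assert 1.6 < row.or_crude < 2.5
        assert row.ci_low < 2.0 < row.ci_high

    def test_small_stratum_skipped(self):
        spec = SimulationSpec(n_individuals=60, n_variants=1,
                              bmi_fractions=(0.9, 0.08, 0.02), rng_seed=2)
        gm, samples, _ = cohort(spec)
        tables = assoc.run_association_suite(gm, samples)
        assert len(tables["skipped"]) > 0
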
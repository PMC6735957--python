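import numpy as np
import pandas as pd
import pytest

from lncforge.genome_model_io import SampleTable
from lncforge.synthetic_fixtures import (
    generate_expression_cohort,
    generate_survival,
)
from lncforge.trait_association import (
    GwasSnp,
    SurvivalResult,
    TraitModelSpec,
    bh_fdr,
    clinical_outcome_association,
    cox_survival,
    differential_expression,
    fit_trait_lmm,
    gwas_overlap_count,
    km_median_split,
    tissue_enrichment_or,
)
from conftest import make_transcript


def survival_samples(expr, surv, seed=0, tissue="tumorT"):
    rng = np.random.default_rng(seed)
    n = len(expr)
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": expr.index,
                "individual_id": [f"I{i:05d}" for i in range(n)],
                "tissue": tissue,
                "sex": rng.choice(["male", "female"], n),
                "age": rng.integers(30, 80, n),
                "race": rng.choice(["groupA", "groupB"], n),
                "condition": "tumor",
                "survival_time": np.asarray(surv["survival_time"]),
                "event": np.asarray(surv["event"]),
            }
        )
    )


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_brute_force_oracle(self, rng):
        # oracle: fdr_(i) = min over j >= i of p_(j) * m / j  (sorted order)
        for _ in range(50):
            m = int(rng.integers(1, 30))
            p = rng.uniform(0, 1, size=m)
            got = bh_fdr(p)
            order = np.argsort(p)
            sorted_p = p[order]
            expected_sorted = np.empty(m)
            for i in range(m):
                expected_sorted[i] = min(
                    min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0
                )
            expected = np.empty(m)
            expected[order] = expected_sorted
            assert got == pytest.approx(expected)


class TestFitTraitLmm:
    def test_constant_expression_null_effects(self):
        m, samples, _ = generate_expression_cohort(
            ["t0"], n_individuals=10, tissues=("a", "b"),
            individual_sd=0.0, residual_sd=0.0, seed=1,
        )
        resp = np.log(m.row("t0"))
        results = fit_trait_lmm(TraitModelSpec("t0", resp, samples))
        assert results  # at least one covariate modelled
        for r in results:
            assert r.estimate == pytest.approx(0.0)
            assert r.p_value == pytest.approx(1.0)

    def test_sex_effect_recovery(self):
        m, samples, _ = generate_expression_cohort(
            ["t0"], n_individuals=100, tissues=("tissueA", "tissueB"),
            sex_effects={"t0": 2.0}, individual_sd=0.3, residual_sd=0.5, seed=7,
        )
        resp = np.log(m.row("t0"))
        results = fit_trait_lmm(TraitModelSpec("t0", resp, samples))
        sex_terms = [r for r in results if r.covariate.startswith("sex[")]
        assert len(sex_terms) == 1
        r = sex_terms[0]
        assert r.flag is None
        # +2.0 was injected for males; sign depends on the reference level
        expected = 2.0 if "[male]" in r.covariate else -2.0
        assert r.estimate == pytest.approx(expected, abs=0.15)
        assert r.p_value < 1e-10

    def test_single_level_covariate_dropped_with_warning(self):
        m, samples, _ = generate_expression_cohort(
            ["t0"], n_individuals=10, tissues=("onlyone",), seed=2
        )
        resp = np.log(m.row("t0"))
        with pytest.warns(UserWarning, match="tissue"):
            results = fit_trait_lmm(TraitModelSpec("t0", resp, samples))
        assert not any(r.covariate.startswith("tissue") for r in results)

    def test_requires_two_individuals(self):
        m, samples, _ = generate_expression_cohort(
            ["t0"], n_individuals=1, tissues=("a", "b"), seed=3
        )
        with pytest.raises(ValueError, match="individuals"):
            fit_trait_lmm(TraitModelSpec("t0", np.log(m.row("t0")), samples))

    @pytest.mark.slow
    def test_null_type_i_error_within_binomial_tolerance(self):
        # 500 zero-effect transcripts; empirical alpha must sit within a
        # 3-sigma binomial band around the nominal 0.05
        m, samples, _ = generate_expression_cohort(
            [f"t{i}" for i in range(500)], n_individuals=40, tissues=("a", "b"),
            seed=99,
        )
        pvals = []
        for tid in m.transcript_ids:
            for r in fit_trait_lmm(
                TraitModelSpec(tid, np.log(m.row(tid)), samples)
            ):
                if r.covariate.startswith("sex[") and r.flag is None:
                    pvals.append(r.p_value)
        frac = np.mean(np.array(pvals) < 0.05)
        tol = 3 * np.sqrt(0.05 * 0.95 / len(pvals))
        assert abs(frac - 0.05) < tol


class TestDifferentialExpression:
    def _cohort(self, n_transcripts, effects, seed, n_individuals=30):
        tids = [f"t{i}" for i in range(n_transcripts)]
        return generate_expression_cohort(
            tids,
            n_individuals=n_individuals,
            tissues=("liver",),
            conditions=("normal", "tumor"),
            condition_effects=effects,
            residual_sd=0.2,
            individual_sd=0.1,
            seed=seed,
        )

    def test_fold_change_boundary_is_strict(self):
        # FC exactly 1.5 must fail the strict > 1.5 gate
        fc = pd.Series([1.5])
        sym = np.maximum(fc, 1.0 / fc)
        assert not bool((sym > 1.5).iloc[0])

    @pytest.mark.slow
    def test_planted_fourfold_effects_recovered(self):
        effects = {f"t{i}": np.log(4.0) for i in range(10)}
        m, samples, _ = self._cohort(100, effects, seed=21)
        df = differential_expression(m, samples, "liver")
        called = set(df.loc[df["de_call"], "transcript_id"])
        assert len(called & set(effects)) >= 9
        false_calls = called - set(effects)
        assert len(false_calls) <= 2  # expected 0 at FDR 0.05, tolerate noise

    @pytest.mark.slow
    def test_null_fixture_false_call_fraction(self):
        m, samples, _ = self._cohort(100, {}, seed=22)
        df = differential_expression(m, samples, "liver")
        assert df["de_call"].mean() <= 0.05

    def test_direction_and_fc(self):
        effects = {"t0": np.log(4.0)}
        m, samples, _ = self._cohort(3, effects, seed=23, n_individuals=20)
        df = differential_expression(m, samples, "liver").set_index("transcript_id")
        assert df.loc["t0", "fold_change"] > 1.5
        assert df.loc["t0", "direction"] == "up"

    def test_single_condition_tissue_is_error(self):
        m, samples, _ = generate_expression_cohort(
            ["t0"], n_individuals=5, tissues=("liver",), conditions=("normal",), seed=4
        )
        with pytest.raises(ValueError, match="tumor and normal"):
            differential_expression(m, samples, "liver")


class TestClinicalOutcome:
    def _outcome_fixture(self, effects, seed, baselines=None, n_individuals=25):
        """Tumor cohort where each individual has one sample per outcome state."""
        tids = sorted(set(list(effects) + list(baselines or {})))
        m, samples, _ = generate_expression_cohort(
            tids,
            n_individuals=n_individuals,
            tissues=("kidney",),
            conditions=("normal", "tumor"),
            condition_effects=effects,
            residual_sd=0.25,
            individual_sd=0.1,
            seed=seed,
        )
        tab = samples.table.copy()
        tab["metastasis"] = (tab["condition"] == "tumor").astype(int)
        tab["condition"] = "tumor"
        if baselines:
            vals = m.values.copy()
            for tid, base in baselines.items():
                vals.loc[tid] = vals.loc[tid] * base
            from lncforge.genome_model_io import ExpressionMatrix

            m = ExpressionMatrix(vals)
        return m, SampleTable(tab)

    def test_moderate_filter_gate(self):
        # strong effect but expression ~1e-4 FPKM: never retained
        m, samples = self._outcome_fixture(
            {"t0": np.log(3.0)}, seed=31, baselines={"t0": 1e-4}
        )
        df = clinical_outcome_association(m, samples, "metastasis", tissue="kidney")
        row = df.set_index("transcript_id").loc["t0"]
        assert not row["expressed"]
        assert not row["retained"]

    def test_planted_recurrence_effect_retained(self):
        tids = {f"t{i}": 0.0 for i in range(8)}
        tids["t0"] = np.log(3.0)
        m, samples = self._outcome_fixture(tids, seed=32)
        tab = samples.table.rename(columns={"metastasis": "recurrence"})
        df = clinical_outcome_association(m, SampleTable(tab), "recurrence", tissue="kidney")
        row = df.set_index("transcript_id").loc["t0"]
        assert row["retained"]

    def test_stage_has_no_fold_change_gate(self):
        # modest ordered stage slope: significant but far below FC 1.5
        rng = np.random.default_rng(33)
        n_ind = 40
        rows, expr = [], []
        for i in range(n_ind):
            stage = int(rng.integers(1, 5))
            b = rng.normal(0, 0.05)
            for k in range(2):
                sid = f"S{i:03d}_{k}"
                rows.append(
                    {
                        "sample_id": sid,
                        "individual_id": f"I{i:03d}",
                        "tissue": "kidney",
                        "sex": ["male", "female"][i % 2],
                        "age": 40 + (i % 30),
                        "race": ["groupA", "groupB", "groupC"][i % 3],
                        "condition": "tumor",
                        "stage": stage,
                    }
                )
                expr.append((sid, np.exp(1.0 + 0.1 * stage + b + rng.normal(0, 0.1))))
        samples = SampleTable(pd.DataFrame(rows))
        from lncforge.genome_model_io import ExpressionMatrix

        m = ExpressionMatrix(
            pd.DataFrame(
                [[v for _, v in expr]], index=["t0"], columns=[s for s, _ in expr]
            )
        )
        df = clinical_outcome_association(m, samples, "stage", tissue="kidney")
        row = df.set_index("transcript_id").loc["t0"]
        assert row["fdr"] < 0.05
        assert row["retained"]  # retained despite tiny per-stage fold change

    def test_missing_outcome_column_is_error(self):
        m, samples = self._outcome_fixture({"t0": 0.0}, seed=34)
        with pytest.raises(KeyError, match="recurrence"):
            clinical_outcome_association(m, samples, "recurrence")


class TestCoxSurvival:
    def test_null_hr_near_one(self):
        rng = np.random.default_rng(2)
        expr = pd.Series(rng.normal(0, 1, 250), index=[f"S{i:05d}" for i in range(250)])
        surv = generate_survival(expr, log_hr=0.0, seed=3)
        r = cox_survival(expr, survival_samples(expr, surv, seed=4))
        assert r.flag is None
        assert 0.8 <= r.hazard_ratio <= 1.25
        assert r.p_value > 0.05

    def test_hr_recovery(self):
        rng = np.random.default_rng(5)
        expr = pd.Series(rng.normal(0, 1, 300), index=[f"S{i:05d}" for i in range(300)])
        surv = generate_survival(expr, log_hr=0.7, seed=9)
        r = cox_survival(expr, survival_samples(expr, surv, seed=6))
        true_hr = np.exp(0.7)
        assert abs(r.hazard_ratio - true_hr) / true_hr <= 0.15

    def test_direction_rule(self):
        assert SurvivalResult("t", 0.5, 0.01).direction == "protective"
        assert SurvivalResult("t", 2.0, 0.01).direction == "risky"

    def test_no_events_is_error(self):
        expr = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        surv = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "survival_time": [1, 2, 3], "event": [0, 0, 0]}
        )
        with pytest.raises(ValueError, match="event"):
            cox_survival(expr, survival_samples(expr, surv, seed=7))

    def test_one_sample_per_individual(self):
        # duplicate individuals: only the lexicographically first sample counts
        rng = np.random.default_rng(8)
        n = 60
        expr = pd.Series(rng.normal(0, 1, n), index=[f"S{i:03d}" for i in range(n)])
        surv = generate_survival(expr, log_hr=0.0, seed=8)
        samples = survival_samples(expr, surv, seed=9)
        tab = samples.table.copy()
        tab["individual_id"] = [f"I{i // 2:03d}" for i in range(n)]  # pairs
        r = cox_survival(expr, SampleTable(tab))
        assert r.flag is None  # fits on the 30 deduplicated patients


class TestKmMedianSplit:
    def test_identical_survival_p_near_one(self):
        expr = pd.Series(
            np.arange(40, dtype=float), index=[f"S{i:03d}" for i in range(40)]
        )
        surv = pd.DataFrame(
            {"sample_id": expr.index, "survival_time": 5.0, "event": 1}
        )
        km = km_median_split(expr, survival_samples(expr, surv, seed=1))
        assert km["p_value"] == pytest.approx(1.0)

    def test_separated_hazards_significant(self):
        rng = np.random.default_rng(11)
        expr = pd.Series(rng.normal(0, 1, 200), index=[f"S{i:04d}" for i in range(200)])
        surv = generate_survival(expr, log_hr=1.2, seed=12)
        km = km_median_split(expr, survival_samples(expr, surv, seed=13))
        assert km["p_value"] < 0.01

    def test_median_over_patients_with_survival_only(self):
        # patients lacking survival info are excluded before the median split
        expr = pd.Series(
            [0.0, 1.0, 2.0, 3.0, 10.0, 11.0, 12.0, 13.0],
            index=[f"S{i}" for i in range(8)],
        )
        surv = pd.DataFrame(
            {
                "sample_id": expr.index,
                "survival_time": [np.nan, np.nan, np.nan, np.nan, 1.0, 2.0, 3.0, 4.0],
                "event": [np.nan, np.nan, np.nan, np.nan, 1, 1, 0, 1],
            }
        )
        samples = survival_samples(expr, surv, seed=2)
        km = km_median_split(expr, samples)
        # median over the 4 informative patients (10..13) = 11.5, not 6.5
        assert km["median"] == pytest.approx(11.5)
        assert km["n_high"] == 2 and km["n_low"] == 2

    def test_degenerate_group_is_error(self):
        expr = pd.Series([1.0, 1.0, 1.0, 2.0], index=list("abcd"))
        surv = pd.DataFrame(
            {"sample_id": list("abcd"), "survival_time": [1, 2, 3, 4], "event": [1, 1, 1, 1]}
        )
        with pytest.raises(ValueError, match="group"):
            km_median_split(expr, survival_samples(expr, surv, seed=3))


class TestTissueEnrichment:
    def test_worked_example(self):
        r = tissue_enrichment_or(5, 10, 2, 40, tissue="brain")
        assert r.odds_ratio == pytest.approx(10.0)
        assert 0.0 <= r.p_value <= 1.0

    def test_equal_proportions_or_one(self):
        r = tissue_enrichment_or(3, 9, 6, 18)
        assert r.odds_ratio == pytest.approx(1.0)

    def test_zero_numerator(self):
        assert tissue_enrichment_or(0, 10, 2, 40).odds_ratio == 0.0

    def test_zero_denominator_or_undefined_but_p_computed(self):
        r = tissue_enrichment_or(5, 0, 2, 40)
        assert np.isnan(r.odds_ratio)
        assert 0.0 <= r.p_value <= 1.0

    def test_or_above_one_iff_rate_higher(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(1, 50, size=4))
            r = tissue_enrichment_or(a, b, c, d)
            assert (r.odds_ratio > 1) == (a / (a + b) > c / (c + d))


class TestGwasOverlap:
    transcript = staticmethod(
        lambda: make_transcript(exons=((1_000, 1_200), (2_000, 2_200)))
    )

    def test_outside_locus(self):
        n, hits = gwas_overlap_count(self.transcript(), [GwasSnp("rs1", "chr1", 5_000)])
        assert n == 0 and hits == []

    def test_intronic_snp_counted(self):
        n, _ = gwas_overlap_count(self.transcript(), [GwasSnp("rs1", "chr1", 1_500)])
        assert n == 1

    def test_locus_boundaries_inclusive(self):
        snps = [
            GwasSnp("at_start", "chr1", 1_000),
            GwasSnp("at_end", "chr1", 2_200),
            GwasSnp("before", "chr1", 999),
            GwasSnp("after", "chr1", 2_201),
        ]
        n, hits = gwas_overlap_count(self.transcript(), snps)
        assert n == 2
        assert {s.id for s in hits} == {"at_start", "at_end"}

    def test_other_chrom_ignored(self):
        n, _ = gwas_overlap_count(self.transcript(), [GwasSnp("rs1", "chr2", 1_500)])
        assert n == 0

    def test_position_validation(self):
        with pytest.raises(ValueError):
            GwasSnp("rs1", "chr1", 0)
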
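"""Diagnostic-accuracy statistics: identities, Wilson CIs, McNemar oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from triage24 import (
    ConfusionTable,
    TriageCategory,
    confusion,
    diagnostic_odds_ratio,
    dor_from_rates,
    mcnemar,
    npv,
    number_needed_to_assess,
    overtriage,
    ppv,
    ppv_from_rates,
    report,
    sensitivity,
    specificity,
    undertriage,
)
from triage24.metrics import UndefinedMetricError
from triage24.simulate import generate, load_preset

P1, P2, P3, DEAD = (TriageCategory.P1, TriageCategory.P2, TriageCategory.P3,
                    TriageCategory.DEAD)

tables = st.builds(
    ConfusionTable,
    tp=st.integers(1, 500), fp=st.integers(1, 500),
    fn=st.integers(1, 500), tn=st.integers(1, 500))


class TestConfusion:
    def test_perfect_two_record_case(self):
        t = confusion([P1, P2], [True, False])
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 0, 0, 1)

    def test_inverted_case(self):
        t = confusion([P3, P1], [True, False])
        assert (t.fn, t.fp) == (1, 1)

    def test_dead_collapses_to_not_p1(self):
        assert confusion([DEAD], [True]).fn == 1

    def test_counts_sum_to_length(self):
        t = confusion([P1, P2, P3, DEAD, P1], [True, True, False, False, True])
        assert t.total == 5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([P1], [True, False])


class TestProportionMetrics:
    def test_symmetric_sensitivity(self):
        assert sensitivity(ConfusionTable(tp=50, fp=0, fn=50, tn=1)).value == 0.5

    def test_registry_scale_sensitivity(self):
        # 1215 of 1738 true-P1 identified: the 69.9% operating-point round trip
        est = sensitivity(ConfusionTable(tp=1215, fp=10, fn=523, tn=10))
        assert est.value == pytest.approx(0.699, abs=5e-4)

    def test_zero_sensitivity_has_zero_lower_bound(self):
        est = sensitivity(ConfusionTable(tp=0, fp=1, fn=10, tn=1))
        assert est.value == 0.0 and est.ci_low == 0.0

    def test_zero_margin_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            specificity(ConfusionTable(tp=5, fp=0, fn=5, tn=0))

    @given(tables)
    def test_wilson_interval_contains_estimate_within_unit_range(self, t):
        for metric in (sensitivity, specificity, ppv, npv):
            est = metric(t)
            assert 0.0 <= est.ci_low <= est.value <= est.ci_high <= 1.0
            assert est.method == "wilson"


class TestOddsRatio:
    @pytest.mark.parametrize("sens, spec, expected", [
        (0.699, 0.653, 4.37),   # published military-registry MPTT row
        (0.432, 0.937, 11.29),  # published military-registry Sieve row
        (0.5, 0.5, 1.0),
    ])
    def test_rate_identity_matches_published_column(self, sens, spec, expected):
        assert dor_from_rates(sens, spec) == pytest.approx(expected, rel=0.01)

    def test_boundary_rates_rejected(self):
        with pytest.raises(ValueError):
            dor_from_rates(1.0, 0.5)

    @given(tables)
    def test_rate_identity_equals_cell_identity(self, t):
        """dor_from_rates on a table's own rates equals (tp*tn)/(fp*fn)."""
        s, p = sensitivity(t).value, specificity(t).value
        if 0 < s < 1 and 0 < p < 1:
            assert dor_from_rates(s, p) == pytest.approx(
                (t.tp * t.tn) / (t.fp * t.fn), rel=1e-9)

    @given(tables)
    def test_woolf_interval_brackets_odds_ratio(self, t):
        est = diagnostic_odds_ratio(t)
        assert est.ci_low <= est.value <= est.ci_high
        assert est.method == "woolf-log"


class TestPredictiveValue:
    @pytest.mark.parametrize("sens, spec, prev, expected", [
        (0.699, 0.653, 0.476, 0.648),  # military-like prevalence
        (0.578, 0.715, 0.195, 0.329),  # civilian-like prevalence
        (0.3, 1.0, 0.7, 1.0),          # perfect specificity
    ])
    def test_bayes_identity_matches_published_column(self, sens, spec, prev, expected):
        assert ppv_from_rates(sens, spec, prev) == pytest.approx(expected, rel=0.01)

    def test_degenerate_prevalence_rejected(self):
        with pytest.raises(ValueError):
            ppv_from_rates(0.7, 0.7, 0.0)

    @given(tables)
    def test_bayes_closure_on_count_tables(self, t):
        """ppv_from_rates on a table's own rates and prevalence equals tp/(tp+fp)."""
        s, p = sensitivity(t).value, specificity(t).value
        prev = (t.tp + t.fn) / t.total
        if 0 < s and 0 < p < 1:
            assert ppv_from_rates(s, p, prev) == pytest.approx(
                t.tp / (t.tp + t.fp), rel=1e-9)


class TestTriageRates:
    def test_overtriage_is_one_minus_ppv(self):
        t = ConfusionTable(tp=34, fp=66, fn=10, tn=10)  # PPV 0.340
        assert overtriage(t) == pytest.approx(0.660)

    def test_undertriage_zero_at_perfect_sensitivity(self):
        assert undertriage(ConfusionTable(tp=10, fp=1, fn=0, tn=5)) == 0.0

    @pytest.mark.parametrize("delta, expected", [
        (0.032, 31.25),  # ~30 genuine P1 casualties per extra missed one
        (0.5, 2.0),
        (0.01, 100.0),
    ])
    def test_number_needed_to_assess(self, delta, expected):
        assert number_needed_to_assess(delta) == pytest.approx(expected)

    def test_non_positive_delta_rejected(self):
        with pytest.raises(ValueError):
            number_needed_to_assess(0.0)


def _paired_vectors(b: int, c: int):
    """Prediction vectors with exactly b (A-correct, B-wrong) and c reversed."""
    truth = [True] * (b + c)
    pred_a = [P1] * b + [P2] * c
    pred_b = [P2] * b + [P1] * c
    return pred_a, pred_b, truth


class TestMcNemar:
    def test_chi_square_case(self):
        cmp_ = mcnemar(*_paired_vectors(10, 20))
        assert (cmp_.b, cmp_.c) == (10, 20)
        assert cmp_.statistic == pytest.approx(10 / 3, rel=1e-6)
        assert cmp_.p_value == pytest.approx(0.0679, abs=2e-3)
        assert cmp_.method == "chi-square"

    def test_balanced_discordance_is_null(self):
        cmp_ = mcnemar(*_paired_vectors(20, 20))
        assert cmp_.p_value >= 0.99

    def test_identical_predictions_give_p_one(self):
        preds = [P1, P2, P1]
        cmp_ = mcnemar(preds, preds, [True, False, False])
        assert (cmp_.b, cmp_.c, cmp_.p_value) == (0, 0, 1.0)

    @given(st.integers(0, 12), st.integers(0, 12))
    def test_small_samples_match_exact_binomial_oracle(self, b, c):
        if b + c == 0:
            return
        cmp_ = mcnemar(*_paired_vectors(b, c))
        oracle = sm_mcnemar([[0, b], [c, 0]], exact=True)
        assert cmp_.method == "exact-binomial"
        assert cmp_.p_value == pytest.approx(float(oracle.pvalue), abs=1e-9)

    @given(st.integers(5, 60), st.integers(5, 60))
    def test_large_samples_match_chi_square_oracle(self, b, c):
        if b + c < 25:
            return
        cmp_ = mcnemar(*_paired_vectors(b, c))
        oracle = sm_mcnemar([[0, b], [c, 0]], exact=False, correction=False)
        assert cmp_.p_value == pytest.approx(float(oracle.pvalue), abs=1e-9)

    @given(st.integers(8, 55), st.integers(8, 55))
    def test_corrected_chi_square_tracks_exact_binomial(self, b, c):
        """Continuity-corrected chi-square approximates the exact test to 0.02
        across moderate discordance (25 <= b+c <= 100)."""
        if not 25 <= b + c <= 100:
            return
        approx = mcnemar(*_paired_vectors(b, c), correction=True)
        exact_p = 2 * stats.binom.cdf(min(b, c), b + c, 0.5)
        assert approx.p_value == pytest.approx(min(exact_p, 1.0), abs=0.02)


@pytest.fixture(scope="module")
def cohort():
    params = load_preset("jttr-like", n=3000, seed=11)
    return generate(params)


class TestReport:
    def test_all_rows_and_cells_populated(self, cohort):
        records, truth = cohort
        tools = ["rr22", "rr24", "mptt", "mptt24", "uk_military_sieve"]
        table, pmat = report(records, truth, tools)
        assert list(table.index) == tools
        for col in ("sensitivity", "specificity", "dor", "ppv",
                    "undertriage", "overtriage"):
            assert table[col].notna().all()
        assert (table[["tp", "fp", "fn", "tn"]].sum(axis=1) == len(records)).all()
        assert pmat.shape == (5, 5)
        assert ((pmat.values >= 0) & (pmat.values <= 1)).all()

    def test_report_invariant_to_record_order(self, cohort):
        records, truth = cohort
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(records))
        t1, p1_ = report(records, truth, ["mptt", "mptt24"])
        t2, p2_ = report([records[i] for i in perm], [truth[i] for i in perm],
                         ["mptt", "mptt24"])
        assert np.allclose(t1.values.astype(float), t2.values.astype(float))
        assert np.allclose(p1_.values, p2_.values)

    def test_degenerate_margin_flagged(self):
        params = load_preset("jttr-like", n=50, seed=1)
        records, truth = generate(params)
        with pytest.raises(UndefinedMetricError):
            # all-true truth labels leave the specificity margin empty
            report(records, [True] * len(records), ["mptt"])
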
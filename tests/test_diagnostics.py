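"""2x2 contingency-table construction, diagnostic battery and reconstruction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from predictivity import (
    ContingencyTable,
    binomial_ci,
    build_table,
    chi2_yates,
    diagnose,
    dichotomize,
    reconstruct_table,
    render_report,
)
from predictivity.diagnostics import ReconstructionError, ZeroMarginError

cells = st.integers(min_value=0, max_value=200)


class TestDichotomize:
    @pytest.mark.parametrize(
        "value, label",
        [(0.00, "active"), (-1.42, "inactive"), (0.37, "active"), (-0.01, "inactive")],
    )
    def test_boundary_rule(self, value, label):
        assert dichotomize([value]) == [label]

    def test_fixture_examples(self, table4):
        by_name = {r.name: r.logbb for r in table4}
        labels = dichotomize([by_name["Cimetidine"], by_name["Benzene"],
                              by_name["Diethyl ether"]])
        assert labels == ["inactive", "active", "active"]

    def test_custom_threshold(self):
        assert dichotomize([0.4], threshold=0.5) == ["inactive"]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            dichotomize([float("nan")])


class TestBuildTable:
    def test_two_by_two_example(self):
        t = build_table(["active", "active", "inactive", "inactive"],
                        ["active", "inactive", "active", "inactive"])
        assert (t.tp, t.fn, t.fp, t.tn) == (1, 1, 1, 1)

    def test_perfect_agreement(self, rng):
        labels = ["active" if v else "inactive" for v in rng.integers(0, 2, 30)]
        t = build_table(labels, labels)
        assert t.fp == t.fn == 0

    def test_random_labels_match_counting_oracle(self, rng):
        obs = ["active" if v else "inactive" for v in rng.integers(0, 2, 100)]
        pred = ["active" if v else "inactive" for v in rng.integers(0, 2, 100)]
        t = build_table(obs, pred)
        assert t.tp == sum(o == p == "active" for o, p in zip(obs, pred))
        assert t.tn == sum(o == p == "inactive" for o, p in zip(obs, pred))
        assert t.fp == sum(o == "inactive" and p == "active" for o, p in zip(obs, pred))
        assert t.fn == sum(o == "active" and p == "inactive" for o, p in zip(obs, pred))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            build_table(["active"], ["active", "inactive"])


class TestDiagnose:
    def test_published_training_diagnostics(self):
        rep = diagnose(ContingencyTable(25, 11, 14, 31))
        assert rep.ac == pytest.approx(69.14, abs=0.005)
        assert rep.se == pytest.approx(64.10, abs=0.005)
        assert rep.sp == pytest.approx(73.81, abs=0.005)
        assert rep.pp == pytest.approx(69.44, abs=0.005)
        assert rep.np_ == pytest.approx(68.89, abs=0.005)
        assert rep.pca == pytest.approx(0.444, abs=5e-4)
        assert rep.pwca == pytest.approx(0.306, abs=5e-4)
        assert rep.or_ == pytest.approx(5.03, abs=0.005)
        assert rep.chi2 == pytest.approx(10.29, abs=0.005)
        assert rep.phi == pytest.approx(0.3564, abs=5e-5)

    def test_published_prior_model_diagnostics(self):
        rep = diagnose(ContingencyTable(35, 7, 10, 36))
        assert rep.ac == pytest.approx(80.68, abs=0.005)
        assert rep.or_ == pytest.approx(18.00, abs=0.005)
        assert rep.chi2 == pytest.approx(30.91, abs=0.005)
        assert rep.phi == pytest.approx(0.5927, abs=5e-5)

    def test_perfect_classifier(self):
        rep = diagnose(ContingencyTable(5, 0, 0, 5))
        assert rep.ac == 100.0
        assert rep.er == 0.0
        assert rep.or_ is None  # fp*fn = 0: flagged undefined

    def test_no_observed_actives(self):
        rep = diagnose(ContingencyTable(0, 3, 0, 7))
        assert rep.se is None and rep.fnr is None
        assert rep.sp is not None  # other fields still computed

    @given(tp=cells, fp=cells, fn=cells, tn=cells)
    @settings(max_examples=500, deadline=None)
    def test_complementarity_identities(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        rep = diagnose(ContingencyTable(tp, fp, fn, tn))
        assert rep.ac + rep.er == pytest.approx(100.0)
        if rep.se is not None:
            assert rep.se + rep.fnr == pytest.approx(100.0)
        if rep.sp is not None:
            assert rep.sp + rep.fpr == pytest.approx(100.0)
        assert rep.pca + rep.pcic == pytest.approx(1.0)
        assert rep.ppp_active + rep.ppp_inactive == pytest.approx(1.0)
        if rep.pp is not None:
            assert rep.pwca == pytest.approx(1 - rep.pp / 100)
        if rep.np_ is not None:
            assert rep.pwci == pytest.approx(1 - rep.np_ / 100)
        if rep.chi2 is not None:
            assert rep.phi**2 * rep.table.n == pytest.approx(rep.chi2, abs=1e-9)

    def test_diagnose_of_built_table_equals_hand_counts(self, rng):
        obs = ["active" if v else "inactive" for v in rng.integers(0, 2, 60)]
        pred = ["active" if v else "inactive" for v in rng.integers(0, 2, 60)]
        rep = diagnose(build_table(obs, pred))
        tp = sum(o == p == "active" for o, p in zip(obs, pred))
        oa = sum(o == "active" for o in obs)
        assert rep.se == pytest.approx(100 * tp / oa)


class TestChi2Yates:
    @pytest.mark.parametrize(
        "cells_, expected",
        [((25, 11, 14, 31), 10.29), ((16, 8, 3, 14), 7.75),
         ((40, 31, 55, 189), 28.24), ((35, 7, 10, 36), 30.91)],
    )
    def test_published_values(self, cells_, expected):
        stat, p = chi2_yates(ContingencyTable(*cells_))
        assert stat == pytest.approx(expected, abs=0.005)
        assert 0 < p < 0.01

    def test_independence_clamped_to_zero(self):
        stat, p = chi2_yates(ContingencyTable(10, 10, 10, 10))
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_scipy_contingency(self, rng):
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(1, 40, size=4)
            t = ContingencyTable(int(tp), int(fp), int(fn), int(tn))
            stat, p = chi2_yates(t)
            ref = stats.chi2_contingency(t.as_array(), correction=True)
            assert stat == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_margin(self):
        with pytest.raises(ZeroMarginError):
            chi2_yates(ContingencyTable(0, 0, 5, 5))


class TestBinomialCI:
    def test_boundaries(self):
        assert binomial_ci(0, 10).lower == 0.0
        assert binomial_ci(10, 10).upper == 1.0

    def test_clopper_pearson_against_beta_quantiles(self):
        ci = binomial_ci(56, 81)
        lo = stats.beta.ppf(0.025, 56, 81 - 56 + 1)
        hi = stats.beta.ppf(0.975, 57, 81 - 56)
        assert ci.lower == pytest.approx(lo, abs=1e-10)
        assert ci.upper == pytest.approx(hi, abs=1e-10)
        # within one percentage point of the published accuracy interval
        assert ci.lower * 100 == pytest.approx(58.53, abs=1.0)
        assert ci.upper * 100 == pytest.approx(78.37, abs=1.0)

    def test_wilson_ordering(self):
        ci = binomial_ci(7, 20, method="wilson")
        assert 0 <= ci.lower <= ci.estimate <= ci.upper <= 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_ci(5, 3)
        with pytest.raises(ValueError, match="alpha"):
            binomial_ci(3, 10, alpha=1.5)
        with pytest.raises(ValueError, match="method"):
            binomial_ci(3, 10, method="bogus")


class TestReconstructTable:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((81, 0.482, 64.10, 73.81), (25, 11, 14, 31)),
            ((41, 0.463, 84.21, 63.64), (16, 8, 3, 14)),
            ((315, 0.302, 42.11, 85.91), (40, 31, 55, 189)),
            ((88, 0.511, 77.78, 83.72), (35, 7, 10, 36)),
            ((28, 0.179, 60.00, 100.00), (3, 0, 2, 23)),
            ((92, 0.435, 77.50, 80.77), (31, 10, 9, 42)),
        ],
    )
    def test_published_summaries(self, args, expected):
        t = reconstruct_table(*args)
        assert (t.tp, t.fp, t.fn, t.tn) == expected

    def test_round_trip_identity(self, rng):
        """summarize -> reconstruct returns the original table for random
        integer tables (uniqueness of the reconstruction)."""
        for _ in range(1000):
            n = int(rng.integers(8, 401))
            oa = int(rng.integers(1, n))
            tp = int(rng.integers(0, oa + 1))
            tn = int(rng.integers(0, n - oa + 1))
            t = ContingencyTable(tp, n - oa - tn, oa - tp, tn)
            prev = round(oa / n, 3)
            se = round(100 * tp / oa, 2)
            sp = round(100 * tn / (n - oa), 2)
            back = reconstruct_table(n, prev, se, sp)
            assert (back.tp, back.fp, back.fn, back.tn) == (t.tp, t.fp, t.fn, t.tn)

    def test_inconsistent_summary_errors_with_candidates(self):
        with pytest.raises(ReconstructionError, match="nearest candidate"):
            reconstruct_table(10, 0.5, 33.33, 50.0)


class TestRenderReport:
    def test_three_column_layout(self):
        reports = {
            "training": diagnose(ContingencyTable(25, 11, 14, 31)),
            "test": diagnose(ContingencyTable(16, 8, 3, 14)),
            "external": diagnose(ContingencyTable(40, 31, 55, 189)),
        }
        text = render_report(reports)
        lines = text.splitlines()
        assert len(lines) == 2 + 17  # header + rule + 17 parameter rows
        assert "training (n=81)" in lines[0]
        assert "69.14" in text and "73.17" in text and "72.70" in text

    def test_undefined_odds_ratio_renders_na(self):
        text = render_report({"test": diagnose(ContingencyTable(3, 0, 2, 23))})
        assert "n.a." in text.splitlines()[-1]

    def test_single_column(self):
        text = render_report({"only": diagnose(ContingencyTable(5, 2, 3, 7))})
        assert "only (n=17)" in text

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            render_report({})
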
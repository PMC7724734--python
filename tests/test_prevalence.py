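import numpy as np
import pandas as pd
import pytest

from cophylo.datasets import specimens_from_counts, survey_counts
from cophylo.errors import CophyloError, SeparationError
from cophylo.prevalence import (cochran_q, logistic_sex_effect,
                                mcnemar_pairwise, percent, prevalence_table,
                                sex_balance_subset, tissue_tropism_test)
from cophylo.simulate import SpecimenSimParams, simulate_specimens
from cophylo.tables import SpecimenTable


def specimens(rows):
    return SpecimenTable(pd.DataFrame(rows))


def record(i, species="sp1", sex="F", leg="negative", gut="negative",
           repro="negative", control=True, locality="L1"):
    return {"specimen_id": f"r{i}", "species": species, "locality": locality,
            "sex": sex, "leg": leg, "gut": gut, "reproductive": repro,
            "control_ok": control}


class TestPrevalenceTable:
    def test_simple_fraction(self):
        t = specimens([record(i, repro="positive" if i < 4 else "negative")
                       for i in range(10)])
        pt = prevalence_table(t)
        assert pt.rows.loc["sp1", "pct"] == 40.0

    def test_percent_formatter_matches_survey_tissue_rates(self):
        assert percent(67, 159) == 42.1
        assert percent(9, 159) == 5.7
        assert percent(5, 159) == 3.1

    def test_survey_counts_reproduce_totals(self):
        t = specimens_from_counts(survey_counts())
        pt = prevalence_table(t)
        infected, screened, pct = pt.totals
        assert (infected, screened, pct) == (119, 271, 43.9)
        assert len(pt.positive_groups()) == 21

    def test_record_order_invariance(self):
        rows = [record(i, species=f"sp{i % 3}",
                       repro="positive" if i % 4 == 0 else "negative")
                for i in range(24)]
        t1 = prevalence_table(specimens(rows))
        t2 = prevalence_table(specimens(rows[::-1]))
        pd.testing.assert_frame_equal(
            t1.rows.sort_index(), t2.rows.sort_index())

    def test_unknown_grouping_key(self):
        t = specimens([record(0)])
        with pytest.raises(Exception, match="grouping"):
            prevalence_table(t, by="habitat")

    def test_group_by_species_and_locality(self):
        rows = [record(0, locality="A", repro="positive"),
                record(1, locality="B")]
        pt = prevalence_table(specimens(rows), by=("species", "locality"))
        assert len(pt.rows) == 2


class TestCochranQ:
    def test_constant_rows_degenerate_q_zero(self):
        # rows with no within-subject discordance: Q = 0, P = 1, flagged
        q, df, p, n = cochran_q(np.vstack([np.ones((4, 3)),
                                           np.zeros((2, 3))]))
        assert (q, p, n) == (0.0, 1.0, 0)

    def test_identical_mixed_rows_follow_the_formula(self):
        # every subject (1,0,1): column totals differ, so Q is positive
        m = np.tile([1, 0, 1], (5, 1))
        q, df, p, n = cochran_q(m)
        assert q == pytest.approx(2 * (3 * 50 - 100) / (3 * 10 - 20))
        assert n == 5

    def test_hand_computed_value(self):
        m = np.array([[1, 0, 0], [1, 0, 0], [1, 1, 0], [0, 0, 0]])
        q, df, p, n = cochran_q(m)
        assert q == pytest.approx(2 * 14 / 6)
        assert df == 2
        assert n == 3

    def test_k2_equals_uncorrected_mcnemar_chisq(self, rng):
        for _ in range(10):
            m = rng.integers(0, 2, size=(12, 2))
            b = int(((m[:, 0] == 1) & (m[:, 1] == 0)).sum())
            c = int(((m[:, 0] == 0) & (m[:, 1] == 1)).sum())
            if b + c == 0:
                continue
            q, df, p, _ = cochran_q(m)
            assert q == pytest.approx((b - c) ** 2 / (b + c))

    def test_matches_brute_force_formula_on_random_matrices(self, rng):
        """Direct scalar evaluation of the defining formula."""
        for _ in range(20):
            m = rng.integers(0, 2, size=(int(rng.integers(4, 15)),
                                         int(rng.integers(2, 5))))
            R = m.sum(axis=1)
            k = m.shape[1]
            if not ((R > 0) & (R < k)).any():
                continue
            C = m.sum(axis=0)
            brute = ((k - 1) * (k * sum(c * c for c in C) - sum(C) ** 2)
                     / (k * sum(R) - sum(r * r for r in R)))
            q, *_ = cochran_q(m)
            assert q == pytest.approx(brute)

    def test_subject_duplication_recomputes_consistently(self, rng):
        m = rng.integers(0, 2, size=(10, 3))
        if not ((m.sum(1) > 0) & (m.sum(1) < 3)).any():
            m[0] = [1, 0, 0]
        doubled = np.vstack([m, m])
        q2, *_ = cochran_q(doubled)
        R = doubled.sum(axis=1)
        C = doubled.sum(axis=0)
        k = 3
        brute = ((k - 1) * (k * np.sum(C**2) - C.sum() ** 2)
                 / (k * R.sum() - np.sum(R**2)))
        assert q2 == pytest.approx(brute)


class TestMcNemar:
    def test_symmetric_discordance_p_one(self):
        m = pd.DataFrame({"a": [1, 1, 0, 0], "b": [0, 0, 1, 1]})
        p, _ = mcnemar_pairwise(m)
        assert p[("a", "b")] == pytest.approx(1.0)

    def test_one_sided_discordance_binomial_tail(self):
        m = pd.DataFrame({"a": [1] * 10, "b": [0] * 10})
        p, _ = mcnemar_pairwise(m, correction="exact")
        assert p[("a", "b")] == pytest.approx(2 * 0.5**10)

    def test_no_discordance_degenerate(self):
        m = pd.DataFrame({"a": [1, 0], "b": [1, 0]})
        p, degenerate = mcnemar_pairwise(m)
        assert p[("a", "b")] == 1.0
        assert degenerate == (("a", "b"),)

    def test_chisq_variant(self):
        m = pd.DataFrame({"a": [1] * 10 + [0] * 2,
                          "b": [0] * 10 + [1] * 2})
        p, _ = mcnemar_pairwise(m, correction="chisq")
        from scipy.stats import chi2

        expected = chi2.sf((10 - 2) ** 2 / 12, 1)
        assert p[("a", "b")] == pytest.approx(expected)

    def test_holm_adjustment_monotone(self):
        m = pd.DataFrame({"a": [1] * 10 + [0] * 10,
                          "b": [0] * 10 + [0] * 10,
                          "c": [1] * 10 + [1] * 10})
        raw, _ = mcnemar_pairwise(m, adjust="none")
        holm, _ = mcnemar_pairwise(m, adjust="holm")
        for pair in raw:
            assert holm[pair] >= raw[pair] - 1e-12


class TestTissueTropism:
    def test_reproductive_dominance_detected(self):
        params = SpecimenSimParams(
            prevalence={"spA": 0.5, "spB": 0.4},
            n_per_species=250,
            control_failure_rate=0.0,
        )
        t = simulate_specimens(params, seed=4)
        res = tissue_tropism_test(t)
        assert res.p_value < 1e-3
        assert res.pairwise[("gut", "reproductive")] < 1e-3
        assert res.pairwise[("leg", "reproductive")] < 1e-3

    def test_excludes_failed_controls(self):
        rows = [record(i, repro="positive", control=(i % 2 == 0))
                for i in range(10)]
        rows += [record(i + 10) for i in range(10)]
        res = tissue_tropism_test(specimens(rows))
        assert res.n_subjects == 15


class TestSexBalanceSubset:
    def test_inclusive_boundary_kept(self):
        rows = ([record(i, sex="F") for i in range(10)]
                + [record(10 + i, sex="M") for i in range(6)])
        t = specimens(rows)
        assert len(sex_balance_subset(t)) == 16

    def test_below_boundary_dropped(self):
        rows = ([record(i, sex="F") for i in range(10)]
                + [record(10 + i, sex="M") for i in range(5)])
        assert len(sex_balance_subset(specimens(rows))) == 0

    def test_single_sex_dropped(self):
        rows = [record(i, sex="F") for i in range(10)]
        assert len(sex_balance_subset(specimens(rows))) == 0


class TestLogisticSexEffect:
    def test_two_by_two_closed_form(self):
        rows = ([record(i, sex="F",
                        repro="positive" if i < 30 else "negative")
                 for i in range(100)]
                + [record(100 + i, sex="M",
                          repro="positive" if i < 15 else "negative")
                   for i in range(100)])
        res = logistic_sex_effect(specimens(rows))
        expected_or = (15 * 70) / (85 * 30)
        assert res.odds_ratio == pytest.approx(expected_or, abs=1e-6)
        assert res.coef == pytest.approx(np.log(expected_or), abs=1e-6)
        assert res.df == 198

    def test_equal_rates_give_null_or(self):
        rows = ([record(i, sex="F",
                        repro="positive" if i % 2 == 0 else "negative")
                 for i in range(50)]
                + [record(50 + i, sex="M",
                          repro="positive" if i % 2 == 0 else "negative")
                   for i in range(50)])
        res = logistic_sex_effect(specimens(rows))
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_complete_separation_flagged(self):
        rows = ([record(i, sex="M", repro="positive") for i in range(20)]
                + [record(20 + i, sex="F") for i in range(20)])
        with pytest.raises(SeparationError):
            logistic_sex_effect(specimens(rows))
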
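"""Cluster-level estimators against independent oracles.

The brute-force oracle solves the weighted normal equations of the pair+arm
ANOVA directly with ``numpy.linalg.solve`` (no statsmodels), and computes the
CI from first principles.
"""

import math

import numpy as np
import pytest
from scipy import stats

from pmcrt.cluster_analysis import (
    ObservedExpected,
    SiteSummary,
    compute_weight,
    crude_effect,
    estimate_cv,
    fit_control_model,
    oe_effect,
    summarize_sites,
    unpaired_ttest_effect,
)
from pmcrt.errors import (
    DegenerateSiteError,
    InsufficientPairsError,
    SeparationError,
    UndefinedCVError,
    WeightError,
)
from pmcrt.outcomes import BUILTIN_SPECS
from pmcrt.trial_data import Dataset, SiteMeta

from conftest import make_record, single_site_dataset


def summary(site, pair, arm, n1, n, outcome="physical_ipv"):
    s = SiteSummary(site, pair, arm, outcome, n1, n, continuity_applied=(n1 == 0))
    s.weight = compute_weight(s)
    return s


# ---------------------------------------------------------------------------
# independent weighted-least-squares oracle


def wls_oracle(y, arm, pair_ids, w):
    """Solve the weighted normal equations X'WX b = X'Wy by hand."""
    pairs = sorted(set(pair_ids))
    X = [[1.0, a] + [1.0 if q == p else 0.0 for p in pairs[1:]]
         for a, q in zip(arm, pair_ids)]
    X, y, w = np.array(X), np.array(y), np.array(w)
    XtW = X.T * w
    beta = np.linalg.solve(XtW @ X, XtW @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    scale = float(resid @ (w * resid)) / df if df > 0 else 0.0
    cov = scale * np.linalg.inv(XtW @ X)
    se = math.sqrt(max(cov[1, 1], 0.0))
    t = stats.t.ppf(0.975, df)
    b = float(beta[1])
    return math.exp(b), math.exp(b - t * se), math.exp(b + t * se), df


def random_summaries(rng, n_pairs, outcome="physical_ipv"):
    out = []
    for p in range(1, n_pairs + 1):
        for arm in ("intervention", "control"):
            n = int(rng.integers(50, 400))
            n1 = int(rng.integers(1, n - 1))
            out.append(summary(f"s{p}{arm[0]}", str(p), arm, n1, n, outcome))
    return out


class TestSummaries:
    def test_prevalence_worked_example(self):
        s = summary("s", "1", "intervention", 139, 508)
        assert s.prevalence == pytest.approx(0.2736, abs=5e-5)
        assert round(100 * s.prevalence) == 27

    def test_zero_numerator_continuity(self):
        s = summary("s", "1", "control", 0, 100)
        assert s.continuity_applied
        assert s.numerator == 0
        assert s.log_prev == pytest.approx(math.log(0.5 / 100))

    def test_summarize_counts_only_nonmissing(self):
        recs = [
            make_record(respondent_id="a", items={"concurrent_partner": "yes"}, sex="male"),
            make_record(respondent_id="b", items={"concurrent_partner": "no"}, sex="male"),
            make_record(respondent_id="c", sex="male"),  # item missing
        ]
        ds = single_site_dataset(recs)
        s = summarize_sites(ds, BUILTIN_SPECS["concurrency"])[0]
        assert (s.numerator, s.denominator) == (1, 2)

    def test_degenerate_site_all_ineligible(self):
        ds = single_site_dataset([make_record()])  # women only
        with pytest.raises(DegenerateSiteError, match="s1"):
            summarize_sites(ds, BUILTIN_SPECS["concurrency"])


class TestWeights:
    def test_half_prevalence(self):
        assert compute_weight(summary("s", "1", "control", 50, 100)) == pytest.approx(100.0)

    def test_direct_formula(self):
        s = summary("s", "1", "control", 139, 508)
        p = 139 / 508
        assert compute_weight(s) == pytest.approx(508 * p / (1 - p))
        assert compute_weight(s) == pytest.approx(191.3, abs=0.1)

    def test_prevalence_one_raises(self):
        with pytest.raises(WeightError):
            compute_weight(SiteSummary("s", "1", "control", "o", 10, 10))

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(0)
        summaries = random_summaries(rng, 4)
        base = crude_effect(summaries)
        for s in summaries:
            s.weight *= 7.3
        scaled = crude_effect(summaries)
        assert scaled.rr == pytest.approx(base.rr, rel=1e-12)
        assert scaled.ci_low == pytest.approx(base.ci_low, rel=1e-12)


class TestCrudeEffect:
    def test_identical_prevalences_null(self):
        summaries = [
            summary(f"s{p}{a[0]}", str(p), a, 30, 100)
            for p in range(1, 5)
            for a in ("intervention", "control")
        ]
        est = crude_effect(summaries)
        assert est.rr == pytest.approx(1.0)
        assert est.residual_variance == 0.0
        assert est.ci_low == pytest.approx(1.0) and est.ci_high == pytest.approx(1.0)
        assert est.df == 3

    def test_two_pair_toy_matches_oracle(self):
        summaries = [
            summary("a", "1", "intervention", 20, 100),
            summary("b", "1", "control", 40, 100),
            summary("c", "2", "intervention", 10, 100),
            summary("d", "2", "control", 30, 100),
        ]
        est = crude_effect(summaries)
        rr, lo, hi, df = wls_oracle(
            [s.log_prev for s in summaries],
            [1 if s.arm == "intervention" else 0 for s in summaries],
            [s.pair_id for s in summaries],
            [s.weight for s in summaries],
        )
        assert est.rr == pytest.approx(rr, abs=1e-10)
        assert est.ci_low == pytest.approx(lo, abs=1e-10)
        assert est.ci_high == pytest.approx(hi, abs=1e-10)
        assert est.df == df == 1

    @pytest.mark.parametrize("n_pairs", [2, 3])
    def test_oracle_equivalence_random(self, n_pairs):
        rng = np.random.default_rng(42 + n_pairs)
        for _ in range(50):
            summaries = random_summaries(rng, n_pairs)
            est = crude_effect(summaries)
            rr, lo, hi, _ = wls_oracle(
                [s.log_prev for s in summaries],
                [1 if s.arm == "intervention" else 0 for s in summaries],
                [s.pair_id for s in summaries],
                [s.weight for s in summaries],
            )
            assert est.rr == pytest.approx(rr, rel=1e-10)
            assert est.ci_low == pytest.approx(lo, rel=1e-10)
            assert est.ci_high == pytest.approx(hi, rel=1e-10)

    def test_single_pair_raises(self):
        summaries = [
            summary("a", "1", "intervention", 20, 100),
            summary("b", "1", "control", 40, 100),
        ]
        with pytest.raises(InsufficientPairsError):
            crude_effect(summaries)

    def test_pair_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        summaries = random_summaries(rng, 4)
        base = crude_effect(summaries)
        relabel = {"1": "9", "2": "3", "3": "2", "4": "0"}
        for s in summaries:
            s.pair_id = relabel[s.pair_id]
        assert crude_effect(summaries).rr == pytest.approx(base.rr, rel=1e-12)
        assert crude_effect(summaries).ci_high == pytest.approx(base.ci_high, rel=1e-12)

    def test_arm_swap_antisymmetry(self):
        rng = np.random.default_rng(8)
        summaries = random_summaries(rng, 4)
        base = crude_effect(summaries)
        for s in summaries:
            s.arm = "control" if s.arm == "intervention" else "intervention"
        swapped = crude_effect(summaries)
        assert swapped.rr == pytest.approx(1 / base.rr, rel=1e-10)
        assert swapped.ci_low == pytest.approx(1 / base.ci_high, rel=1e-10)
        assert swapped.ci_high == pytest.approx(1 / base.ci_low, rel=1e-10)


class TestAdjustedEffect:
    def oe(self, site, pair, arm, O, E):
        o = ObservedExpected(site, pair, arm, O, E, continuity_applied=(O == 0))
        o.weight = o.expected
        return o

    def test_hand_set_oe_matches_oracle(self):
        oes = [
            self.oe("a", "1", "intervention", 12, 20.0),
            self.oe("b", "1", "control", 25, 22.0),
            self.oe("c", "2", "intervention", 8, 15.0),
            self.oe("d", "2", "control", 30, 28.0),
            self.oe("e", "3", "intervention", 14, 30.0),
            self.oe("f", "3", "control", 21, 20.0),
        ]
        est = oe_effect(oes, "physical_ipv")
        rr, lo, hi, df = wls_oracle(
            [o.log_ratio for o in oes],
            [1 if o.arm == "intervention" else 0 for o in oes],
            [o.pair_id for o in oes],
            [o.weight for o in oes],
        )
        assert est.rr == pytest.approx(rr, abs=1e-10)
        assert est.ci_low == pytest.approx(lo, abs=1e-10)
        assert est.ci_high == pytest.approx(hi, abs=1e-10)

    def test_zero_observed_uses_continuity(self):
        o = self.oe("a", "1", "intervention", 0, 5.0)
        assert o.ratio == pytest.approx(0.1)
        assert o.continuity_applied
        assert o.weight == pytest.approx(5.0)

    def test_calibrated_null_gives_unit_ratio(self):
        # model predictions equal to observed prevalences -> all O/E = 1
        oes = [
            self.oe(f"s{p}{a[0]}", str(p), a, 30, 30.0)
            for p in range(1, 5)
            for a in ("intervention", "control")
        ]
        est = oe_effect(oes, "x")
        assert est.rr == pytest.approx(1.0)
        assert est.residual_variance == pytest.approx(0.0, abs=1e-20)


class TestControlModel:
    def _dataset(self, n, rng, beta_age=0.0, base=-0.85):
        recs = []
        for i in range(n):
            age = int(rng.integers(18, 50))
            eta = base + beta_age * (age - 30)
            yes = rng.random() < 1 / (1 + math.exp(-eta))
            recs.append(
                make_record(
                    respondent_id=f"r{i}",
                    age=age,
                    items={"concurrent_partner": "yes" if yes else "no"},
                    sex="male",
                )
            )
        sites = [SiteMeta("s1", "1", "control", ea_ids=("s1_ea1",))]
        return Dataset(records=recs, sites=sites)

    def test_intercept_only_behaviour(self):
        rng = np.random.default_rng(1)
        ds = self._dataset(3000, rng)
        model = fit_control_model(ds, BUILTIN_SPECS["concurrency"], {"s1_ea1": 0.57})
        preds = [model.predict(r) for r in ds.records[:50]]
        assert np.mean([model.predict(r) for r in ds.records]) == pytest.approx(0.30, abs=0.03)
        assert max(preds) - min(preds) < 0.15  # no real covariate signal

    def test_age_coefficient_recovery(self):
        rng = np.random.default_rng(2)
        ds = self._dataset(2000, rng, beta_age=0.05)
        model = fit_control_model(ds, BUILTIN_SPECS["concurrency"], {"s1_ea1": 0.3})
        assert model.params[1] == pytest.approx(0.05, abs=0.03)

    def test_continuous_ea_prevalence_accepted(self):
        rng = np.random.default_rng(3)
        ds = self._dataset(500, rng)
        model = fit_control_model(ds, BUILTIN_SPECS["concurrency"], {"s1_ea1": 0.57})
        assert 0.0 < model.predict(ds.records[0]) < 1.0

    def test_constant_outcome_raises_separation(self):
        recs = [
            make_record(respondent_id=f"r{i}", sex="male",
                        items={"concurrent_partner": "no"})
            for i in range(50)
        ]
        ds = Dataset(records=recs, sites=[SiteMeta("s1", "1", "control")])
        with pytest.raises(SeparationError):
            fit_control_model(ds, BUILTIN_SPECS["concurrency"], {})


class TestTTest:
    def test_identical_values_degenerate(self):
        summaries = [
            summary(f"s{i}", str(i // 2 + 1), a, 30, 100)
            for i, a in enumerate(["intervention", "control"] * 4)
        ]
        est = unpaired_ttest_effect(summaries)
        assert est.rr == pytest.approx(1.0)
        assert est.ci_low == pytest.approx(1.0) and est.ci_high == pytest.approx(1.0)

    def test_hand_computed_oracle(self):
        # 4+4 toy: compare with the textbook pooled-variance computation
        vals = {"intervention": [10, 14, 9, 12], "control": [20, 25, 22, 30]}
        summaries = []
        i = 0
        for arm, ns in vals.items():
            for n1 in ns:
                summaries.append(summary(f"s{i}", str(i % 4 + 1), arm, n1, 100))
                i += 1
        est = unpaired_ttest_effect(summaries)

        y1 = np.log([v / 100 for v in vals["intervention"]])
        y0 = np.log([v / 100 for v in vals["control"]])
        sp2 = (3 * np.var(y1, ddof=1) + 3 * np.var(y0, ddof=1)) / 6
        diff = y1.mean() - y0.mean()
        se = math.sqrt(sp2 * 0.5)
        t = stats.t.ppf(0.975, 6)
        assert est.df == 6
        assert est.rr == pytest.approx(math.exp(diff), rel=1e-12)
        assert est.ci_low == pytest.approx(math.exp(diff - t * se), rel=1e-12)
        # cross-check the t statistic with scipy
        scipy_t = stats.ttest_ind(y1, y0, equal_var=True)
        assert diff / se == pytest.approx(scipy_t.statistic, rel=1e-12)

    def test_fewer_than_two_per_arm(self):
        summaries = [
            summary("a", "1", "intervention", 10, 100),
            summary("b", "1", "control", 20, 100),
            summary("c", "2", "control", 25, 100),
        ]
        with pytest.raises(InsufficientPairsError):
            unpaired_ttest_effect(summaries)

    def test_paired_ci_narrower_under_strong_pair_effects(self):
        # strong pair effects: the paired analysis should usually win
        rng = np.random.default_rng(9)
        wins = 0
        reps = 60
        for _ in range(reps):
            summaries = []
            for p in range(1, 5):
                base = rng.uniform(0.1, 0.4)
                for arm in ("intervention", "control"):
                    pv = np.clip(base + rng.normal(0, 0.01), 0.02, 0.9)
                    n = 200
                    summaries.append(summary(f"s{p}{arm[0]}", str(p), arm,
                                             max(1, int(pv * n)), n))
            paired = crude_effect(summaries)
            unpaired = unpaired_ttest_effect(summaries)
            if (math.log(paired.ci_high) - math.log(paired.ci_low)) < (
                math.log(unpaired.ci_high) - math.log(unpaired.ci_low)
            ):
                wins += 1
        assert wins > reps / 2


class TestCV:
    def test_identical_prevalences_huge_n(self):
        summaries = [summary(f"s{i}", "1", "control", 30000, 100000) for i in range(8)]
        assert estimate_cv(summaries).k == 0.0

    def test_all_zero_raises(self):
        summaries = [summary(f"s{i}", "1", "control", 0, 100) for i in range(4)]
        with pytest.raises(UndefinedCVError):
            estimate_cv(summaries)

    def test_formula_directly(self):
        summaries = [
            summary("a", "1", "control", 20, 100),
            summary("b", "1", "control", 40, 200),
        ]
        p = np.array([0.2, 0.2])
        # zero empirical variance -> truncated at zero
        assert estimate_cv(summaries).k == 0.0
        summaries = [
            summary("a", "1", "control", 10, 100),
            summary("b", "1", "control", 40, 100),
        ]
        p = np.array([0.1, 0.4])
        s2 = p.var(ddof=1)
        pbar = p.mean()
        k2 = (s2 - pbar * (1 - pbar) / 100) / pbar**2
        assert estimate_cv(summaries).k == pytest.approx(math.sqrt(k2))
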
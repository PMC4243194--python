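"""Cluster-level intention-to-treat machinery.

Two-stage analysis for a pair-matched community randomized trial with binary
outcomes:

* crude effects — site-level log prevalences entered into a weighted ANOVA
  with terms for arm and matched pair;
* adjusted effects — an individual-level logistic model fitted to control-arm
  follow-up data (age, marital status, baseline enumeration-area prevalence)
  predicts the count expected in each site absent the intervention; the
  site-level log observed/expected ratios enter the same weighted ANOVA;
* an unpaired t-test sensitivity analysis on the same site-level summaries;
* the between-cluster coefficient of variation of true prevalence.

Weights are inversely proportional to the delta-method variance of the
log-scale site measure: ``n*p/(1-p)`` for a prevalence, the expected count
for an observed/expected ratio.  To keep the weights (nearly) independent of
each site's own sampling noise — weighting by the site's estimated variance
correlates weight with estimate and biases the pooled log ratio — the
prevalence entering the weight is the pooled prevalence over the summarized
sites, so that weights differ across sites through their denominators.  The
ANOVA is invariant to rescaling all weights.  A site with a zero numerator
has 0.5 added to the numerator only (denominator unchanged) so the log
measure exists.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import (
    DegenerateSiteError,
    InsufficientPairsError,
    SeparationError,
    UndefinedCVError,
    WeightError,
)
from .outcomes import OutcomeSpec, evaluate_outcome
from .trial_data import Dataset, IndividualRecord

CONTINUITY = 0.5


@dataclass(slots=True)
class SiteSummary:
    """Per-site numerator/denominator for one outcome at one round."""

    site_id: str
    pair_id: str
    arm: str
    outcome_id: str
    numerator: int
    denominator: int
    continuity_applied: bool = False
    weight: float = field(default=0.0)

    @property
    def prevalence(self) -> float:
        return self.numerator / self.denominator

    @property
    def effective_prevalence(self) -> float:
        """Prevalence with the continuity correction applied to a zero count."""
        num = CONTINUITY if self.numerator == 0 else self.numerator
        return num / self.denominator

    @property
    def log_prev(self) -> float:
        return math.log(self.effective_prevalence)


@dataclass(slots=True)
class ObservedExpected:
    """Observed vs model-expected outcome count in one site."""

    site_id: str
    pair_id: str
    arm: str
    observed: int
    expected: float
    continuity_applied: bool = False
    weight: float = 0.0

    @property
    def effective_observed(self) -> float:
        return CONTINUITY if self.observed == 0 else float(self.observed)

    @property
    def ratio(self) -> float:
        return self.effective_observed / self.expected

    @property
    def log_ratio(self) -> float:
        return math.log(self.ratio)


@dataclass(slots=True)
class EffectEstimate:
    """Risk ratio with CI from a cluster-level comparison."""

    outcome_id: str
    rr: float
    ci_low: float
    ci_high: float
    scale: str  # 'crude' | 'adjusted' | 'ttest' | 'matched'
    df: int
    residual_variance: float
    log_rr: float = 0.0
    se: float = 0.0


@dataclass(slots=True)
class CVEstimate:
    outcome_id: str
    round: str
    arm_set: str  # 'all' | 'control_only'
    k: float


# ---------------------------------------------------------------------------
# site summaries and weights


def compute_weight(s: SiteSummary, prevalence: float | None = None) -> float:
    """Inverse delta-method variance of the log site prevalence: ``n*p/(1-p)``.

    By default ``p`` is the site's own (continuity-corrected) prevalence.
    The analysis pipeline passes the pooled prevalence over all summarized
    sites instead, which keeps the weight independent of the site's sampling
    noise; either way a prevalence of exactly 1 has zero log-scale variance
    and raises.
    """
    p = s.effective_prevalence if prevalence is None else prevalence
    if p >= 1.0:
        raise WeightError(
            f"site {s.site_id}: prevalence 1 gives an undefined log-scale weight"
        )
    return s.denominator * p / (1.0 - p)


def summarize_sites(
    ds: Dataset,
    spec: OutcomeSpec,
    round: str = "followup",
    sites: list | None = None,
) -> list[SiteSummary]:
    """One weighted numerator/denominator summary per site.

    Only respondents in the outcome denominator with a determinable composite
    value are counted.  A site with none raises :class:`DegenerateSiteError`.
    """
    out = []
    for meta in sites if sites is not None else ds.sites:
        n = n1 = 0
        for rec in ds.records_for(meta.site_id, round):
            ov = evaluate_outcome(rec, spec)
            if ov.in_denominator and ov.value is not None:
                n += 1
                n1 += ov.value
        if n == 0:
            raise DegenerateSiteError(
                f"site {meta.site_id}: no eligible respondent with a "
                f"non-missing {spec.outcome_id} value at {round}"
            )
        out.append(
            SiteSummary(
                site_id=meta.site_id,
                pair_id=meta.pair_id,
                arm=meta.arm,
                outcome_id=spec.outcome_id,
                numerator=n1,
                denominator=n,
                continuity_applied=(n1 == 0),
            )
        )
    pooled = sum(
        CONTINUITY if s.numerator == 0 else s.numerator for s in out
    ) / sum(s.denominator for s in out)
    for s in out:
        s.weight = compute_weight(s, pooled)
    return out


# ---------------------------------------------------------------------------
# weighted pair+arm ANOVA shared by the crude and adjusted analyses


def _pair_anova(
    y: np.ndarray,
    arm: np.ndarray,
    pair_ids: list,
    weights: np.ndarray,
    outcome_id: str,
    scale: str,
) -> EffectEstimate:
    pairs = sorted(set(pair_ids))
    n_pairs = len(pairs)
    if n_pairs < 2:
        raise InsufficientPairsError(
            "at least two matched pairs are needed for a residual degree of freedom"
        )
    for p in pairs:
        arms_in_pair = {a for a, q in zip(arm, pair_ids) if q == p}
        if arms_in_pair != {0, 1}:
            raise InsufficientPairsError(f"pair {p!r} lacks one site per arm")

    X = np.zeros((len(y), 1 + 1 + n_pairs - 1))
    X[:, 0] = 1.0
    X[:, 1] = arm
    for j, p in enumerate(pairs[1:], start=2):
        X[:, j] = [1.0 if q == p else 0.0 for q in pair_ids]

    res = sm.WLS(y, X, weights=weights).fit()
    coef = res.params[1]
    se = float(res.bse[1])
    df = int(res.df_resid)
    resid_var = float(res.scale)
    if resid_var < 1e-24:  # numerically zero residual variance
        se = 0.0
        resid_var = 0.0
    tcrit = stats.t.ppf(0.975, df)
    return EffectEstimate(
        outcome_id=outcome_id,
        rr=math.exp(coef),
        ci_low=math.exp(coef - tcrit * se),
        ci_high=math.exp(coef + tcrit * se),
        scale=scale,
        df=df,
        residual_variance=resid_var,
        log_rr=float(coef),
        se=se,
    )


def crude_effect(summaries: list[SiteSummary]) -> EffectEstimate:
    """Weighted ANOVA of log site prevalence on arm + pair.

    Returns the intervention-vs-control prevalence ratio with a t-based
    95% CI on ``2P - P - 1`` residual degrees of freedom.
    """
    y = np.array([s.log_prev for s in summaries])
    arm = np.array([1.0 if s.arm == "intervention" else 0.0 for s in summaries])
    w = np.array([s.weight for s in summaries], dtype=float)
    return _pair_anova(
        y, arm, [s.pair_id for s in summaries], w,
        summaries[0].outcome_id, "crude",
    )


# ---------------------------------------------------------------------------
# adjusted (observed/expected) analysis


class ControlModel:
    """Individual-level logistic model fitted to control-arm follow-up data.

    Predictors: age, marital status (married/cohabiting indicator) and the
    respondent's enumeration-area baseline prevalence of the outcome (or its
    configured proxy), entered as a continuous covariate.
    """

    def __init__(self, params: np.ndarray, baseline_prev: dict, fallback_prev: float):
        self.params = np.asarray(params, dtype=float)
        self.baseline_prev = dict(baseline_prev)
        self.fallback_prev = float(fallback_prev)

    def _features(self, rec: IndividualRecord) -> np.ndarray:
        bp = self.baseline_prev.get(rec.ea_id, self.fallback_prev)
        married = 1.0 if rec.marital_status == "married_cohabiting" else 0.0
        return np.array([1.0, float(rec.age), married, bp])

    def predict(self, rec: IndividualRecord) -> float:
        eta = float(self._features(rec) @ self.params)
        return 1.0 / (1.0 + math.exp(-eta))


def baseline_ea_prevalence(
    ds: Dataset, spec: OutcomeSpec, round: str = "baseline"
) -> dict[str, float]:
    """Baseline prevalence of the outcome (or proxy spec) per enumeration area.

    EAs with no eligible baseline respondent are absent from the map; callers
    fall back to the overall mean.
    """
    counts: dict[str, list] = {}
    for rec in ds.records:
        if rec.round != round:
            continue
        ov = evaluate_outcome(rec, spec)
        if ov.in_denominator and ov.value is not None:
            n, n1 = counts.setdefault(rec.ea_id, [0, 0])
            counts[rec.ea_id][0] = n + 1
            counts[rec.ea_id][1] = n1 + ov.value
    return {ea: n1 / n for ea, (n, n1) in counts.items()}


def fit_control_model(
    ds: Dataset,
    spec: OutcomeSpec,
    baseline_prev: dict[str, float],
    round: str = "followup",
) -> ControlModel:
    """Fit the control-arm logistic model used to generate expected counts.

    Complete-case on age, marital status and EA baseline prevalence (the
    latter always available via the overall-mean fallback).  A constant
    outcome raises :class:`SeparationError`; non-convergence falls back to a
    lightly ridge-penalized fit with a warning.
    """
    fallback = (
        float(np.mean(list(baseline_prev.values()))) if baseline_prev else 0.5
    )
    rows, ys = [], []
    control_sites = {s.site_id for s in ds.sites if s.arm == "control"}
    for rec in ds.records:
        if rec.round != round or rec.site_id not in control_sites:
            continue
        ov = evaluate_outcome(rec, spec)
        if not ov.in_denominator or ov.value is None:
            continue
        bp = baseline_prev.get(rec.ea_id, fallback)
        married = 1.0 if rec.marital_status == "married_cohabiting" else 0.0
        rows.append([1.0, float(rec.age), married, bp])
        ys.append(1.0 if ov.value else 0.0)
    if not rows:
        raise DegenerateSiteError(
            f"no control-arm respondents with a non-missing {spec.outcome_id} value"
        )
    y = np.array(ys)
    X = np.array(rows)
    if y.min() == y.max():
        raise SeparationError(
            f"{spec.outcome_id}: control-arm outcome is constant ({y[0]:g})"
        )
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100)
    if not res.converged or not np.all(np.isfinite(res.params)):
        warnings.warn(
            f"{spec.outcome_id}: control model did not converge; "
            "falling back to ridge-penalized fit",
            stacklevel=2,
        )
        res = model.fit_regularized(alpha=1e-4, L1_wt=0.0)
    return ControlModel(res.params, baseline_prev, fallback)


def compute_observed_expected(
    ds: Dataset,
    spec: OutcomeSpec,
    model: ControlModel,
    round: str = "followup",
    sites: list | None = None,
) -> list[ObservedExpected]:
    """Per-site observed count and model-expected count at follow-up.

    Weight is the model-expected count: the inverse variance of a log count
    evaluated at the expected rather than the (noisy) observed rate.
    """
    out = []
    for meta in sites if sites is not None else ds.sites:
        observed = 0
        expected = 0.0
        n_used = 0
        for rec in ds.records_for(meta.site_id, round):
            ov = evaluate_outcome(rec, spec)
            if not ov.in_denominator or ov.value is None:
                continue
            observed += ov.value
            expected += model.predict(rec)
            n_used += 1
        if n_used == 0 or expected <= 0.0:
            raise DegenerateSiteError(
                f"site {meta.site_id}: expected count is zero for {spec.outcome_id}"
            )
        oe = ObservedExpected(
            site_id=meta.site_id,
            pair_id=meta.pair_id,
            arm=meta.arm,
            observed=observed,
            expected=expected,
            continuity_applied=(observed == 0),
        )
        oe.weight = oe.expected
        out.append(oe)
    return out


def oe_effect(oes: list[ObservedExpected], outcome_id: str, scale: str = "adjusted") -> EffectEstimate:
    """Weighted pair+arm ANOVA of the site log observed/expected ratios."""
    y = np.array([oe.log_ratio for oe in oes])
    arm = np.array([1.0 if oe.arm == "intervention" else 0.0 for oe in oes])
    w = np.array([oe.weight for oe in oes], dtype=float)
    return _pair_anova(y, arm, [oe.pair_id for oe in oes], w, outcome_id, scale)


def adjusted_effect(
    ds: Dataset,
    spec: OutcomeSpec,
    model: ControlModel | None = None,
    baseline_prev: dict | None = None,
    round: str = "followup",
) -> EffectEstimate:
    """Two-stage covariate-adjusted prevalence ratio.

    Fits the control model when one is not supplied, computes site
    observed/expected ratios for both arms and runs the weighted pair+arm
    ANOVA on their logs.
    """
    if model is None:
        if baseline_prev is None:
            baseline_prev = baseline_ea_prevalence(ds, spec)
        model = fit_control_model(ds, spec, baseline_prev, round=round)
    oes = compute_observed_expected(ds, spec, model, round=round)
    return oe_effect(oes, spec.outcome_id, "adjusted")


# ---------------------------------------------------------------------------
# sensitivity t-test and between-cluster variation


def unpaired_ttest_effect(site_values: list) -> EffectEstimate:
    """Equal-variance two-sample t-test on site-level log measures.

    Accepts SiteSummary (log prevalence) or ObservedExpected (log O/E)
    objects.  ``df = (number of sites) - 2``.
    """
    logs, arms = [], []
    for s in site_values:
        logs.append(s.log_prev if isinstance(s, SiteSummary) else s.log_ratio)
        arms.append(s.arm)
    y = np.array(logs)
    a = np.array([1 if x == "intervention" else 0 for x in arms])
    y1, y0 = y[a == 1], y[a == 0]
    if len(y1) < 2 or len(y0) < 2:
        raise InsufficientPairsError("need at least two sites per arm for a t-test")
    n1, n0 = len(y1), len(y0)
    df = n1 + n0 - 2
    sp2 = (
        (n1 - 1) * np.var(y1, ddof=1) + (n0 - 1) * np.var(y0, ddof=1)
    ) / df
    diff = float(np.mean(y1) - np.mean(y0))
    se = math.sqrt(sp2 * (1 / n1 + 1 / n0))
    tcrit = stats.t.ppf(0.975, df)
    outcome_id = getattr(site_values[0], "outcome_id", "")
    return EffectEstimate(
        outcome_id=outcome_id,
        rr=math.exp(diff),
        ci_low=math.exp(diff - tcrit * se),
        ci_high=math.exp(diff + tcrit * se),
        scale="ttest",
        df=df,
        residual_variance=float(sp2),
        log_rr=diff,
        se=se,
    )


def estimate_cv(
    summaries: list[SiteSummary], round: str = "followup", arm_set: str = "all"
) -> CVEstimate:
    """Between-cluster coefficient of variation of true prevalence.

    ``k^2 = max(0, (s^2 - pbar*(1-pbar)/ntilde) / pbar^2)`` where ``s^2`` is
    the empirical variance of observed site prevalences, ``pbar`` their mean
    and ``ntilde`` the harmonic-mean site denominator; the binomial sampling
    contribution is subtracted and the estimate truncated at zero.
    """
    if len(summaries) < 2:
        raise UndefinedCVError("need at least two sites to estimate k")
    p = np.array([s.prevalence for s in summaries])
    n = np.array([s.denominator for s in summaries], dtype=float)
    pbar = float(p.mean())
    if pbar == 0.0:
        raise UndefinedCVError("mean prevalence is zero; k undefined")
    s2 = float(np.var(p, ddof=1))
    ntilde = len(n) / float(np.sum(1.0 / n))
    k2 = max(0.0, (s2 - pbar * (1.0 - pbar) / ntilde) / pbar**2)
    return CVEstimate(
        outcome_id=summaries[0].outcome_id,
        round=round,
        arm_set=arm_set,
        k=math.sqrt(k2),
    )
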
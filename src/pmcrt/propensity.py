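"""Exposure-matched secondary analysis.

A logistic model of threshold-level intervention exposure is fitted to
intervention-arm follow-up respondents; exposed respondents are then matched
1:1 without replacement to control-arm respondents by optimal assignment on
the linear-predictor (logit) scale, and the adjusted cluster-level pipeline
is re-run on the matched subset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import linear_sum_assignment

from .cluster_analysis import (
    EffectEstimate,
    baseline_ea_prevalence,
    compute_observed_expected,
    fit_control_model,
    oe_effect,
)
from .errors import FitError, MatchingError
from .outcomes import OutcomeSpec, classify_exposure
from .trial_data import Dataset

DEFAULT_COVARIATES = (
    "age",
    "marital_status",
    "relationship_duration",
    "residence_duration",
    "stayed_elsewhere_past_year",
    "works_outside_community",
    "time_out_in_community",
    "gated_compound",
    "pair_id",
    "ea_pct_gated",
    "ea_n_households",
)


@dataclass(frozen=True)
class PropensityModelSpec:
    """Covariates of the exposure-propensity logistic model."""

    covariates: tuple = DEFAULT_COVARIATES


@dataclass(slots=True)
class ScoredRespondent:
    respondent_id: str
    score: float  # logit of exposure propensity
    pair_id: str
    site_id: str = ""


@dataclass(slots=True)
class MatchResult:
    """1:1 matches between exposed and control respondents."""

    matches: list = field(default_factory=list)  # (exposed_id, control_id, distance)
    unmatched_exposed: list = field(default_factory=list)
    balance: dict = field(default_factory=dict)  # covariate -> (smd_before, smd_after)

    @property
    def total_distance(self) -> float:
        return sum(d for _, _, d in self.matches)

    def matched_ids(self) -> set:
        out = set()
        for e, c, _ in self.matches:
            out.add(e)
            out.add(c)
        return out


def _covariate_frame(ds: Dataset, records, covariates) -> pd.DataFrame:
    """Numeric design frame for the spec covariates (pair_id one-hot)."""
    pair_of = {s.site_id: s.pair_id for s in ds.sites}
    rows = []
    for rec in records:
        row: dict = {"respondent_id": rec.respondent_id}
        for cov in covariates:
            if cov == "age":
                row[cov] = float(rec.age)
            elif cov == "marital_status":
                row[cov] = 1.0 if rec.marital_status == "married_cohabiting" else 0.0
            elif cov == "pair_id":
                row[cov] = pair_of[rec.site_id]
            else:
                v = rec.covariates.get(cov)
                row[cov] = float(v) if v is not None else np.nan
        rows.append(row)
    df = pd.DataFrame(rows).set_index("respondent_id")
    if "pair_id" in df.columns:
        df = pd.get_dummies(df, columns=["pair_id"], drop_first=True, dtype=float)
    return df


class PropensityScorer:
    """Fitted exposure model; scores any record on probability or logit scale."""

    def __init__(self, params: pd.Series, ds: Dataset, covariates: tuple):
        self.params = params
        self._ds = ds
        self.covariates = covariates

    def _design(self, records) -> pd.DataFrame:
        df = _covariate_frame(self._ds, records, self.covariates)
        df.insert(0, "const", 1.0)
        for col in self.params.index:
            if col not in df.columns:
                df[col] = 0.0
        return df[list(self.params.index)]

    def logit(self, records) -> pd.Series:
        X = self._design(records).dropna()
        return X @ self.params

    def score(self, records) -> pd.Series:
        eta = self.logit(records)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_propensity(
    ds: Dataset, spec: PropensityModelSpec = PropensityModelSpec()
) -> PropensityScorer:
    """Logistic model of threshold exposure on intervention-arm follow-up data."""
    intervention_sites = {s.site_id for s in ds.sites if s.arm == "intervention"}
    recs = [
        r
        for r in ds.records
        if r.round == "followup" and r.site_id in intervention_sites
    ]
    if not recs:
        raise FitError("no intervention-arm follow-up records to fit exposure model")
    y = pd.Series(
        [1.0 if classify_exposure(r) == "threshold" else 0.0 for r in recs],
        index=[r.respondent_id for r in recs],
    )
    X = _covariate_frame(ds, recs, spec.covariates)
    X.insert(0, "const", 1.0)
    keep = X.dropna().index
    X, y = X.loc[keep], y.loc[keep]
    if y.nunique() < 2:
        raise FitError("exposure indicator is constant; propensity model unidentifiable")
    model = sm.GLM(y.to_numpy(), X.to_numpy(), family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100)
    if not res.converged or not np.all(np.isfinite(res.params)):
        res = model.fit_regularized(alpha=1e-4, L1_wt=0.0)
    params = pd.Series(res.params, index=X.columns)
    return PropensityScorer(params, ds, spec.covariates)


def _match_stratum(exposed, controls):
    """Optimal 1:1 assignment inside one stratum (deterministic order)."""
    exposed = sorted(exposed, key=lambda s: s.respondent_id)
    controls = sorted(controls, key=lambda s: s.respondent_id)
    cost = np.abs(
        np.subtract.outer(
            np.array([e.score for e in exposed]),
            np.array([c.score for c in controls]),
        )
    )
    rows, cols = linear_sum_assignment(cost)
    matched = {r: c for r, c in zip(rows, cols)}
    pairs, unmatched = [], []
    for i, e in enumerate(exposed):
        if i in matched:
            c = controls[matched[i]]
            pairs.append((e.respondent_id, c.respondent_id, float(abs(e.score - c.score))))
        else:
            unmatched.append(e.respondent_id)
    return pairs, unmatched


def match_exposed(
    exposed: list[ScoredRespondent],
    controls: list[ScoredRespondent],
    within_pair: bool = False,
) -> MatchResult:
    """Optimal 1:1 matching without replacement minimizing total |score diff|.

    With ``within_pair`` matches are restricted to the control site of the
    same matched pair.  When a stratum has more exposed than controls the
    surplus is reported in ``unmatched_exposed`` with a warning.
    """
    if not exposed or not controls:
        raise MatchingError("need at least one exposed and one control respondent")
    result = MatchResult()
    if within_pair:
        strata = sorted({s.pair_id for s in exposed})
        for pair in strata:
            ex = [s for s in exposed if s.pair_id == pair]
            co = [s for s in controls if s.pair_id == pair]
            if not co:
                result.unmatched_exposed.extend(s.respondent_id for s in ex)
                continue
            pairs, unmatched = _match_stratum(ex, co)
            result.matches.extend(pairs)
            result.unmatched_exposed.extend(unmatched)
    else:
        pairs, unmatched = _match_stratum(exposed, controls)
        result.matches.extend(pairs)
        result.unmatched_exposed.extend(unmatched)
    if result.unmatched_exposed:
        warnings.warn(
            f"{len(result.unmatched_exposed)} exposed respondents left unmatched "
            "(more exposed than available controls)",
            stacklevel=2,
        )
    return result


def covariate_balance(
    ds: Dataset,
    exposed_ids,
    control_ids,
    matched: MatchResult,
    covariates=DEFAULT_COVARIATES,
) -> dict:
    """Standardized mean differences exposed-vs-control, before and after matching."""
    by_id = {r.respondent_id: r for r in ds.records}

    def smd(ids_a, ids_b):
        recs_a = [by_id[i] for i in ids_a]
        recs_b = [by_id[i] for i in ids_b]
        covs = tuple(c for c in covariates if c != "pair_id")
        fa = _covariate_frame(ds, recs_a, covs)
        fb = _covariate_frame(ds, recs_b, covs)
        out = {}
        for col in fa.columns:
            sd = math.sqrt((fa[col].var(ddof=1) + fb[col].var(ddof=1)) / 2.0)
            diff = fa[col].mean() - fb[col].mean()
            out[col] = 0.0 if sd == 0 else abs(diff) / sd
        return out

    before = smd(exposed_ids, control_ids)
    m_exp = [e for e, _, _ in matched.matches]
    m_ctl = [c for _, c, _ in matched.matches]
    after = smd(m_exp, m_ctl) if matched.matches else {k: float("nan") for k in before}
    return {k: (before[k], after.get(k, float("nan"))) for k in before}


def score_dataset(
    ds: Dataset, scorer: PropensityScorer
) -> tuple[list[ScoredRespondent], list[ScoredRespondent]]:
    """Logit scores for threshold-exposed intervention respondents and all controls."""
    pair_of = {s.site_id: s.pair_id for s in ds.sites}
    arm_of = {s.site_id: s.arm for s in ds.sites}
    fu = [r for r in ds.records if r.round == "followup"]
    eta = scorer.logit(fu)
    exposed, controls = [], []
    for rec in fu:
        if rec.respondent_id not in eta.index:
            continue  # incomplete covariates
        sr = ScoredRespondent(
            respondent_id=rec.respondent_id,
            score=float(eta[rec.respondent_id]),
            pair_id=pair_of[rec.site_id],
            site_id=rec.site_id,
        )
        if arm_of[rec.site_id] == "intervention":
            if classify_exposure(rec) == "threshold":
                exposed.append(sr)
        else:
            controls.append(sr)
    if not exposed:
        raise MatchingError("no threshold-exposed intervention respondents")
    return exposed, controls


def matched_effect(
    ds: Dataset,
    spec: OutcomeSpec,
    mr: MatchResult,
    baseline_prev: dict | None = None,
) -> EffectEstimate:
    """Adjusted cluster-level comparison restricted to matched respondents.

    Rebuilds site summaries over matched exposed respondents and their
    matched controls, refits the control model on the matched control subset
    and runs the identical observed/expected weighted ANOVA.
    """
    if not mr.matches:
        raise MatchingError("empty match result")
    keep = mr.matched_ids()
    sub = Dataset(
        records=[
            r for r in ds.records
            if r.round != "followup" or r.respondent_id in keep
        ],
        sites=list(ds.sites),
    )
    if baseline_prev is None:
        baseline_prev = baseline_ea_prevalence(sub, spec)
    model = fit_control_model(sub, spec, baseline_prev)
    oes = compute_observed_expected(sub, spec, model)
    est = oe_effect(oes, spec.outcome_id, "matched")
    return est
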
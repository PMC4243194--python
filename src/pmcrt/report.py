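"""Publication-style output tables for the end-to-end analysis.

The effects table mirrors the trial-report layout: one row per indicator
(attitude outcomes split by sex), pooled numerator/denominator per arm at
each round, and crude/adjusted risk ratios with 95% CIs.  Percentages are
rounded to the nearest integer; raw fractions are emitted alongside.
"""

from __future__ import annotations

import logging

import pandas as pd

from .cluster_analysis import (
    adjusted_effect,
    baseline_ea_prevalence,
    crude_effect,
    fit_control_model,
    summarize_sites,
    unpaired_ttest_effect,
)
from .errors import PmcrtError
from .outcomes import BUILTIN_SPECS, OutcomeSpec
from .trial_data import Dataset

log = logging.getLogger("pmcrt")

# (outcome_id, sex restriction) rows of the effects table
ANALYSIS_ROWS: tuple = (
    ("accept_violence", "male"),
    ("accept_violence", "female"),
    ("accept_refuse_sex", "male"),
    ("accept_refuse_sex", "female"),
    ("physical_ipv", None),
    ("sexual_ipv", None),
    ("community_response", None),
    ("concurrency", None),
)


def percent(numerator: int, denominator: int) -> int:
    """Whole-number percentage as printed in the report tables."""
    return round(100.0 * numerator / denominator)


def arm_totals(ds: Dataset, spec: OutcomeSpec, round: str) -> dict:
    """Pooled numerator/denominator per arm (summed over sites)."""
    totals = {arm: [0, 0] for arm in ("intervention", "control")}
    for s in summarize_sites(ds, spec, round):
        totals[s.arm][0] += s.numerator
        totals[s.arm][1] += s.denominator
    return {arm: tuple(v) for arm, v in totals.items()}


def effects_table(
    ds: Dataset, specs: dict | None = None, rows=ANALYSIS_ROWS
) -> pd.DataFrame:
    """Crude + adjusted cluster-level effect estimates for every indicator."""
    if specs is None:
        specs = BUILTIN_SPECS
    out = []
    for outcome_id, sex in rows:
        if outcome_id not in specs:
            continue
        spec = specs[outcome_id]
        if sex is not None:
            spec = spec.restricted_to(sex)
        row: dict = {"outcome": outcome_id, "sex": sex or "both"}
        try:
            fu = arm_totals(ds, spec, "followup")
        except PmcrtError as exc:
            log.warning("skipping %s (%s): %s", outcome_id, sex, exc)
            continue
        for arm in ("intervention", "control"):
            n1, n = fu[arm]
            row[f"fu_{arm}"] = f"{n1}/{n}"
            row[f"fu_{arm}_pct"] = percent(n1, n)
        try:
            bl = arm_totals(ds, spec, "baseline")
            for arm in ("intervention", "control"):
                n1, n = bl[arm]
                row[f"bl_{arm}"] = f"{n1}/{n}"
                row[f"bl_{arm}_pct"] = percent(n1, n)
        except PmcrtError:
            for arm in ("intervention", "control"):
                row[f"bl_{arm}"] = ""
                row[f"bl_{arm}_pct"] = ""

        try:
            summaries = summarize_sites(ds, spec, "followup")
            for s in summaries:
                if s.continuity_applied:
                    log.warning(
                        "continuity correction (0.5) applied: site %s, outcome %s",
                        s.site_id, outcome_id,
                    )
            est = crude_effect(summaries)
            row.update(
                crude_rr=round(est.rr, 2),
                crude_ci_low=round(est.ci_low, 2),
                crude_ci_high=round(est.ci_high, 2),
            )
            tt = unpaired_ttest_effect(summaries)
            row.update(ttest_rr=round(tt.rr, 2))
        except PmcrtError as exc:
            log.warning("crude effect failed for %s (%s): %s", outcome_id, sex, exc)
        try:
            bprev = baseline_ea_prevalence(ds, spec)
            model = fit_control_model(ds, spec, bprev)
            est = adjusted_effect(ds, spec, model=model)
            row.update(
                adj_rr=round(est.rr, 2),
                adj_ci_low=round(est.ci_low, 2),
                adj_ci_high=round(est.ci_high, 2),
            )
        except PmcrtError as exc:
            log.warning("adjusted effect failed for %s (%s): %s", outcome_id, sex, exc)
        out.append(row)
    return pd.DataFrame(out)


_DESCRIPTIVE_PREDICATES = {
    "ever_regular_partner": lambda r: r.ever_regular_partner,
    "regular_partner_past_year": lambda r: r.regular_partner_past_year,
    "partnered_past_year": lambda r: r.partnered_past_year,
    "married_cohabiting": lambda r: r.marital_status == "married_cohabiting",
}


def descriptives_table(ds: Dataset, round: str) -> pd.DataFrame:
    """Respondent-characteristics counts by sex and arm (tidy layout)."""
    arm_of = {s.site_id: s.arm for s in ds.sites}
    rows = []
    for characteristic, pred in _DESCRIPTIVE_PREDICATES.items():
        for sex in ("female", "male"):
            for arm in ("intervention", "control"):
                recs = [
                    r
                    for r in ds.records
                    if r.round == round and r.sex == sex and arm_of[r.site_id] == arm
                ]
                if not recs:
                    continue
                num = sum(1 for r in recs if pred(r))
                rows.append(
                    {
                        "characteristic": characteristic,
                        "sex": sex,
                        "arm": arm,
                        "numerator": num,
                        "denominator": len(recs),
                        "percent": percent(num, len(recs)),
                    }
                )
    return pd.DataFrame(rows)


def pooled_percent(table: pd.DataFrame, characteristic: str, sex: str) -> int:
    """Percentage pooled over arms from a descriptives table."""
    sub = table[(table.characteristic == characteristic) & (table.sex == sex)]
    return percent(int(sub.numerator.sum()), int(sub.denominator.sum()))
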
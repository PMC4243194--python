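"""Composite binary outcomes and the intervention-exposure classification.

Six built-in composite indicators are constructed from item-level responses:

===================  =========================================  ==========
outcome_id           denominator                                direction
===================  =========================================  ==========
accept_violence      all respondents (reported by sex)          decrease
accept_refuse_sex    all respondents (reported by sex)          increase
physical_ipv         women partnered in the past year           decrease
sexual_ipv           women partnered in the past year           decrease
community_response   women whose constructed physical/sexual    increase
                     partner-violence outcome is true
concurrency          non-polygamous men with a regular partner  decrease
                     in the past year
===================  =========================================  ==========

Missingness rule for ``any_yes`` composites: true if any item is "yes",
false only if every item was answered "no", missing otherwise.  The
``helped_and_any_response`` rule additionally requires the gate item
("someone tried to help") to be "yes".
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import yaml

from .codes import (
    ATTITUDE_HIT_ITEMS,
    CONCURRENCY_ITEMS,
    EXPOSURE_ORD,
    HELPED_ITEM,
    PHYSICAL_ITEMS,
    REFUSE_SEX_ITEMS,
    RESPONSE_ITEMS,
    ROUTES,
    SEXUAL_ITEMS,
)
from .errors import OutcomeSpecError
from .trial_data import IndividualRecord

DENOMINATORS = ("all", "partnered_women", "nonpoly_regular_men", "ipv_women")
RULES = ("any_yes", "helped_and_any_response")
DIRECTIONS = ("increase", "decrease")


@dataclass(frozen=True)
class OutcomeSpec:
    """Definition of one composite indicator."""

    outcome_id: str
    denominator: str  # one of DENOMINATORS
    item_codes: tuple
    rule: str = "any_yes"
    direction: str = "decrease"
    sex: str | None = None  # extra restriction, e.g. report attitudes by sex

    def __post_init__(self):
        if self.denominator not in DENOMINATORS:
            raise OutcomeSpecError(f"unknown denominator {self.denominator!r}")
        if self.rule not in RULES:
            raise OutcomeSpecError(f"unknown rule {self.rule!r}")
        if self.direction not in DIRECTIONS:
            raise OutcomeSpecError(f"unknown direction {self.direction!r}")
        if not self.item_codes:
            raise OutcomeSpecError("item_codes must be non-empty")

    def restricted_to(self, sex: str) -> "OutcomeSpec":
        return replace(self, sex=sex)


@dataclass(slots=True)
class OutcomeValue:
    respondent_id: str
    outcome_id: str
    in_denominator: bool
    value: bool | None


BUILTIN_SPECS: dict[str, OutcomeSpec] = {
    s.outcome_id: s
    for s in (
        OutcomeSpec("accept_violence", "all", ATTITUDE_HIT_ITEMS, "any_yes", "decrease"),
        OutcomeSpec("accept_refuse_sex", "all", REFUSE_SEX_ITEMS, "any_yes", "increase"),
        OutcomeSpec("physical_ipv", "partnered_women", PHYSICAL_ITEMS, "any_yes", "decrease"),
        OutcomeSpec("sexual_ipv", "partnered_women", SEXUAL_ITEMS, "any_yes", "decrease"),
        OutcomeSpec(
            "community_response",
            "ipv_women",
            (HELPED_ITEM,) + RESPONSE_ITEMS,
            "helped_and_any_response",
            "increase",
        ),
        OutcomeSpec("concurrency", "nonpoly_regular_men", CONCURRENCY_ITEMS, "any_yes", "decrease"),
    )
}


def get_spec(outcome_id: str) -> OutcomeSpec:
    try:
        return BUILTIN_SPECS[outcome_id]
    except KeyError:
        raise OutcomeSpecError(f"unknown outcome_id {outcome_id!r}") from None


def load_outcome_config(path) -> dict[str, OutcomeSpec]:
    """Load user outcome specs (YAML) merged over the built-in six."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    specs = dict(BUILTIN_SPECS)
    for oid, cfg in raw.items():
        specs[oid] = OutcomeSpec(
            outcome_id=oid,
            denominator=cfg["denominator"],
            item_codes=tuple(cfg["item_codes"]),
            rule=cfg.get("rule", "any_yes"),
            direction=cfg.get("direction", "decrease"),
            sex=cfg.get("sex"),
        )
    return specs


def _any_yes(rec: IndividualRecord, codes) -> bool | None:
    saw_missing = False
    for code in codes:
        v = rec.items.get(code)
        if v == "yes":
            return True
        if v != "no":
            saw_missing = True
    return None if saw_missing else False


def _in_denominator(rec: IndividualRecord, spec: OutcomeSpec) -> bool:
    if spec.sex is not None and rec.sex != spec.sex:
        return False
    d = spec.denominator
    if d == "all":
        return True
    if d == "partnered_women":
        return rec.sex == "female" and rec.partnered_past_year
    if d == "nonpoly_regular_men":
        return (
            rec.sex == "male"
            and rec.polygamous is False
            and rec.regular_partner_past_year
        )
    if d == "ipv_women":
        if rec.sex != "female" or not rec.partnered_past_year:
            return False
        phys = _any_yes(rec, PHYSICAL_ITEMS)
        sexv = _any_yes(rec, SEXUAL_ITEMS)
        return phys is True or sexv is True
    raise OutcomeSpecError(f"unknown denominator {d!r}")


def evaluate_outcome(rec: IndividualRecord, spec: OutcomeSpec) -> OutcomeValue:
    """Evaluate one composite indicator for one respondent.

    ``in_denominator`` applies the indicator's eligibility restriction;
    ``value`` is None when the respondent is out of denominator or the
    answered items cannot determine the composite.
    """
    if not _in_denominator(rec, spec):
        return OutcomeValue(rec.respondent_id, spec.outcome_id, False, None)

    if spec.rule == "any_yes":
        value = _any_yes(rec, spec.item_codes)
    elif spec.rule == "helped_and_any_response":
        helped = rec.items.get(HELPED_ITEM)
        if helped == "no":
            value = False
        elif helped == "yes":
            any_resp = _any_yes(rec, RESPONSE_ITEMS)
            value = any_resp  # True / False / None propagate
        else:
            value = None
    else:  # pragma: no cover - guarded by OutcomeSpec.__post_init__
        raise OutcomeSpecError(f"unknown rule {spec.rule!r}")
    return OutcomeValue(rec.respondent_id, spec.outcome_id, True, value)


def classify_exposure(rec: IndividualRecord) -> str:
    """Classify intervention exposure from the three route frequencies.

    Returns ``"unexposed"``, ``"any"`` (at least one route at least once) or
    ``"threshold"`` (all three routes at least once, or one route at least
    once and a *different* route at least a few times).  Missing routes count
    as "never".
    """
    levels = [EXPOSURE_ORD.get(rec.exposure_counts.get(r, "never"), 0) for r in ROUTES]
    n_once = sum(1 for v in levels if v >= 1)
    if n_once == 0:
        return "unexposed"
    if n_once == 3:
        return "threshold"
    n_few = sum(1 for v in levels if v >= 2)
    # one route >= once plus a different route >= few_times
    if n_once >= 2 and n_few >= 1:
        return "threshold"
    return "any"
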
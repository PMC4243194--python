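"""Domain types, validation and CSV I/O for individual-level trial data.

One CSV row per respondent.  Site/pair/arm structure is carried on every row
and re-derived into :class:`SiteMeta` objects at read time, so a dataset is a
single self-contained file.  Missing values are empty strings in the CSV and
``None`` internally — never conflated with an answered "no", because outcome
denominators depend on the distinction.

Survey eligibility rules (age 18–49; at least one year of residence when a
residence duration is recorded; one respondent per household when household
ids are present) are applied at read time and tallied in a
:class:`ValidationReport`, keeping the analysis modules free of sampling
rules.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import yaml

from .codes import (
    ALL_ITEM_CODES,
    ARMS,
    COVARIATE_KEYS,
    EXPOSURE_LEVELS,
    MARITAL_LEVELS,
    ROUNDS,
    ROUTES,
    SEXES,
)
from .errors import DataError, ParseError, SchemaError

AGE_MIN, AGE_MAX = 18, 49
MIN_RESIDENCE_YEARS = 1.0

_FIXED_COLUMNS = (
    "respondent_id",
    "household_id",
    "site_id",
    "ea_id",
    "pair_id",
    "arm",
    "round",
    "sex",
    "age",
    "marital_status",
    "polygamous",
    "ever_regular_partner",
    "regular_partner_past_year",
    "partnered_past_year",
)

_MANDATORY_COLUMNS = tuple(c for c in _FIXED_COLUMNS if c != "household_id")


def default_schema() -> dict:
    """Column mapping used when no schema config is given.

    ``fields`` maps logical field names to CSV columns; ``items``,
    ``exposure`` and ``covariates`` map codes to columns.  This is the
    extension point for surveys whose variable dictionary differs from the
    built-in one.
    """
    return {
        "fields": {c: c for c in _FIXED_COLUMNS},
        "items": {code: f"item_{code}" for code in ALL_ITEM_CODES},
        "exposure": {route: f"exp_{route}" for route in ROUTES},
        "covariates": {k: f"cov_{k}" for k in COVARIATE_KEYS},
    }


def load_schema(path) -> dict:
    """Read a YAML schema config, overlaying it on the default schema."""
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    schema = default_schema()
    for section in ("fields", "items", "exposure", "covariates"):
        schema[section].update(user.get(section, {}))
    return schema


@dataclass(slots=True)
class IndividualRecord:
    """One survey respondent."""

    respondent_id: str
    site_id: str
    ea_id: str
    round: str  # 'baseline' | 'followup'
    sex: str  # 'female' | 'male'
    age: int
    marital_status: str  # 'married_cohabiting' | 'other'
    polygamous: bool | None
    ever_regular_partner: bool
    regular_partner_past_year: bool
    partnered_past_year: bool  # regular or casual partner in past year
    items: dict = field(default_factory=dict)  # code -> 'yes' | 'no' | None
    exposure_counts: dict = field(default_factory=dict)  # route -> level
    covariates: dict = field(default_factory=dict)
    household_id: str | None = None

    def item(self, code: str) -> str | None:
        return self.items.get(code)


@dataclass(slots=True)
class SiteMeta:
    """One cluster (study site) with its pair, arm and enumeration areas."""

    site_id: str
    pair_id: str
    arm: str  # 'intervention' | 'control'
    ea_ids: tuple = ()
    n_households: int = 0


@dataclass(slots=True)
class ValidationReport:
    n_rows: int = 0
    n_retained: int = 0
    excluded_age: int = 0
    excluded_residence: int = 0
    excluded_duplicate_household: int = 0
    messages: list = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return (
            self.excluded_age
            + self.excluded_residence
            + self.excluded_duplicate_household
        )

    def render(self) -> str:
        lines = [
            f"rows read:            {self.n_rows}",
            f"rows retained:        {self.n_retained}",
            f"excluded (age):       {self.excluded_age}",
            f"excluded (residence): {self.excluded_residence}",
            f"excluded (household): {self.excluded_duplicate_household}",
        ]
        lines.extend(self.messages)
        return "\n".join(lines)


@dataclass(slots=True)
class Dataset:
    """Validated records plus the site/pair structure they live in."""

    records: list
    sites: list
    validation: ValidationReport = field(default_factory=ValidationReport)

    def site(self, site_id: str) -> SiteMeta:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise DataError(f"unknown site_id {site_id!r}")

    def records_for(self, site_id: str, round: str | None = None) -> list:
        return [
            r
            for r in self.records
            if r.site_id == site_id and (round is None or r.round == round)
        ]

    def subset(self, respondent_ids) -> "Dataset":
        keep = set(respondent_ids)
        return Dataset(
            records=[r for r in self.records if r.respondent_id in keep],
            sites=list(self.sites),
            validation=ValidationReport(),
        )

    def arm_of(self, site_id: str) -> str:
        return self.site(site_id).arm

    def pair_of(self, site_id: str) -> str:
        return self.site(site_id).pair_id


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_bool(value: str, column: str, rownum: int, optional: bool = False):
    v = value.strip().lower()
    if v == "":
        if optional:
            return None
        raise ParseError(f"row {rownum}: empty value in mandatory column {column!r}")
    if v in ("1", "true", "yes"):
        return True
    if v in ("0", "false", "no"):
        return False
    raise ParseError(f"row {rownum}: bad boolean {value!r} in column {column!r}")


def _parse_level(value: str, levels, column: str, rownum: int) -> str:
    v = value.strip()
    if v not in levels:
        raise ParseError(
            f"row {rownum}: unknown level {value!r} in column {column!r} "
            f"(expected one of {', '.join(levels)})"
        )
    return v


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_covariate(value: str):
    v = value.strip()
    if v == "":
        return None
    if v in ("0", "1"):  # ambiguous; keep numeric, bool semantics downstream
        return float(v)
    try:
        return float(v)
    except ValueError:
        return v


def read_dataset(path, schema: dict | str | None = None) -> Dataset:
    """Read and validate an individual-level CSV.

    Rows failing survey eligibility are excluded and counted in
    ``Dataset.validation``; structural problems (missing mandatory columns,
    unknown categorical levels, malformed pairs) raise.
    """
    if schema is None:
        schema = default_schema()
    elif not isinstance(schema, dict):
        schema = load_schema(schema)
    fields = schema["fields"]

    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for logical in _MANDATORY_COLUMNS:
            if fields[logical] not in header:
                raise SchemaError(f"missing mandatory column {fields[logical]!r}")
        rows = list(reader)

    report = ValidationReport(n_rows=len(rows))
    records: list[IndividualRecord] = []
    site_info: dict[str, dict] = {}
    seen_households: set[tuple[str, str, str]] = set()

    has_household = fields["household_id"] in header

    for i, row in enumerate(rows, start=2):  # header is line 1
        age_raw = row[fields["age"]].strip()
        try:
            age = int(age_raw)
        except ValueError:
            raise ParseError(f"row {i}: bad age {age_raw!r}") from None

        round_ = _parse_level(row[fields["round"]], ROUNDS, fields["round"], i)
        sex = _parse_level(row[fields["sex"]], SEXES, fields["sex"], i)
        marital = _parse_level(
            row[fields["marital_status"]], MARITAL_LEVELS, fields["marital_status"], i
        )
        arm = _parse_level(row[fields["arm"]], ARMS, fields["arm"], i)

        items = {}
        for code, col in schema["items"].items():
            raw = row.get(col, "")
            raw = "" if raw is None else raw.strip()
            if raw == "":
                continue
            items[code] = _parse_level(raw, ("yes", "no"), col, i)

        exposure = {}
        for route, col in schema["exposure"].items():
            raw = row.get(col, "")
            raw = "" if raw is None else raw.strip()
            if raw == "":
                exposure[route] = "never"
                continue
            exposure[route] = _parse_level(raw, EXPOSURE_LEVELS, col, i)

        covariates = {}
        for key, col in schema["covariates"].items():
            if col in row and row[col] is not None:
                val = _parse_covariate(row[col])
                if val is not None:
                    covariates[key] = val

        rec = IndividualRecord(
            respondent_id=row[fields["respondent_id"]].strip(),
            household_id=(
                row[fields["household_id"]].strip() or None if has_household else None
            ),
            site_id=row[fields["site_id"]].strip(),
            ea_id=row[fields["ea_id"]].strip(),
            round=round_,
            sex=sex,
            age=age,
            marital_status=marital,
            polygamous=_parse_bool(
                row[fields["polygamous"]], fields["polygamous"], i, optional=True
            ),
            ever_regular_partner=_parse_bool(
                row[fields["ever_regular_partner"]], fields["ever_regular_partner"], i
            ),
            regular_partner_past_year=_parse_bool(
                row[fields["regular_partner_past_year"]],
                fields["regular_partner_past_year"],
                i,
            ),
            partnered_past_year=_parse_bool(
                row[fields["partnered_past_year"]], fields["partnered_past_year"], i
            ),
            items=items,
            exposure_counts=exposure,
            covariates=covariates,
        )

        # -- eligibility filters -------------------------------------------
        if not (AGE_MIN <= age <= AGE_MAX):
            report.excluded_age += 1
            continue
        res = rec.covariates.get("residence_duration")
        if res is not None and res < MIN_RESIDENCE_YEARS:
            report.excluded_residence += 1
            continue
        if rec.household_id is not None:
            key = (rec.site_id, rec.round, rec.household_id)
            if key in seen_households:
                report.excluded_duplicate_household += 1
                continue
            seen_households.add(key)

        records.append(rec)
        info = site_info.setdefault(
            rec.site_id, {"pair": None, "arm": None, "eas": set()}
        )
        pair_id = row[fields["pair_id"]].strip()
        if info["pair"] not in (None, pair_id) or info["arm"] not in (None, arm):
            raise DataError(f"site {rec.site_id!r} has inconsistent pair/arm labels")
        info["pair"], info["arm"] = pair_id, arm
        info["eas"].add(rec.ea_id)

    report.n_retained = len(records)

    sites = [
        SiteMeta(
            site_id=sid,
            pair_id=info["pair"],
            arm=info["arm"],
            ea_ids=tuple(sorted(info["eas"])),
        )
        for sid, info in sorted(site_info.items())
    ]
    _check_pairs(sites)
    return Dataset(records=records, sites=sites, validation=report)


def _check_pairs(sites) -> None:
    by_pair: dict[str, list] = {}
    for s in sites:
        by_pair.setdefault(s.pair_id, []).append(s)
    for pair_id, members in by_pair.items():
        if len(members) == 2 and {m.arm for m in members} != set(ARMS):
            raise DataError(f"pair {pair_id!r}: both sites in the same arm")
        if len(members) > 2:
            raise DataError(f"pair {pair_id!r}: more than two sites")


def write_dataset(ds: Dataset, path, schema: dict | None = None) -> None:
    """Write a Dataset back to CSV, inverse of :func:`read_dataset`."""
    if schema is None:
        schema = default_schema()
    fields = schema["fields"]
    site_by_id = {s.site_id: s for s in ds.sites}

    cov_keys = sorted(
        set(schema["covariates"])
        | {k for r in ds.records for k in r.covariates}
    )
    cov_cols = {k: schema["covariates"].get(k, f"cov_{k}") for k in cov_keys}

    header = (
        [fields[c] for c in _FIXED_COLUMNS]
        + [schema["items"][c] for c in ALL_ITEM_CODES]
        + [schema["exposure"][r] for r in ROUTES]
        + [cov_cols[k] for k in cov_keys]
    )

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in ds.records:
            meta = site_by_id.get(rec.site_id)
            if meta is None:
                raise DataError(f"record {rec.respondent_id}: unknown site {rec.site_id!r}")
            row = [
                rec.respondent_id,
                _fmt(rec.household_id),
                rec.site_id,
                rec.ea_id,
                meta.pair_id,
                meta.arm,
                rec.round,
                rec.sex,
                str(rec.age),
                rec.marital_status,
                _fmt(rec.polygamous),
                _fmt(rec.ever_regular_partner),
                _fmt(rec.regular_partner_past_year),
                _fmt(rec.partnered_past_year),
            ]
            row += [rec.items.get(c, "") or "" for c in ALL_ITEM_CODES]
            row += [rec.exposure_counts.get(r, "never") for r in ROUTES]
            row += [_fmt(rec.covariates.get(k)) for k in cov_keys]
            writer.writerow(row)
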
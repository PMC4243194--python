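"""Synthetic pair-matched trial generator.

Generates full individual-level datasets (baseline + follow-up rounds) with
the statistical structure the cluster-level analysis assumes:

* per-outcome site prevalences drawn from a logit-normal cluster model whose
  parameters are moment-matched so the coefficient of variation of true
  prevalences equals a target ``k``;
* an intervention effect injected on the risk-ratio scale at follow-up;
* item-level responses back-filled consistently with each composite outcome
  (one uniformly chosen item set to "yes" when the composite is true, all
  items answered "no" when false, items missing outside the denominator);
* demographics matched to configurable marginals and intervention-exposure
  route counts consistent with the threshold classification.

Every stochastic operation takes an explicit seed; the same seed reproduces
the dataset exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import brentq

from .codes import (
    ATTITUDE_HIT_ITEMS,
    CONCURRENCY_ITEMS,
    HELPED_ITEM,
    PHYSICAL_ITEMS,
    REFUSE_SEX_ITEMS,
    RESPONSE_ITEMS,
    ROUTES,
    SEXUAL_ITEMS,
)
from .errors import CalibrationError
from .outcomes import BUILTIN_SPECS
from .trial_data import Dataset, IndividualRecord, SiteMeta

_ITEMS_BY_OUTCOME = {
    "accept_violence": ATTITUDE_HIT_ITEMS,
    "accept_refuse_sex": REFUSE_SEX_ITEMS,
    "physical_ipv": PHYSICAL_ITEMS,
    "sexual_ipv": SEXUAL_ITEMS,
    "concurrency": CONCURRENCY_ITEMS,
}


# ---------------------------------------------------------------------------
# logit-normal cluster model, moment-matched to a target CV

_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(80)
_GH_W = _GH_W / _GH_W.sum()


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _ln_mean(mu: float, sigma: float) -> float:
    return float(np.sum(_GH_W * _expit(mu + sigma * _GH_X)))


def _ln_cv(mu: float, sigma: float) -> float:
    p = _expit(mu + sigma * _GH_X)
    m = float(np.sum(_GH_W * p))
    v = float(np.sum(_GH_W * p * p)) - m * m
    return math.sqrt(max(v, 0.0)) / m


def logit_normal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a logit-normal with the given mean and coefficient of variation.

    Raises :class:`CalibrationError` when ``cv`` is infeasible for the mean
    (the supremum is ``sqrt((1-mean)/mean)``).
    """
    if not 0.0 < mean < 1.0:
        raise CalibrationError(f"mean prevalence must be in (0,1), got {mean}")
    if cv < 0:
        raise CalibrationError("cv must be non-negative")
    if cv == 0.0:
        return _logit(mean), 0.0
    cv_max = math.sqrt((1.0 - mean) / mean)
    if cv >= 0.95 * cv_max:
        raise CalibrationError(
            f"cv {cv:.3f} infeasible for mean {mean:.3f} (supremum {cv_max:.3f})"
        )

    def mu_for(sigma: float) -> float:
        return brentq(lambda mu: _ln_mean(mu, sigma) - mean, -40.0, 40.0, xtol=1e-12)

    def cv_gap(sigma: float) -> float:
        return _ln_cv(mu_for(sigma), sigma) - cv

    sigma = brentq(cv_gap, 1e-8, 30.0, xtol=1e-10)
    return mu_for(sigma), sigma


def draw_site_prevalences(
    mean: float, cv: float, n_sites: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw true site prevalences from the moment-matched logit-normal model."""
    mu, sigma = logit_normal_params(mean, cv)
    return _expit(mu + sigma * rng.standard_normal(n_sites))


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class OutcomeSim:
    """Generation parameters for one composite outcome."""

    control_prev: object  # float, or {'female': f, 'male': f}
    rr: float = 1.0
    k: float = 0.0
    pair_sd: float = 0.0
    age_coef: float = 0.0  # per-year log-odds shift, for confounding scenarios

    def prev_for(self, sex: str) -> float:
        if isinstance(self.control_prev, dict):
            return float(self.control_prev[sex])
        return float(self.control_prev)

    def mean_prev(self) -> float:
        if isinstance(self.control_prev, dict):
            return float(np.mean(list(self.control_prev.values())))
        return float(self.control_prev)


def default_outcome_sims() -> dict[str, OutcomeSim]:
    return {
        "accept_violence": OutcomeSim({"female": 0.59, "male": 0.75}, rr=0.5, k=0.15),
        "accept_refuse_sex": OutcomeSim({"female": 0.60, "male": 0.62}, rr=1.25, k=0.05),
        "physical_ipv": OutcomeSim(0.22, rr=0.5, k=0.2),
        "sexual_ipv": OutcomeSim(0.20, rr=0.76, k=0.2),
        "community_response": OutcomeSim(0.13, rr=2.0, k=0.3),
        "concurrency": OutcomeSim(0.45, rr=0.57, k=0.15),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic trial."""

    n_pairs: int = 4
    n_per_sex_site: object = 150  # follow-up; int or {'female': n, 'male': n}
    n_per_sex_site_baseline: object = 100
    outcomes: dict = field(default_factory=default_outcome_sims)
    n_eas_per_site: int = 2
    age_mean: float = 28.5
    age_sd: float = 7.5
    married_rate: dict = field(
        default_factory=lambda: {"female": 0.60, "male": 0.51}
    )
    polygamous_rate: dict = field(
        default_factory=lambda: {"female": 0.20, "male": 0.10}
    )
    ever_regular_rate: dict = field(
        default_factory=lambda: {"female": 0.92, "male": 0.76}
    )
    regular_given_ever: dict = field(
        default_factory=lambda: {"female": 0.86, "male": 0.93}
    )
    casual_given_no_regular: dict = field(
        default_factory=lambda: {"female": 0.24, "male": 0.35}
    )
    # threshold / any-but-not-threshold exposure rates by arm and sex
    exposure_threshold: dict = field(
        default_factory=lambda: {
            "intervention": {"female": 0.53, "male": 0.85},
            "control": {"female": 0.01, "male": 0.02},
        }
    )
    exposure_any_extra: dict = field(
        default_factory=lambda: {
            "intervention": {"female": 0.15, "male": 0.06},
            "control": {"female": 0.0, "male": 0.0},
        }
    )
    exposure_residence_coef: float = 0.0  # drives propensity-model scenarios
    age_shift_intervention: float = 0.0  # years; induces confounding by age

    def n_for(self, sex: str, round: str) -> int:
        n = self.n_per_sex_site if round == "followup" else self.n_per_sex_site_baseline
        if isinstance(n, dict):
            return int(n.get(sex, 0))
        return int(n)


def config_from_yaml(path) -> SimulationConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "outcomes" in raw:
        raw["outcomes"] = {
            oid: OutcomeSim(**params) for oid, params in raw["outcomes"].items()
        }
    return SimulationConfig(**raw)


# ---------------------------------------------------------------------------
# trial generation


def _site_truth(cfg: SimulationConfig, rng: np.random.Generator) -> dict:
    """Per-outcome true prevalence for every site, both arms, both rounds.

    Cluster effects persist across rounds; the intervention effect scales
    follow-up prevalence in intervention sites by the target risk ratio.
    """
    truth: dict = {}
    n_sites = 2 * cfg.n_pairs
    for oid, osim in cfg.outcomes.items():
        _, sigma = logit_normal_params(osim.mean_prev(), osim.k)
        pair_eff = (
            rng.normal(0.0, osim.pair_sd, size=cfg.n_pairs)
            if osim.pair_sd > 0
            else np.zeros(cfg.n_pairs)
        )
        site_eff = sigma * rng.standard_normal(n_sites) if sigma > 0 else np.zeros(n_sites)
        per_sex = {}
        sexes = (
            list(osim.control_prev) if isinstance(osim.control_prev, dict)
            else ["female", "male"]
        )
        for sex in sexes:
            target = osim.prev_for(sex)
            if osim.k > 0:
                mu_sex = brentq(
                    lambda mu: _ln_mean(mu, sigma) - target, -40.0, 40.0, xtol=1e-12
                )
            else:
                mu_sex = _logit(target)
            logits = mu_sex + np.repeat(pair_eff, 2) + site_eff
            p_control = _expit(logits)
            p_interv = osim.rr * p_control
            if np.any(p_interv >= 0.99):
                raise CalibrationError(
                    f"{oid}: risk ratio {osim.rr} pushes a site prevalence above 0.99"
                )
            per_sex[sex] = (p_control, p_interv)
        truth[oid] = per_sex
    return truth


def _route_pattern(kind: str, rng: np.random.Generator) -> dict:
    """Route frequencies consistent with an exposure class."""
    if kind == "unexposed":
        return {r: "never" for r in ROUTES}
    order = list(rng.permutation(len(ROUTES)))
    counts = {r: "never" for r in ROUTES}
    if kind == "any":
        counts[ROUTES[order[0]]] = "once"
        return counts
    # threshold: one route once plus a different route at least a few times
    counts[ROUTES[order[0]]] = "once"
    counts[ROUTES[order[1]]] = "few_times" if rng.random() < 0.6 else "many_times"
    if rng.random() < 0.5:
        counts[ROUTES[order[2]]] = "once"
    return counts


def simulate_trial(
    cfg: SimulationConfig, seed: int, return_truth: bool = False
):
    """Generate one synthetic trial dataset (baseline + follow-up).

    With ``return_truth`` also returns the per-record intended composite
    values, keyed ``(respondent_id, outcome_id)``, for round-trip checks.
    """
    rng = np.random.default_rng(seed)
    sites = []
    for i in range(1, cfg.n_pairs + 1):
        sites.append(SiteMeta(f"p{i}i", f"{i}", "intervention"))
        sites.append(SiteMeta(f"p{i}c", f"{i}", "control"))

    site_truth = _site_truth(cfg, rng)

    ea_attrs = {}
    for s in sites:
        eas = tuple(f"{s.site_id}_ea{j + 1}" for j in range(cfg.n_eas_per_site))
        s.ea_ids = eas
        for ea in eas:
            ea_attrs[ea] = (
                float(np.round(rng.uniform(0.1, 0.6), 3)),
                int(rng.integers(300, 900)),
            )

    records: list[IndividualRecord] = []
    truth: dict = {}

    for site_index, meta in enumerate(sites):
        for round_ in ("baseline", "followup"):
            for sex in ("female", "male"):
                n = cfg.n_for(sex, round_)
                if n == 0:
                    continue
                block = _generate_block(
                    cfg, rng, meta, site_index, round_, sex, n, site_truth,
                    ea_attrs, truth,
                )
                records.extend(block)

    ds = Dataset(records=records, sites=sites)
    return (ds, truth) if return_truth else ds


def _generate_block(
    cfg, rng, meta, site_index, round_, sex, n, site_truth, ea_attrs, truth
):
    age_shift = (
        cfg.age_shift_intervention
        if meta.arm == "intervention" and round_ == "followup"
        else 0.0
    )
    age = np.clip(
        np.round(rng.normal(cfg.age_mean + age_shift, cfg.age_sd, size=n)), 18, 49
    ).astype(int)
    married = rng.random(n) < cfg.married_rate[sex]
    poly = married & (rng.random(n) < cfg.polygamous_rate[sex])
    ever_reg = rng.random(n) < cfg.ever_regular_rate[sex]
    reg_py = ever_reg & (rng.random(n) < cfg.regular_given_ever[sex])
    casual = (~reg_py) & (rng.random(n) < cfg.casual_given_no_regular[sex])
    part_py = reg_py | casual

    rel_dur = np.round(rng.exponential(5.0, size=n), 1)
    res_dur = np.round(1.0 + rng.exponential(4.0, size=n), 1)
    stayed = rng.random(n) < 0.15
    works_out = rng.random(n) < 0.40
    time_out = rng.integers(0, 4, size=n)

    ea_idx = np.arange(n) % cfg.n_eas_per_site
    gated_u = rng.random(n)

    # exposure classes (follow-up only; nobody is exposed at baseline)
    if round_ == "followup":
        t_rate = cfg.exposure_threshold[meta.arm][sex]
        a_rate = cfg.exposure_any_extra[meta.arm][sex]
        beta = cfg.exposure_residence_coef
        if beta != 0.0 and 0.0 < t_rate < 1.0:
            p_thr = _expit(_logit(t_rate) + beta * (res_dur - 5.0))
        else:
            p_thr = np.full(n, t_rate)
        u = rng.random(n)
        exp_class = np.where(u < p_thr, 2, np.where(u < p_thr + a_rate, 1, 0))
    else:
        exp_class = np.zeros(n, dtype=int)

    # per-outcome individual draws
    outcome_draws = {}
    for oid, osim in cfg.outcomes.items():
        per_sex = site_truth[oid]
        if sex not in per_sex:
            continue
        p_control, p_interv = per_sex[sex]
        use_interv = meta.arm == "intervention" and round_ == "followup"
        p_site = (p_interv if use_interv else p_control)[site_index]
        if osim.age_coef != 0.0:
            p_ind = _expit(_logit(p_site) + osim.age_coef * (age - cfg.age_mean))
        else:
            p_ind = np.full(n, p_site)
        outcome_draws[oid] = rng.random(n) < p_ind

    class_names = ("unexposed", "any", "threshold")
    block = []
    for i in range(n):
        rid = f"{meta.site_id}-{round_[0]}-{sex[0]}{i:04d}"
        ea = meta.ea_ids[ea_idx[i]]
        pct_gated, n_house = ea_attrs[ea]
        items: dict = {}

        def fill(oid, codes, eligible):
            if oid not in outcome_draws or not eligible:
                return None
            val = bool(outcome_draws[oid][i])
            if val:
                yes_at = int(rng.integers(0, len(codes)))
                for j, c in enumerate(codes):
                    items[c] = "yes" if j == yes_at else "no"
            else:
                for c in codes:
                    items[c] = "no"
            truth[(rid, oid)] = val
            return val

        fill("accept_violence", ATTITUDE_HIT_ITEMS, True)
        fill("accept_refuse_sex", REFUSE_SEX_ITEMS, True)
        phys = fill("physical_ipv", PHYSICAL_ITEMS, sex == "female" and part_py[i])
        sexv = fill("sexual_ipv", SEXUAL_ITEMS, sex == "female" and part_py[i])
        if "community_response" in cfg.outcomes and (phys or sexv):
            val = bool(outcome_draws["community_response"][i])
            if val:
                items[HELPED_ITEM] = "yes"
                yes_at = int(rng.integers(0, len(RESPONSE_ITEMS)))
                for j, c in enumerate(RESPONSE_ITEMS):
                    items[c] = "yes" if j == yes_at else "no"
            else:
                items[HELPED_ITEM] = "no"
            truth[(rid, "community_response")] = val
        fill(
            "concurrency",
            CONCURRENCY_ITEMS,
            sex == "male" and (not poly[i]) and reg_py[i],
        )

        block.append(
            IndividualRecord(
                respondent_id=rid,
                site_id=meta.site_id,
                ea_id=ea,
                round=round_,
                sex=sex,
                age=int(age[i]),
                marital_status="married_cohabiting" if married[i] else "other",
                polygamous=bool(poly[i]),
                ever_regular_partner=bool(ever_reg[i]),
                regular_partner_past_year=bool(reg_py[i]),
                partnered_past_year=bool(part_py[i]),
                items=items,
                exposure_counts=_route_pattern(class_names[exp_class[i]], rng),
                covariates={
                    "relationship_duration": float(rel_dur[i]),
                    "residence_duration": float(res_dur[i]),
                    "stayed_elsewhere_past_year": float(stayed[i]),
                    "works_outside_community": float(works_out[i]),
                    "time_out_in_community": float(time_out[i]),
                    "gated_compound": float(gated_u[i] < pct_gated),
                    "ea_pct_gated": pct_gated,
                    "ea_n_households": float(n_house),
                },
            )
        )
    return block


# ---------------------------------------------------------------------------
# replication driver and summary


@dataclass(frozen=True)
class RecoverySummary:
    outcome_id: str
    scale: str
    n_reps: int
    true_log_rr: float
    mean_log_rr: float
    bias: float
    empirical_se: float  # SD of replicate log-rr estimates
    mc_se: float  # Monte-Carlo SE of the mean
    coverage: float  # share of replicate CIs covering the true RR


def summarize_simulation(
    estimates: list, true_rr: float
) -> RecoverySummary:
    """Bias / empirical SE / CI-coverage summary of replicated estimates."""
    if len(estimates) < 2:
        raise ValueError("need at least two replicates")
    logs = np.array([e.log_rr for e in estimates])
    cover = np.mean([e.ci_low <= true_rr <= e.ci_high for e in estimates])
    sd = float(np.std(logs, ddof=1))
    return RecoverySummary(
        outcome_id=estimates[0].outcome_id,
        scale=estimates[0].scale,
        n_reps=len(estimates),
        true_log_rr=math.log(true_rr),
        mean_log_rr=float(np.mean(logs)),
        bias=float(np.mean(logs) - math.log(true_rr)),
        empirical_se=sd,
        mc_se=sd / math.sqrt(len(logs)),
        coverage=float(cover),
    )


def replicate_trials(
    cfg: SimulationConfig,
    outcome_id: str,
    reps: int,
    seed: int,
    scales: tuple = ("crude", "adjusted"),
) -> dict[str, list]:
    """Simulate ``reps`` trials and estimate the effect on one outcome.

    Returns per-scale lists of :class:`EffectEstimate`.  Seeds for each
    replicate are spawned deterministically from ``seed``.
    """
    from .cluster_analysis import (
        adjusted_effect,
        baseline_ea_prevalence,
        crude_effect,
        fit_control_model,
        summarize_sites,
    )

    spec = BUILTIN_SPECS[outcome_id]
    results: dict[str, list] = {s: [] for s in scales}
    seeds = np.random.SeedSequence(seed).generate_state(reps)
    for r in range(reps):
        ds = simulate_trial(cfg, int(seeds[r]))
        if "crude" in scales:
            summaries = summarize_sites(ds, spec, "followup")
            results["crude"].append(crude_effect(summaries))
        if "adjusted" in scales:
            bprev = baseline_ea_prevalence(ds, spec)
            model = fit_control_model(ds, spec, bprev)
            results["adjusted"].append(adjusted_effect(ds, spec, model=model))
    return results
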
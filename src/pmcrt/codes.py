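"""Canonical questionnaire vocabulary.

Item codes, exposure routes and ordinal exposure levels shared by the data
layer and the outcome constructors.  A record's ``items`` map may only use
codes listed here; a missing key (or ``None`` value) means the item was not
asked or not answered.
"""

from __future__ import annotations

# Physical-violence acts (7 codes).
PHYSICAL_ITEMS: tuple[str, ...] = (
    "phys_slap_throw",
    "phys_push_shove",
    "phys_fist",
    "phys_kick_drag",
    "phys_choke_burn",
    "phys_weapon",
    "phys_stick",
)

# Sexual-violence acts (2 codes).
SEXUAL_ITEMS: tuple[str, ...] = (
    "sex_forced",
    "sex_afraid",
)

# Scenarios in which hitting a partner is judged acceptable (12 codes).
ATTITUDE_HIT_ITEMS: tuple[str, ...] = (
    "att_hit_disobeys",
    "att_hit_answers_back",
    "att_hit_disrespects_relatives",
    "att_hit_suspects_unfaithful",
    "att_hit_finds_unfaithful",
    "att_hit_gossips",
    "att_hit_neglects_children",
    "att_hit_housework",
    "att_hit_refuses_sex",
    "att_hit_accuses_infidelity",
    "att_hit_tells_secrets",
    "att_hit_angry",
)

# Acceptability of a married woman refusing sex (1 code).
REFUSE_SEX_ITEMS: tuple[str, ...] = ("att_refuse_sex_ok",)

# Community response to violence: the gate question plus 6 response types.
HELPED_ITEM: str = "resp_helped"
RESPONSE_ITEMS: tuple[str, ...] = (
    "resp_gathered_people",
    "resp_knocked_door",
    "resp_separated",
    "resp_informed_authority",
    "resp_asked_how_help",
    "resp_told_talk_other",
)

# Sexual concurrency (1 code).
CONCURRENCY_ITEMS: tuple[str, ...] = ("concurrent_partner",)

ALL_ITEM_CODES: tuple[str, ...] = (
    PHYSICAL_ITEMS
    + SEXUAL_ITEMS
    + ATTITUDE_HIT_ITEMS
    + REFUSE_SEX_ITEMS
    + (HELPED_ITEM,)
    + RESPONSE_ITEMS
    + CONCURRENCY_ITEMS
)

# Partner-violence items must be missing when the respondent had no partner
# in the past year.
PARTNER_VIOLENCE_ITEMS: tuple[str, ...] = PHYSICAL_ITEMS + SEXUAL_ITEMS

# Intervention-exposure routes and ordinal frequency levels (low to high).
ROUTES: tuple[str, ...] = ("materials", "activities", "multimedia")
EXPOSURE_LEVELS: tuple[str, ...] = ("never", "once", "few_times", "many_times")
EXPOSURE_ORD: dict[str, int] = {lvl: i for i, lvl in enumerate(EXPOSURE_LEVELS)}

# Covariates carried for the adjustment and propensity models.
COVARIATE_KEYS: tuple[str, ...] = (
    "relationship_duration",
    "residence_duration",
    "stayed_elsewhere_past_year",
    "works_outside_community",
    "time_out_in_community",
    "gated_compound",
    "ea_pct_gated",
    "ea_n_households",
)

ROUNDS: tuple[str, ...] = ("baseline", "followup")
SEXES: tuple[str, ...] = ("female", "male")
ARMS: tuple[str, ...] = ("intervention", "control")
MARITAL_LEVELS: tuple[str, ...] = ("married_cohabiting", "other")
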
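import pytest

from pmcrt.trial_data import Dataset, IndividualRecord, SiteMeta


def make_record(**overrides) -> IndividualRecord:
    """Record factory with sensible defaults (partnered adult woman)."""
    base = dict(
        respondent_id="r1",
        site_id="s1",
        ea_id="s1_ea1",
        round="followup",
        sex="female",
        age=30,
        marital_status="married_cohabiting",
        polygamous=False,
        ever_regular_partner=True,
        regular_partner_past_year=True,
        partnered_past_year=True,
        items={},
        exposure_counts={},
        covariates={},
    )
    base.update(overrides)
    return IndividualRecord(**base)


def single_site_dataset(records, arm="intervention") -> Dataset:
    sites = [SiteMeta("s1", "1", arm, ea_ids=("s1_ea1",))]
    return Dataset(records=records, sites=sites)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_trial():
    """One small complete synthetic trial shared by read-only tests."""
    from pmcrt.synthetic_cohort import SimulationConfig, simulate_trial

    cfg = SimulationConfig(n_per_sex_site=60, n_per_sex_site_baseline=40)
    return simulate_trial(cfg, seed=20260903)
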
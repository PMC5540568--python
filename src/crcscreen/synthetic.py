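"""Synthetic inputs: illustrative parameters, Basque-like population and
round-structured programme count tables.

Everything the pipeline needs can be generated here without downloads.
The natural-history defaults are **illustrative, not calibrated to the
Basque cancer registry** (the programme evaluation prints no
natural-history values): they are chosen to sit in a plausibility
envelope - unscreened cumulative CRC incidence by age 80 of 4-7%, mean
preclinical sojourn of 2-6 years, male onset above female with the female
onset shifted to older ages (CRC in women presents later), matching the
sex ordering of screening benefit seen in FIT programmes.

:func:`table1_fixture` returns the published 2009-2014 programme counts
(three rounds by sex) verbatim as the golden fixture for the indicator
layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .indicators import CountTable
from .natural_history import LifeTable, NaturalHistoryParams, SEXES
from .population import PopulationSpec
from .screening import (ColonoscopyCharacteristics, ParticipationModel,
                        ScreeningPolicy, SurveillanceThresholds,
                        TestCharacteristics)

#: Real-data magnitudes the synthetic population targets.
TARGET_POPULATION_50_69 = {"female": 299_200, "male": 287_500}


# ---------------------------------------------------------------------------
# Natural-history and policy defaults


def make_default_lifetable(sex: str) -> LifeTable:
    """Gompertz-Makeham other-cause mortality, women below men.

    Parameters give period life expectancies of roughly 78 (men) and 84
    (women), in line with a southern-European 2008 population.
    """
    ages = np.arange(0, 101)
    if sex == "male":
        hazard = 2.0e-4 + 3.2e-5 * np.exp(0.092 * ages)
    elif sex == "female":
        hazard = 1.0e-4 + 1.3e-5 * np.exp(0.096 * ages)
    else:
        raise ConfigurationError(f"sex must be one of {SEXES}")
    return LifeTable.from_hazard(sex, ages, hazard)


def make_default_params(sex: str) -> NaturalHistoryParams:
    """Illustrative adenoma-carcinoma parameters for one sex.

    Male onset rates are above female in every band and the female rates
    are shifted towards older ages; the progressive fraction and dwell
    rates put the unscreened lifetime clinical CRC risk by age 80 in the
    4-7% envelope with mean preclinical sojourn between 2 and 6 years.
    """
    edges = np.array([20.0, 40.0, 50.0, 60.0, 70.0, 100.0])
    if sex == "male":
        onset = np.array([0.0026, 0.0108, 0.0200, 0.0280, 0.0310])
    elif sex == "female":
        onset = np.array([0.0010, 0.0046, 0.0100, 0.0215, 0.0380])
    else:
        raise ConfigurationError(f"sex must be one of {SEXES}")
    return NaturalHistoryParams(
        sex=sex,
        onset_age_edges=edges,
        onset_rates=onset,
        frailty_variance=1.0,
        p_progressive=0.22,
        rate_small_to_large=0.12,
        rate_large_to_preclinical=0.11,
        stage_progression_rates=np.array([0.55, 0.60, 0.70]),
        sojourn_rates=np.array([0.12, 0.25, 0.55, 1.00]),
        cure_fraction=np.array([0.90, 0.75, 0.45, 0.05]),
        excess_mortality=np.array([0.15, 0.25, 0.45, 1.00]),
    )


def make_default_test() -> TestCharacteristics:
    """Quantitative FIT at the 20 ug Hb/g cut-off (one sample)."""
    return TestCharacteristics(
        sensitivity={"small_adenoma": 0.04, "large_adenoma": 0.22,
                     "preclinical_I": 0.60, "preclinical_II": 0.72,
                     "preclinical_III": 0.82, "preclinical_IV": 0.88},
        specificity=0.965,
        cutoff_label="20 ug Hb/g")


def make_default_colonoscopy() -> ColonoscopyCharacteristics:
    return ColonoscopyCharacteristics(
        sensitivity={"small_adenoma": 0.77, "large_adenoma": 0.95,
                     "preclinical_I": 0.95, "preclinical_II": 0.97,
                     "preclinical_III": 0.98, "preclinical_IV": 0.98},
        completeness=0.95)


def make_default_policy(programme_start_year: float = 2009.0) -> ScreeningPolicy:
    """Biennial FIT, ages 50-69, with the programme's observed behaviour.

    First-round participation and retention reproduce the published
    programme behaviour (women 69.4% / men 64.0% first round; 91.8%
    regular participation); conversion rates are implied by the observed
    second-round totals.
    """
    return ScreeningPolicy(
        programme_start_year=programme_start_year,
        start_age=50.0, stop_age=70.0, interval=2.0,
        test=make_default_test(),
        participation={
            "female": ParticipationModel(first_round=0.694,
                                         retention=0.918, conversion=0.30),
            "male": ParticipationModel(first_round=0.640,
                                       retention=0.918, conversion=0.25),
        },
        colonoscopy_adherence=0.929,
        colonoscopy=make_default_colonoscopy(),
        thresholds=SurveillanceThresholds(),
        surveillance_stop_age=74.0,
        exclusion_colonoscopy_years=5.0)


def make_population_spec(sample_size: int = 200_000, horizon: int = 30,
                         renewal: bool = False,
                         baseline_year: float = 2008.0) -> PopulationSpec:
    """Basque-like 2008 baseline age structure, ages 30-89.

    Within each sex the single-year strata are flat to age 64 and decline
    exponentially afterwards; each sex is scaled so that its 50-69
    population matches the programme's target-population magnitude
    (~586,700 in total).
    """
    ages = np.arange(30, 90)
    shape = np.where(ages < 65, 1.0, np.exp(-0.045 * (ages - 64)))
    strata = {}
    for sex in SEXES:
        target = TARGET_POPULATION_50_69[sex]
        mask = (ages >= 50) & (ages < 70)
        scale = target / shape[mask].sum()
        strata[sex] = {int(a): float(np.round(scale * s))
                       for a, s in zip(ages, shape)}
    return PopulationSpec(baseline_year=baseline_year, strata=strata,
                          sample_size=sample_size, horizon=horizon,
                          renewal=renewal)


# ---------------------------------------------------------------------------
# Count-table generators


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the Table-1-like synthetic count generator.

    Round structure mirrors an organised programme ramping up: the
    first-round positivity and detection rates sit above later rounds
    (``positivity_decline`` and ``detection_decline`` multiply the rate
    per successive round), participation rises, and the screened stage
    distribution is early-stage heavy.
    """

    population_scale: float = 300_000.0        # round-1 eligible per sex
    round_scale: tuple = (1.0, 0.52, 0.14)
    invited_fraction: float = 0.96
    sex_onset_multiplier: float = 1.9          # male positivity vs female
    participation: dict = field(default_factory=lambda: {
        "female": (0.69, 0.73, 0.75), "male": (0.64, 0.68, 0.70)})
    first_round_positivity: dict = field(default_factory=lambda: {
        "female": 0.052, "male": 0.090})
    positivity_decline: float = 0.82
    colonoscopy_adherence: float = 0.93
    first_round_ppv: dict = field(default_factory=lambda: {
        "advanced_adenoma": 0.40, "crc": 0.058})
    detection_decline: float = 0.80
    stage_distribution_screen: tuple = (0.66, 0.28, 0.06)   # I-II, III-IV, unk

    def __post_init__(self):
        for sex, levels in self.participation.items():
            if any(not 0 <= p <= 1 for p in levels):
                raise ConfigurationError("participation must be in [0, 1]")
        if self.sex_onset_multiplier <= 0 or self.population_scale <= 0:
            raise ConfigurationError("multipliers and scales must be > 0")
        if not np.isclose(sum(self.stage_distribution_screen), 1.0):
            raise ConfigurationError("stage distribution must sum to 1")


def make_count_fixture(config: SyntheticConfig,
                       rng: np.random.Generator) -> CountTable:
    """Draw a synthetic programme count table with Table-1-like structure.

    All counts are binomial/multinomial thinnings down the invitation
    chain, so the invariant chain (invited <= eligible, ...,
    colonoscopies <= positives, stages sum to CRC) holds by construction.
    """
    rows = []
    n_rounds = len(config.round_scale)
    for sex in sorted(SEXES):
        for r in range(n_rounds):
            eligible = int(round(config.population_scale
                                 * config.round_scale[r]))
            invited = int(rng.binomial(eligible, config.invited_fraction))
            p_part = config.participation[sex][r]
            participants = int(rng.binomial(invited, p_part))
            p_pos = (config.first_round_positivity[sex]
                     * config.positivity_decline ** r)
            positives = int(rng.binomial(participants, p_pos))
            colonoscopies = int(rng.binomial(positives,
                                             config.colonoscopy_adherence))
            decline = config.detection_decline ** r
            p_crc = min(1.0, config.first_round_ppv["crc"] * decline)
            crc = int(rng.binomial(colonoscopies, p_crc))
            p_aa = min(1.0, config.first_round_ppv["advanced_adenoma"] * decline)
            aa = int(rng.binomial(colonoscopies - crc, p_aa))
            stages = rng.multinomial(crc, config.stage_distribution_screen)
            rows.append({
                "sex": sex, "round": r + 1, "eligible": eligible,
                "invited": invited, "participants": participants,
                "positives": positives, "colonoscopies": colonoscopies,
                "detected_advanced_adenoma": aa,
                "detected_advanced_neoplasia": aa + crc,
                "detected_crc": crc,
                "crc_stage_i_ii": int(stages[0]),
                "crc_stage_iii_iv": int(stages[1]),
                "crc_stage_unknown": int(stages[2]),
            })
    return CountTable(pd.DataFrame(rows))


def table1_fixture() -> CountTable:
    """The published 2009-2014 Basque programme counts, transcribed
    verbatim (per sex, rounds 1-3), as the golden indicator fixture."""
    with resources.files("crcscreen.data").joinpath(
            "table1_counts.csv").open("r") as fh:
        return CountTable(pd.read_csv(fh))
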
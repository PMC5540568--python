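"""Age-structured baseline population and paired scenario runs.

A :class:`PopulationSpec` describes the baseline calendar year (2008 for
the Basque programme), the real population per sex and single-year age
stratum, the simulated sample size per sex, and the projection horizon.
:func:`build_population` samples a weighted microsimulation sample whose
members carry complete no-screening histories; :func:`run_pair` then
evaluates the no-screening and screening scenarios on the *same* persons
(common random numbers: the natural history is sampled once and shared,
and the overlay uses its own generator), aggregating per-calendar-year
counts scaled by the population weight.

The default population is a closed cohort of the baseline year; an
optional renewal mode adds an entering cohort at the youngest stratum age
each year so programme activity does not vanish as the cohort ages out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .natural_history import (HistoryBatch, LifeTable, NaturalHistoryParams,
                              Person, persons_from_batch, sample_histories)
from .screening import ScreeningPolicy, apply_screening

MODES = ("screen", "surveillance", "interval", "clinical")
N_STAGES = 4


@dataclass(frozen=True)
class PopulationSpec:
    """Baseline population structure and simulation sizing.

    ``strata`` maps sex -> {age (int, attained at baseline) -> persons}.
    ``sample_size`` is the number of simulated persons per sex; the
    scaling weight is real persons / simulated persons, per sex.
    """

    baseline_year: float = 2008.0
    strata: dict = None
    sample_size: int = 200_000
    horizon: int = 30
    renewal: bool = False

    def __post_init__(self):
        if not self.strata:
            raise ConfigurationError("population spec needs strata")
        for sex, ages in self.strata.items():
            for a, n in ages.items():
                if n < 0:
                    raise ConfigurationError("stratum sizes must be >= 0")
        if self.total() <= 0:
            raise ConfigurationError("total population must be > 0")
        if self.sample_size <= 0:
            raise ConfigurationError("sample size must be > 0")
        if self.horizon < 0:
            raise ConfigurationError("horizon must be >= 0")

    def total(self, sex: str | None = None) -> float:
        sexes = [sex] if sex else list(self.strata)
        return float(sum(sum(self.strata[s].values()) for s in sexes))

    def weight(self, sex: str) -> float:
        w = self.total(sex) / self.sample_size
        if w <= 0:
            raise ConfigurationError("population weight must be > 0")
        return w


@dataclass
class ScenarioResult:
    """Per-calendar-year outputs of one scenario arm.

    All count arrays share the calendar index ``years`` (the first
    projection year is baseline + 1) and are scaled to the real
    population by the stratum weight.  CRC detections are split by mode
    (screen / surveillance / interval / clinical) and stage I-IV.
    """

    label: str
    sex: str
    years: np.ndarray
    weight: float
    n_simulated: int
    seed: int | None = None
    invitations: np.ndarray = None
    participants: np.ndarray = None
    positives: np.ndarray = None
    diagnostic_colonoscopies: np.ndarray = None
    surveillance_colonoscopies: np.ndarray = None
    adenomas_detected: np.ndarray = None
    crc_by_mode_stage: np.ndarray = None   # (n_years, 4 modes, 4 stages)
    crc_incidence: np.ndarray = None
    crc_deaths: np.ndarray = None
    person_years: np.ndarray = None
    life_years_lost: np.ndarray = None

    _COUNT_FIELDS = ("invitations", "participants", "positives",
                     "diagnostic_colonoscopies", "surveillance_colonoscopies",
                     "adenomas_detected", "crc_incidence", "crc_deaths",
                     "person_years", "life_years_lost")

    def __post_init__(self):
        n = len(self.years)
        for name in self._COUNT_FIELDS:
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(n))
        if self.crc_by_mode_stage is None:
            self.crc_by_mode_stage = np.zeros((n, len(MODES), N_STAGES))

    @property
    def total_colonoscopies(self) -> np.ndarray:
        return self.diagnostic_colonoscopies + self.surveillance_colonoscopies

    def crc_detected(self, mode: str | None = None) -> np.ndarray:
        """Yearly CRC diagnoses, optionally restricted to one mode."""
        if mode is None:
            return self.crc_by_mode_stage.sum(axis=(1, 2))
        return self.crc_by_mode_stage[:, MODES.index(mode), :].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        data = {"year": self.years.astype(int)}
        for name in self._COUNT_FIELDS:
            data[name] = getattr(self, name)
        data["total_colonoscopies"] = self.total_colonoscopies
        for m in MODES:
            data[f"crc_{m}"] = self.crc_detected(m)
        for s in range(N_STAGES):
            data[f"crc_stage_{s + 1}"] = self.crc_by_mode_stage[:, :, s].sum(axis=1)
        df = pd.DataFrame(data)
        df.insert(0, "scenario", self.label)
        df.insert(1, "sex", self.sex)
        return df

    @staticmethod
    def combine(results: list["ScenarioResult"]) -> "ScenarioResult":
        """Sum results over sexes (same calendar index and label)."""
        first = results[0]
        out = ScenarioResult(label=first.label, sex="all",
                             years=first.years.copy(),
                             weight=np.nan,
                             n_simulated=sum(r.n_simulated for r in results))
        for r in results:
            if not np.array_equal(r.years, first.years):
                raise ConfigurationError("calendar indices differ")
            for name in ScenarioResult._COUNT_FIELDS:
                setattr(out, name, getattr(out, name) + getattr(r, name))
            out.crc_by_mode_stage = out.crc_by_mode_stage + r.crc_by_mode_stage
        return out


@dataclass
class PairedPersonOutcomes:
    """Per-person paired outcomes used for dominance checks."""

    sex: str
    unscreened_diag_age: np.ndarray
    unscreened_diag_stage: np.ndarray
    unscreened_diag_lesion: np.ndarray
    unscreened_crc_death_age: np.ndarray
    screened_diag_age: np.ndarray
    screened_diag_stage: np.ndarray
    screened_diag_lesion: np.ndarray
    screened_crc_death_age: np.ndarray
    other_cause_death_age: np.ndarray


def build_population(spec: PopulationSpec,
                     params: dict[str, NaturalHistoryParams],
                     lifetables: dict[str, LifeTable],
                     rng: np.random.Generator) -> list[Person]:
    """Sample the baseline population with resolved no-screening histories.

    Ages are assigned multinomially over the strata; a person of stratum
    age ``a`` is ``a + 0.5`` years old at the baseline mid-year, so the
    birth year is ``baseline_year - a``.  Other-cause death is drawn
    conditional on being alive at baseline.  In renewal mode, one
    entering cohort (the youngest stratum age) is added per projection
    year, scaled to the stratum size.
    """
    persons: list[Person] = []
    offset = 0
    for sex in sorted(spec.strata):
        ages = np.array(sorted(spec.strata[sex]))
        sizes = np.array([spec.strata[sex][a] for a in ages], dtype=float)
        probs = sizes / sizes.sum()
        counts = rng.multinomial(spec.sample_size, probs)
        age_at_baseline = np.repeat(ages, counts).astype(float) + 0.5
        birth_year = spec.baseline_year + 0.5 - age_at_baseline
        n = len(age_at_baseline)
        batch = sample_histories(params[sex], lifetables[sex], n, rng,
                                 baseline_age=age_at_baseline)
        persons.extend(persons_from_batch(batch, birth_year=birth_year,
                                          id_offset=offset))
        offset += n
        if spec.renewal:
            # one entering cohort per projection year, the size of the
            # youngest baseline stratum (qualitative steady-state mode)
            a0 = int(ages[0])
            m = int(counts[0])
            for y in range(1, spec.horizon + 1):
                if m == 0:
                    break
                entry_age = np.full(m, a0 + 0.5)
                b = sample_histories(params[sex], lifetables[sex], m, rng,
                                     baseline_age=entry_age)
                persons.extend(persons_from_batch(
                    b, birth_year=spec.baseline_year + y - a0,
                    id_offset=offset))
                offset += m
    return persons


def _year_index(t: float, baseline: float, horizon: int) -> int:
    """Index of calendar time t in the projection window, or -1."""
    i = int(np.floor(t)) - int(baseline) - 1
    return i if 0 <= i < horizon else -1


def _accumulate_outcome(res: ScenarioResult, baseline: float, horizon: int,
                        birth: float, oc_age: float,
                        diag_age: float, diag_stage: int, mode: str,
                        crc_death_age: float) -> None:
    if diag_stage > 0 and np.isfinite(diag_age):
        i = _year_index(birth + diag_age, baseline, horizon)
        if i >= 0:
            res.crc_by_mode_stage[i, MODES.index(mode), diag_stage - 1] += 1
            res.crc_incidence[i] += 1
    if np.isfinite(crc_death_age) and crc_death_age < oc_age:
        i = _year_index(birth + crc_death_age, baseline, horizon)
        if i >= 0:
            res.crc_deaths[i] += 1
            res.life_years_lost[i] += oc_age - crc_death_age


_EVENT_FIELD = {"invitation": "invitations",
                "FIT_negative": "participants",
                "FIT_positive": "participants",
                "diagnostic_colonoscopy": "diagnostic_colonoscopies",
                "surveillance_colonoscopy": "surveillance_colonoscopies",
                "lesion_removal": "adenomas_detected"}


def run_pair(population: list[Person], policy: ScreeningPolicy,
             params: dict[str, NaturalHistoryParams],
             spec: PopulationSpec, rng: np.random.Generator, *,
             collect_person_outcomes: bool = False):
    """Run the no-screening and screening scenarios on the same persons.

    Returns ``(no_screening, screening)`` :class:`ScenarioResult` pairs
    (per-sex results combined over sexes are left to the caller via
    :meth:`ScenarioResult.combine`); with ``collect_person_outcomes`` a
    dict sex -> :class:`PairedPersonOutcomes` is appended to the return.
    """
    baseline = spec.baseline_year
    horizon = spec.horizon
    years = np.arange(int(baseline) + 1, int(baseline) + 1 + horizon)
    max_year = baseline + 1 + horizon

    by_sex: dict[str, list[Person]] = {}
    for p in population:
        by_sex.setdefault(p.sex, []).append(p)

    unscreened, screened, outcomes = [], [], {}
    for sex in sorted(by_sex):
        persons = by_sex[sex]
        w = spec.weight(sex)
        res_u = ScenarioResult(label="no_screening", sex=sex, years=years,
                               weight=w, n_simulated=len(persons))
        res_s = ScenarioResult(label="screening", sex=sex, years=years,
                               weight=w, n_simulated=len(persons))
        if collect_person_outcomes:
            n = len(persons)
            rec = PairedPersonOutcomes(
                sex=sex,
                unscreened_diag_age=np.full(n, np.inf),
                unscreened_diag_stage=np.zeros(n, dtype=int),
                unscreened_diag_lesion=np.full(n, -1, dtype=int),
                unscreened_crc_death_age=np.full(n, np.inf),
                screened_diag_age=np.full(n, np.inf),
                screened_diag_stage=np.zeros(n, dtype=int),
                screened_diag_lesion=np.full(n, -1, dtype=int),
                screened_crc_death_age=np.full(n, np.inf),
                other_cause_death_age=np.full(n, np.inf))
        death_u = np.empty(len(persons))
        death_s = np.empty(len(persons))
        for j, person in enumerate(persons):
            birth = person.birth_year
            # no-screening arm: clinical course only
            _accumulate_outcome(res_u, baseline, horizon, birth,
                                person.other_cause_death_age,
                                person.crc_diagnosis_age,
                                person.crc_diagnosis_stage, "clinical",
                                person.crc_death_age)
            death_u[j] = person.death_age
            # screening arm
            out = apply_screening(person, policy, params[sex], rng,
                                  record_events=True, max_year=max_year)
            for ev in out.events:
                f = _EVENT_FIELD.get(ev.kind)
                if f is None:
                    continue
                i = ev.year - int(baseline) - 1
                if 0 <= i < horizon:
                    getattr(res_s, f)[i] += 1
                    if ev.kind == "FIT_positive":
                        res_s.positives[i] += 1
            _accumulate_outcome(res_s, baseline, horizon, birth,
                                person.other_cause_death_age,
                                out.diagnosis_age, out.diagnosis_stage,
                                out.diagnosis_mode or "clinical",
                                out.crc_death_age)
            death_s[j] = out.death_age
            if collect_person_outcomes:
                rec.unscreened_diag_age[j] = person.crc_diagnosis_age
                rec.unscreened_diag_stage[j] = person.crc_diagnosis_stage
                rec.unscreened_diag_lesion[j] = person.crc_diagnosis_lesion
                rec.unscreened_crc_death_age[j] = person.crc_death_age
                rec.screened_diag_age[j] = out.diagnosis_age
                rec.screened_diag_stage[j] = out.diagnosis_stage
                rec.screened_diag_lesion[j] = out.diagnosis_lesion
                rec.screened_crc_death_age[j] = out.crc_death_age
                rec.other_cause_death_age[j] = person.other_cause_death_age

        # person-years per calendar year, vectorised over persons
        births = np.array([p.birth_year for p in persons])
        for res, deaths in ((res_u, death_u), (res_s, death_s)):
            death_t = births + deaths
            starts = years[None, :].astype(float)
            alive = np.clip(np.minimum(death_t[:, None], starts + 1.0)
                            - starts, 0.0, 1.0)
            res.person_years[:] = alive.sum(axis=0)
        for res in (res_u, res_s):
            for name in ScenarioResult._COUNT_FIELDS:
                setattr(res, name, getattr(res, name) * w)
            res.crc_by_mode_stage = res.crc_by_mode_stage * w
        unscreened.append(res_u)
        screened.append(res_s)
        if collect_person_outcomes:
            outcomes[sex] = rec

    if collect_person_outcomes:
        return unscreened, screened, outcomes
    return unscreened, screened


def project_activity(result: ScenarioResult, years_of_interest) -> pd.DataFrame:
    """Programme-activity projection rows for selected calendar years.

    Mirrors the structure of a published projection table: invitations,
    participants (with %), diagnostic, surveillance and total
    colonoscopies, adenomas detected and CRC detected.
    """
    years = np.atleast_1d(np.asarray(years_of_interest, dtype=int))
    rows = []
    for y in years:
        idx = np.nonzero(result.years == y)[0]
        if len(idx) == 0:
            raise ConfigurationError(f"year {y} outside the projection horizon")
        i = idx[0]
        inv = result.invitations[i]
        part = result.participants[i]
        rows.append({
            "year": int(y),
            "invitations": inv,
            "participants": part,
            "participation_pct": 100.0 * part / inv if inv > 0 else np.nan,
            "diagnostic_colonoscopies": result.diagnostic_colonoscopies[i],
            "surveillance_colonoscopies": result.surveillance_colonoscopies[i],
            "total_colonoscopies": result.total_colonoscopies[i],
            "adenomas_detected": result.adenomas_detected[i],
            "crc_detected": result.crc_detected()[i],
        })
    return pd.DataFrame(rows)
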
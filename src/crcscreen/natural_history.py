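"""Colorectal-cancer natural history: adenoma-carcinoma life histories.

The disease model follows the adenoma-carcinoma sequence.  Adenomas arise
in each individual according to a non-homogeneous Poisson process whose
age-band onset rate is multiplied by an individual gamma frailty (mean 1).
A lesion starts as a small adenoma (<10 mm) and may grow into a large
adenoma (>=10 mm).  A "progressive" fraction of adenomas can transform
into preclinical invasive cancer, which passes through stages I-IV.  In
every preclinical stage, clinical presentation (symptomatic diagnosis)
competes with progression to the next stage; the presentation rate is the
reciprocal of the mean stage sojourn time.  All dwell times are
exponential (piecewise-exponential over the path), one rate per
transition.

Death from other causes is drawn once per individual from a sex-specific
lifetable by inverse-transform sampling.  Survival after a clinical CRC
diagnosis is a per-stage mixture of cure (probability ``cure_fraction``)
and exponential excess mortality (rate ``excess_mortality``), attached at
the diagnosis age.  The two uniforms that drive post-diagnosis survival
are drawn once per person and stored, so that a screening overlay can
re-evaluate survival at an anticipated stage with common random numbers.

The module exposes both a per-person operation surface
(:func:`sample_other_cause_death`, :func:`sample_lesion_history`,
:func:`resolve_clinical_course`) and a vectorised batch sampler
(:func:`sample_histories`) that the population builders use; both share
one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

# Lesion state codes, ordered by severity.
SMALL_ADENOMA = 0
LARGE_ADENOMA = 1
PRECLINICAL_I = 2
PRECLINICAL_II = 3
PRECLINICAL_III = 4
PRECLINICAL_IV = 5

N_STATES = 6
N_PRECLINICAL = 4

STATE_NAMES = {
    SMALL_ADENOMA: "small_adenoma",
    LARGE_ADENOMA: "large_adenoma",
    PRECLINICAL_I: "preclinical_I",
    PRECLINICAL_II: "preclinical_II",
    PRECLINICAL_III: "preclinical_III",
    PRECLINICAL_IV: "preclinical_IV",
}

SEXES = ("male", "female")


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# Lifetable


@dataclass(frozen=True)
class LifeTable:
    """Sex-specific all-cause (other-cause) mortality table.

    Parameters
    ----------
    sex : {"male", "female"}
    ages : array of int
        Increasing age grid in years; must start at 0 and reach >= 100.
    survival : array of float
        Probability of surviving from birth to each grid age;
        ``survival[0] == 1`` and the column is non-increasing.
    """

    sex: str
    ages: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ages", _as_float_array(self.ages))
        object.__setattr__(self, "survival", _as_float_array(self.survival))
        self.validate()

    @classmethod
    def from_hazard(cls, sex: str, ages, hazard) -> "LifeTable":
        """Build from a per-year hazard column: S(a) = exp(-sum of h)."""
        ages = _as_float_array(ages)
        hazard = _as_float_array(hazard)
        if np.any(hazard < 0):
            raise ConfigurationError("lifetable hazard must be >= 0")
        if len(hazard) != len(ages):
            raise ConfigurationError("hazard and age grids differ in length")
        widths = np.diff(ages)
        cumhaz = np.concatenate([[0.0], np.cumsum(hazard[:-1] * widths)])
        return cls(sex=sex, ages=ages, survival=np.exp(-cumhaz))

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise ConfigurationError(f"lifetable sex must be one of {SEXES}")
        if self.ages[0] != 0 or self.ages[-1] < 100:
            raise ConfigurationError("lifetable age grid must cover 0..100")
        if np.any(np.diff(self.ages) <= 0):
            raise ConfigurationError("lifetable age grid must be increasing")
        if abs(self.survival[0] - 1.0) > 1e-12:
            raise ConfigurationError("lifetable survival at age 0 must be 1")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ConfigurationError("lifetable survival must be non-increasing")
        if np.any(self.survival < 0):
            raise ConfigurationError("lifetable survival must be >= 0")

    def survival_at(self, age) -> np.ndarray:
        """Linear interpolation of the survival curve at continuous ages."""
        return np.interp(age, self.ages, self.survival)

    def sample_death_age(self, rng: np.random.Generator, n: int | None = None,
                         min_age=0.0) -> np.ndarray | float:
        """Inverse-transform draw(s) of the other-cause death age.

        With ``min_age`` the draw is conditional on being alive at that age
        (uniform on (0, S(min_age))).  Mass below S(max age) is assigned to
        the last grid age.
        """
        scalar = n is None
        size = 1 if scalar else n
        s_min = self.survival_at(min_age)
        u = rng.uniform(0.0, s_min, size=size)
        # invert the (decreasing) survival curve; np.interp needs ascending x
        age = np.interp(u, self.survival[::-1], self.ages[::-1])
        age = np.maximum(age, np.asarray(min_age, dtype=float))
        return float(age[0]) if scalar else age


def sample_other_cause_death(lifetable: LifeTable, sex: str,
                             rng_stream: np.random.Generator) -> float:
    """Draw one other-cause death age for a person of the given sex."""
    if lifetable.sex != sex:
        raise ConfigurationError(
            f"lifetable is for sex {lifetable.sex!r}, requested {sex!r}")
    return lifetable.sample_death_age(rng_stream)


# ---------------------------------------------------------------------------
# Natural-history parameters


@dataclass(frozen=True)
class NaturalHistoryParams:
    """All rates of the adenoma-carcinoma natural-history model for one sex.

    Units: onset rates in adenomas per person-year within each age band;
    all transition/sojourn rates per lesion-year; survival parameters per
    stage I-IV (cure probability, excess death rate per year).
    """

    sex: str
    onset_age_edges: np.ndarray        # len k+1, e.g. [20, 40, ..., 100]
    onset_rates: np.ndarray            # len k
    frailty_variance: float = 1.0      # gamma frailty, mean 1
    p_progressive: float = 0.1
    rate_small_to_large: float = 0.05
    rate_large_to_preclinical: float = 0.05
    stage_progression_rates: np.ndarray = field(
        default_factory=lambda: np.array([0.55, 0.60, 0.70]))
    sojourn_rates: np.ndarray = field(
        default_factory=lambda: np.array([0.12, 0.25, 0.55, 1.00]))
    cure_fraction: np.ndarray = field(
        default_factory=lambda: np.array([0.90, 0.75, 0.45, 0.05]))
    excess_mortality: np.ndarray = field(
        default_factory=lambda: np.array([0.15, 0.25, 0.45, 1.00]))

    def __post_init__(self):
        for name in ("onset_age_edges", "onset_rates",
                     "stage_progression_rates", "sojourn_rates",
                     "cure_fraction", "excess_mortality"):
            object.__setattr__(self, name, _as_float_array(getattr(self, name)))
        self.validate()

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise ConfigurationError(f"sex must be one of {SEXES}")
        if len(self.onset_rates) != len(self.onset_age_edges) - 1:
            raise ConfigurationError(
                "onset_rates must have one entry per age band")
        if np.any(np.diff(self.onset_age_edges) <= 0):
            raise ConfigurationError("onset age band edges must increase")
        for name in ("onset_rates", "stage_progression_rates",
                     "sojourn_rates", "excess_mortality"):
            if np.any(getattr(self, name) < 0):
                raise ConfigurationError(f"{name} must be >= 0")
        if len(self.stage_progression_rates) != N_PRECLINICAL - 1:
            raise ConfigurationError("need 3 stage progression rates (I-III)")
        for name in ("sojourn_rates", "cure_fraction", "excess_mortality"):
            if len(getattr(self, name)) != N_PRECLINICAL:
                raise ConfigurationError(f"{name} needs one entry per stage I-IV")
        if not (0.0 <= self.p_progressive <= 1.0):
            raise ConfigurationError("p_progressive must be in [0, 1]")
        if np.any(self.cure_fraction < 0) or np.any(self.cure_fraction > 1):
            raise ConfigurationError("cure fractions must be in [0, 1]")
        if self.frailty_variance < 0:
            raise ConfigurationError("frailty variance must be >= 0")
        if self.rate_small_to_large < 0 or self.rate_large_to_preclinical < 0:
            raise ConfigurationError("transition rates must be >= 0")

    # -- onset process helpers (piecewise-constant rate) --

    def cumulative_onset(self, ages) -> np.ndarray:
        """Integral of the onset rate from age 0 to each given age."""
        edges = self.onset_age_edges
        widths = np.diff(edges)
        cum = np.concatenate([[0.0], np.cumsum(self.onset_rates * widths)])
        ages = np.asarray(ages, dtype=float)
        a = np.clip(ages, edges[0], edges[-1])
        out = np.interp(a, edges, cum)
        # rate is 0 outside the band range; clip handles both tails
        return out

    def invert_cumulative_onset(self, u) -> np.ndarray:
        """Inverse of :meth:`cumulative_onset` over positive-rate bands."""
        edges = self.onset_age_edges
        widths = np.diff(edges)
        cum = np.concatenate([[0.0], np.cumsum(self.onset_rates * widths)])
        # drop flat (zero-rate) segments so the inverse is well defined
        keep = np.concatenate([[True], np.diff(cum) > 0])
        keep[0] = True
        xp, fp = cum[keep], edges[keep]
        if len(xp) < 2:
            raise ConfigurationError("onset rate is zero everywhere")
        return np.interp(u, xp, fp)

    def frailty_gamma_shape(self) -> float:
        if self.frailty_variance <= 0:
            raise ConfigurationError("degenerate frailty has no gamma shape")
        return 1.0 / self.frailty_variance

    def scaled(self, multiplier: float) -> "NaturalHistoryParams":
        """Return a copy with all onset rates multiplied by ``multiplier``."""
        if multiplier < 0:
            raise ConfigurationError("onset multiplier must be >= 0")
        return replace(self, onset_rates=self.onset_rates * multiplier)


# ---------------------------------------------------------------------------
# Lesions and persons


@dataclass(slots=True)
class Lesion:
    """One adenoma/carcinoma trajectory, as state-entry ages.

    ``inf`` marks a state that is never reached.  ``clinical_age`` is the
    age of symptomatic presentation (the lesion leaves its preclinical
    stage for clinical diagnosis); ``clinical_stage`` is 1..4, or 0 when
    no presentation ever occurs.
    """

    onset_age: float
    large_age: float = np.inf
    preclinical_ages: tuple = (np.inf, np.inf, np.inf, np.inf)
    clinical_age: float = np.inf
    clinical_stage: int = 0
    progressive: bool = False

    def state_at(self, age: float) -> int | None:
        """Most advanced state occupied at ``age`` (None before onset or
        after clinical presentation)."""
        if age < self.onset_age or age >= self.clinical_age:
            return None
        state = SMALL_ADENOMA
        if age >= self.large_age:
            state = LARGE_ADENOMA
        for s in range(N_PRECLINICAL):
            if age >= self.preclinical_ages[s]:
                state = PRECLINICAL_I + s
        return state

    def entry_ages(self) -> np.ndarray:
        return np.array([self.onset_age, self.large_age,
                         *self.preclinical_ages])

    def check_invariants(self) -> None:
        path = self.entry_ages()
        finite = np.isfinite(path)
        if np.any(np.diff(path[finite]) <= 0):
            raise AssertionError("transition ages must be strictly increasing")
        if finite[2:].any() and not self.progressive:
            raise AssertionError("non-progressive lesion left adenoma states")
        if np.isfinite(self.clinical_age):
            s = self.clinical_stage
            if not (1 <= s <= 4):
                raise AssertionError("clinical stage must be 1..4")
            if self.clinical_age <= self.preclinical_ages[s - 1]:
                raise AssertionError(
                    "clinical presentation must fall inside the stage sojourn")


@dataclass(slots=True)
class Person:
    """One simulated individual's complete no-screening life history."""

    id: int
    sex: str
    birth_year: float
    frailty: float
    other_cause_death_age: float
    lesions: list = field(default_factory=list)
    u_cure: float = np.nan          # shared survival uniforms (CRN)
    u_time: float = np.nan
    crc_diagnosis_age: float = np.inf     # no-screening clinical diagnosis
    crc_diagnosis_stage: int = 0
    crc_diagnosis_lesion: int = -1        # index into ``lesions``
    crc_death_age: float = np.inf         # no-screening CRC death
    death_age: float = np.inf             # min(other-cause, CRC)


# ---------------------------------------------------------------------------
# Vectorised batch sampling


@dataclass
class LesionArrays:
    """Struct-of-arrays layout of all lesions in a batch."""

    person: np.ndarray        # person index per lesion
    onset: np.ndarray
    large: np.ndarray         # entry age into large-adenoma state (inf: never)
    preclinical: np.ndarray   # (m, 4) entry ages into stages I..IV
    clinical_age: np.ndarray  # inf if no presentation
    clinical_stage: np.ndarray  # 0 or 1..4
    progressive: np.ndarray   # bool

    def __len__(self):
        return len(self.onset)


@dataclass
class HistoryBatch:
    """Vectorised no-screening histories for ``n`` persons of one sex."""

    sex: str
    frailty: np.ndarray
    other_cause_death_age: np.ndarray
    u_cure: np.ndarray
    u_time: np.ndarray
    lesions: LesionArrays
    diagnosis_age: np.ndarray      # inf if never clinically diagnosed
    diagnosis_stage: np.ndarray
    diagnosis_lesion: np.ndarray   # global lesion row, -1 if none
    crc_death_age: np.ndarray      # inf if cured / no diagnosis
    death_age: np.ndarray          # min(other-cause, CRC death)

    def __len__(self):
        return len(self.frailty)


def _safe_exponential(rng, rate: float, size: int) -> np.ndarray:
    """Exp(rate) draws; rate 0 yields +inf (transition never happens)."""
    e = rng.standard_exponential(size)
    if rate <= 0:
        return np.full(size, np.inf)
    return e / rate


def _sample_lesion_arrays(params: NaturalHistoryParams,
                          oc_death_age: np.ndarray,
                          frailty: np.ndarray,
                          rng: np.random.Generator) -> LesionArrays:
    """Sample lesion onsets and full trajectories for a batch of persons.

    Onset: thinned non-homogeneous Poisson process with cumulative rate
    frailty * integral of the age-band rate, truncated at the other-cause
    death age.  Transitions: independent exponential dwell times; in each
    preclinical stage clinical presentation competes with progression.
    """
    n = len(oc_death_age)
    cum_at_death = params.cumulative_onset(oc_death_age)
    lam = frailty * cum_at_death
    counts = rng.poisson(lam)
    m = int(counts.sum())
    person = np.repeat(np.arange(n), counts)
    if m == 0:
        empty = np.empty(0)
        return LesionArrays(person=person.astype(int), onset=empty,
                            large=empty, preclinical=np.empty((0, 4)),
                            clinical_age=empty,
                            clinical_stage=np.empty(0, dtype=int),
                            progressive=np.empty(0, dtype=bool))
    u = rng.uniform(size=m) * np.repeat(cum_at_death, counts)
    onset = params.invert_cumulative_onset(u)

    progressive = rng.uniform(size=m) < params.p_progressive
    large = onset + _safe_exponential(rng, params.rate_small_to_large, m)
    to_pre = large + _safe_exponential(rng, params.rate_large_to_preclinical, m)

    preclinical = np.full((m, 4), np.inf)
    clinical_age = np.full(m, np.inf)
    clinical_stage = np.zeros(m, dtype=int)

    entry = np.where(progressive, to_pre, np.inf)
    preclinical[:, 0] = entry
    for s in range(N_PRECLINICAL):
        prog_rate = (params.stage_progression_rates[s]
                     if s < N_PRECLINICAL - 1 else 0.0)
        soj_rate = params.sojourn_rates[s]
        total = prog_rate + soj_rate
        dwell = _safe_exponential(rng, total, m)
        u_evt = rng.uniform(size=m)
        p_clin = 1.0 if total <= 0 else soj_rate / total
        present = u_evt < p_clin
        exit_age = entry + dwell
        here = np.isfinite(entry)
        clin_here = here & present & np.isfinite(exit_age)
        clinical_age[clin_here] = exit_age[clin_here]
        clinical_stage[clin_here] = s + 1
        entry = np.where(here & ~present, exit_age, np.inf)
        if s < N_PRECLINICAL - 1:
            preclinical[:, s + 1] = entry

    return LesionArrays(person=person, onset=onset, large=large,
                        preclinical=preclinical, clinical_age=clinical_age,
                        clinical_stage=clinical_stage, progressive=progressive)


def crc_survival_age(diagnosis_age, stage, u_cure, u_time,
                     params: NaturalHistoryParams):
    """Age at CRC death for a diagnosis at ``stage`` (1..4), or inf if cured.

    Mixture-cure survival: with probability ``cure_fraction[stage]`` the
    person never dies of CRC; otherwise the residual lifetime is
    exponential with the stage excess-mortality rate.  The two uniforms
    are person-level so overlays can re-evaluate at an anticipated stage.
    """
    stage = np.asarray(stage)
    idx = np.clip(stage - 1, 0, 3)
    pi = params.cure_fraction[idx]
    rho = params.excess_mortality[idx]
    cured = np.asarray(u_cure) < pi
    with np.errstate(divide="ignore"):
        t = -np.log(np.asarray(u_time)) / rho
    return np.where(cured | (stage <= 0), np.inf, np.asarray(diagnosis_age) + t)


def _resolve_batch(params, oc_death_age, u_cure, u_time,
                   les: LesionArrays):
    """Earliest clinical presentation per person and the resulting CRC death."""
    n = len(oc_death_age)
    diag_age = np.full(n, np.inf)
    diag_stage = np.zeros(n, dtype=int)
    diag_lesion = np.full(n, -1, dtype=int)
    if len(les):
        valid = les.clinical_age < oc_death_age[les.person]
        np.minimum.at(diag_age, les.person[valid], les.clinical_age[valid])
        rows = np.nonzero(valid)[0]
        first = rows[les.clinical_age[rows] == diag_age[les.person[rows]]]
        diag_stage[les.person[first]] = les.clinical_stage[first]
        diag_lesion[les.person[first]] = first
    crc_death = crc_survival_age(diag_age, diag_stage, u_cure, u_time, params)
    crc_death = np.where(diag_stage > 0, crc_death, np.inf)
    death = np.minimum(oc_death_age, crc_death)
    return diag_age, diag_stage, diag_lesion, crc_death, death


def sample_histories(params: NaturalHistoryParams, lifetable: LifeTable,
                     n: int, rng: np.random.Generator, *,
                     baseline_age=None) -> HistoryBatch:
    """Sample ``n`` complete no-screening life histories of one sex.

    ``baseline_age`` (scalar or array), when given, conditions the
    other-cause death age on being alive at that age (used when building a
    prevalent baseline population); lesion histories are always sampled
    from birth.
    """
    if lifetable.sex != params.sex:
        raise ConfigurationError("lifetable and parameter sexes differ")
    if params.frailty_variance > 0:
        shape = params.frailty_gamma_shape()
        frailty = rng.gamma(shape, 1.0 / shape, size=n)
    else:
        frailty = np.ones(n)
    min_age = 0.0 if baseline_age is None else baseline_age
    oc = lifetable.sample_death_age(rng, n, min_age=min_age)
    u_cure = rng.uniform(size=n)
    u_time = rng.uniform(size=n)
    les = _sample_lesion_arrays(params, oc, frailty, rng)
    diag_age, diag_stage, diag_lesion, crc_death, death = _resolve_batch(
        params, oc, u_cure, u_time, les)
    return HistoryBatch(sex=params.sex, frailty=frailty,
                        other_cause_death_age=oc, u_cure=u_cure,
                        u_time=u_time, lesions=les,
                        diagnosis_age=diag_age, diagnosis_stage=diag_stage,
                        diagnosis_lesion=diag_lesion,
                        crc_death_age=crc_death, death_age=death)


def lesions_of(batch: HistoryBatch, person_index: int) -> list[Lesion]:
    """Materialise the Lesion objects of one person in a batch."""
    les = batch.lesions
    rows = np.nonzero(les.person == person_index)[0]
    return [_lesion_from_row(les, r) for r in rows]


def _lesion_from_row(les: LesionArrays, r: int) -> Lesion:
    return Lesion(onset_age=float(les.onset[r]),
                  large_age=float(les.large[r]),
                  preclinical_ages=tuple(les.preclinical[r]),
                  clinical_age=float(les.clinical_age[r]),
                  clinical_stage=int(les.clinical_stage[r]),
                  progressive=bool(les.progressive[r]))


# ---------------------------------------------------------------------------
# Per-person operation surface


def sample_lesion_history(params: NaturalHistoryParams, person: Person,
                          rng_stream: np.random.Generator) -> list[Lesion]:
    """Sample the lesion sequence of one person (requires sex, frailty and
    other-cause death age to be set)."""
    if person.sex != params.sex:
        raise ConfigurationError("person and parameter sexes differ")
    les = _sample_lesion_arrays(
        params, np.array([person.other_cause_death_age]),
        np.array([person.frailty]), rng_stream)
    return [_lesion_from_row(les, r) for r in range(len(les))]


def resolve_clinical_course(person: Person, params: NaturalHistoryParams,
                            rng_stream: np.random.Generator) -> Person:
    """Attach the no-screening clinical diagnosis and CRC death to a person.

    The earliest clinical presentation before the other-cause death age
    sets the diagnosis; survival is drawn from the stage-specific
    mixture-cure model.  The survival uniforms are stored on the person.
    """
    if np.isnan(person.u_cure):
        person.u_cure = float(rng_stream.uniform())
        person.u_time = float(rng_stream.uniform())
    best_age, best_stage, best_idx = np.inf, 0, -1
    for i, lesion in enumerate(person.lesions):
        if (np.isfinite(lesion.clinical_age)
                and lesion.clinical_age < person.other_cause_death_age
                and lesion.clinical_age < best_age):
            best_age, best_stage, best_idx = (lesion.clinical_age,
                                              lesion.clinical_stage, i)
    person.crc_diagnosis_age = best_age
    person.crc_diagnosis_stage = best_stage
    person.crc_diagnosis_lesion = best_idx
    if best_stage > 0:
        person.crc_death_age = float(crc_survival_age(
            best_age, best_stage, person.u_cure, person.u_time, params))
    else:
        person.crc_death_age = np.inf
    person.death_age = min(person.other_cause_death_age, person.crc_death_age)
    return person


def persons_from_batch(batch: HistoryBatch, *, birth_year,
                       id_offset: int = 0) -> list[Person]:
    """Materialise Person objects (with Lesion lists) from a batch.

    ``birth_year`` is a scalar or per-person array of calendar birth years.
    """
    n = len(batch)
    birth_year = np.broadcast_to(np.asarray(birth_year, dtype=float), (n,))
    les = batch.lesions
    order = np.argsort(les.person, kind="stable")
    lesion_lists: list[list[Lesion]] = [[] for _ in range(n)]
    lesion_rows: list[list[int]] = [[] for _ in range(n)]
    for r in order:
        p = les.person[r]
        lesion_lists[p].append(_lesion_from_row(les, r))
        lesion_rows[p].append(r)
    persons = []
    for i in range(n):
        diag_row = batch.diagnosis_lesion[i]
        local = (lesion_rows[i].index(diag_row) if diag_row >= 0 else -1)
        persons.append(Person(
            id=id_offset + i, sex=batch.sex, birth_year=float(birth_year[i]),
            frailty=float(batch.frailty[i]),
            other_cause_death_age=float(batch.other_cause_death_age[i]),
            lesions=lesion_lists[i],
            u_cure=float(batch.u_cure[i]), u_time=float(batch.u_time[i]),
            crc_diagnosis_age=float(batch.diagnosis_age[i]),
            crc_diagnosis_stage=int(batch.diagnosis_stage[i]),
            crc_diagnosis_lesion=local,
            crc_death_age=float(batch.crc_death_age[i]),
            death_age=float(batch.death_age[i])))
    return persons
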
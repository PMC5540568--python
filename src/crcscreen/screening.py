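"""FIT screening programme overlaid on fixed natural histories.

The overlay never modifies the no-screening fields of a
:class:`~crcscreen.natural_history.Person`: it walks the person's frozen
lesion trajectories, applies invitations, participation behaviour, FIT
results, colonoscopy and surveillance, and produces a separate screened
outcome.  Detected adenomas are removed (their trajectory is truncated,
so any later clinical presentation of that lesion is voided); detected
preclinical cancers become screen-detected CRC at the current stage.

Survival after a screen-detected cancer is re-evaluated at the detection
age and (anticipated) stage using the person's stored survival uniforms,
so stage shift alone drives the benefit.  Because a detection with no
stage shift would otherwise move the death *earlier* by the lead time,
the screened CRC death age of a lesion is floored at that same lesion's
no-screening CRC death age: early detection never hastens death.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import ConfigurationError
from .natural_history import (LARGE_ADENOMA, N_STATES, PRECLINICAL_I,
                              SEXES, SMALL_ADENOMA, STATE_NAMES, Person,
                              crc_survival_age)


class FollowUpCategory(Enum):
    """Post-colonoscopy follow-up recommendation.

    The six categories map to exactly one next action and interval:
    return to FIT screening in 10 y (normal, hyperplastic), FIT in 5 y
    (low-risk adenomas), surveillance colonoscopy in 3 y (intermediate)
    or 1 y (high risk), or referral to treatment (cancer).  The model has
    no hyperplastic-polyp state, so that category is never assigned but is
    kept for completeness of the coding list.
    """

    NORMAL_10Y = "normal_10y"
    HYPERPLASTIC_10Y = "hyperplastic_10y"
    LOW_RISK_5Y_TEST = "low_risk_5y_test"
    INTERMEDIATE_3Y_COLONOSCOPY = "intermediate_3y_colonoscopy"
    HIGH_RISK_1Y_COLONOSCOPY = "high_risk_1y_colonoscopy"
    CANCER_REFERRAL = "cancer_referral"


#: Years until the next action for each category (None = treatment referral).
FOLLOWUP_INTERVALS = {
    FollowUpCategory.NORMAL_10Y: 10.0,
    FollowUpCategory.HYPERPLASTIC_10Y: 10.0,
    FollowUpCategory.LOW_RISK_5Y_TEST: 5.0,
    FollowUpCategory.INTERMEDIATE_3Y_COLONOSCOPY: 3.0,
    FollowUpCategory.HIGH_RISK_1Y_COLONOSCOPY: 1.0,
    FollowUpCategory.CANCER_REFERRAL: None,
}

#: Categories whose next action is a surveillance colonoscopy.
SURVEILLANCE_CATEGORIES = frozenset({
    FollowUpCategory.INTERMEDIATE_3Y_COLONOSCOPY,
    FollowUpCategory.HIGH_RISK_1Y_COLONOSCOPY,
})


def _state_probability_vector(d, what) -> np.ndarray:
    """Accept a dict keyed by state name or a length-6 sequence."""
    if isinstance(d, dict):
        try:
            vec = np.array([float(d[STATE_NAMES[s]]) for s in range(N_STATES)])
        except KeyError as e:
            raise ConfigurationError(f"{what}: missing state {e}") from e
    else:
        vec = np.asarray(d, dtype=float)
        if vec.shape != (N_STATES,):
            raise ConfigurationError(f"{what}: need one value per lesion state")
    if np.any(vec < 0) or np.any(vec > 1):
        raise ConfigurationError(f"{what}: probabilities must be in [0, 1]")
    return vec


@dataclass(frozen=True)
class TestCharacteristics:
    """Per-state FIT sensitivity and per-round specificity.

    ``sensitivity`` has one probability for each lesion state
    (small/large adenoma, preclinical I-IV); ``specificity`` is the
    probability of a negative test in a person-round with no lesion in a
    detectable state.  ``cutoff_label`` is free text (e.g. "20 ug Hb/g").
    """

    sensitivity: np.ndarray
    specificity: float
    cutoff_label: str = "20 ug Hb/g"

    def __post_init__(self):
        vec = _state_probability_vector(self.sensitivity, "FIT sensitivity")
        object.__setattr__(self, "sensitivity", vec)
        if not (0.0 <= self.specificity <= 1.0):
            raise ConfigurationError("specificity must be in [0, 1]")
        if np.any(np.diff(vec) < 0):
            warnings.warn("FIT sensitivity is not non-decreasing along the "
                          "small->large->preclinical state path",
                          stacklevel=2)


@dataclass(frozen=True)
class ColonoscopyCharacteristics:
    """Per-state detection sensitivity and completeness (caecum reached)."""

    sensitivity: np.ndarray
    completeness: float = 0.95

    def __post_init__(self):
        vec = _state_probability_vector(self.sensitivity,
                                        "colonoscopy sensitivity")
        object.__setattr__(self, "sensitivity", vec)
        if not (0.0 <= self.completeness <= 1.0):
            raise ConfigurationError("completeness must be in [0, 1]")


@dataclass(frozen=True)
class ParticipationModel:
    """Two-state attendance behaviour for one sex.

    First invitation: Bernoulli(first round probability, optionally by
    age band).  Afterwards, previous attenders re-attend with
    ``retention`` and previous non-attenders convert with ``conversion``.
    """

    first_round: float | tuple = 0.65
    retention: float = 0.92
    conversion: float = 0.25

    def __post_init__(self):
        for name in ("retention", "conversion"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        fr = self.first_round
        if np.isscalar(fr):
            if not (0.0 <= fr <= 1.0):
                raise ConfigurationError("first_round must be in [0, 1]")
        else:
            for lo, hi, p in fr:
                if lo >= hi or not (0.0 <= p <= 1.0):
                    raise ConfigurationError("bad first_round age band")

    def first_round_probability(self, age: float) -> float:
        if np.isscalar(self.first_round):
            return float(self.first_round)
        for lo, hi, p in self.first_round:
            if lo <= age < hi:
                return float(p)
        return 0.0


@dataclass(frozen=True)
class SurveillanceThresholds:
    """Size-only adenoma risk classification (European-guideline style).

    The model carries no dysplasia grade, so risk is classified from the
    number of detected adenomas and how many are large (>=10 mm):
    1-2 small -> low risk; any large or 3-4 adenomas -> intermediate;
    >= ``high_large`` large or >= ``high_total`` adenomas -> high risk.
    """

    intermediate_total: int = 3
    high_large: int = 3
    high_total: int = 5


@dataclass(frozen=True)
class ScreeningPolicy:
    """Complete definition of the organised FIT screening programme."""

    programme_start_year: float = 2009.0
    start_age: float = 50.0
    stop_age: float = 70.0            # exclusive: last invitation before 70
    interval: float = 2.0
    test: TestCharacteristics = None
    participation: dict = None        # sex -> ParticipationModel
    colonoscopy_adherence: float = 0.93
    colonoscopy: ColonoscopyCharacteristics = None
    thresholds: SurveillanceThresholds = field(
        default_factory=SurveillanceThresholds)
    surveillance_stop_age: float = 74.0
    exclusion_colonoscopy_years: float = 5.0

    def __post_init__(self):
        if self.start_age >= self.stop_age:
            raise ConfigurationError("start age must be below stop age")
        if self.interval <= 0:
            raise ConfigurationError("inter-round interval must be > 0")
        if not (0.0 <= self.colonoscopy_adherence <= 1.0):
            raise ConfigurationError("colonoscopy adherence must be in [0, 1]")
        if self.test is None or self.colonoscopy is None:
            raise ConfigurationError("policy needs test and colonoscopy "
                                     "characteristics")
        if self.participation is None:
            raise ConfigurationError("policy needs participation models")
        for sex in self.participation:
            if sex not in SEXES:
                raise ConfigurationError(f"unknown sex {sex!r} in participation")

    def participation_for(self, sex: str) -> ParticipationModel:
        try:
            return self.participation[sex]
        except KeyError:
            raise ConfigurationError(
                f"policy has no participation model for sex {sex!r}")


@dataclass(slots=True)
class ScreeningEvent:
    """One dated programme event for one person (tidy-CSV exportable)."""

    person_id: int
    year: int
    age: float
    kind: str
    state: str = ""
    category: str = ""


@dataclass(slots=True)
class ScreeningHistory:
    """Mutable per-person programme state used by the event loop."""

    attended_before: bool | None = None     # None: never invited
    next_screen_due: float = -np.inf        # calendar time
    surveillance_due: float | None = None
    last_colonoscopy: float = -np.inf
    last_negative_screen: float | None = None
    diagnosed: bool = False


@dataclass
class ScreenedOutcome:
    """Screened-arm counterpart of a person's no-screening course."""

    diagnosis_age: float = np.inf
    diagnosis_stage: int = 0
    diagnosis_lesion: int = -1
    diagnosis_mode: str = ""           # screen / surveillance / interval / clinical
    crc_death_age: float = np.inf
    death_age: float = np.inf
    removal_ages: dict = field(default_factory=dict)   # lesion idx -> age
    events: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Elementary operations


def eligible_for_invitation(person: Person, year: float,
                            policy: ScreeningPolicy,
                            history: ScreeningHistory) -> bool:
    """Invitation filter at calendar time ``year`` (mid-year convention).

    True iff the person is alive, in the target age range, has no prior
    CRC diagnosis, no colonoscopy within the exclusion window, is not on
    a pending surveillance schedule and is not deferred by a 5- or
    10-year follow-up recommendation.
    """
    age = year - person.birth_year
    if not (policy.start_age <= age < policy.stop_age):
        return False
    if year >= person.birth_year + person.other_cause_death_age:
        return False
    if history.diagnosed:
        return False
    if year - history.last_colonoscopy < policy.exclusion_colonoscopy_years:
        return False
    if history.surveillance_due is not None:
        return False
    if year < history.next_screen_due:
        return False
    return True


def draw_participation(person: Person, round_index: int,
                       policy: ScreeningPolicy,
                       rng_stream: np.random.Generator, *,
                       attended_before: bool | None = None,
                       age: float | None = None) -> bool:
    """Attendance draw for one invitation.

    ``round_index`` 0 means the first invitation ever received (uses the
    first-round probability); later rounds use retention or conversion
    depending on ``attended_before``.
    """
    model = policy.participation_for(person.sex)
    if age is None:
        age = policy.start_age
    if round_index == 0 or attended_before is None:
        p = model.first_round_probability(age)
    elif attended_before:
        p = model.retention
    else:
        p = model.conversion
    return bool(rng_stream.uniform() < p)


def _most_advanced_state(person: Person, age: float, removal_ages) -> int | None:
    state = None
    for i, lesion in enumerate(person.lesions):
        if i in removal_ages:
            continue
        s = lesion.state_at(age)
        if s is not None and (state is None or s > state):
            state = s
    return state


def fit_test(person: Person, age: float, test: TestCharacteristics,
             rng_stream: np.random.Generator, *,
             removal_ages=frozenset()) -> bool:
    """One FIT result: True = positive.

    Positive with the state-specific sensitivity of the most advanced
    lesion present, or with 1 - specificity when no lesion is present.
    """
    state = _most_advanced_state(person, age, removal_ages)
    p = (1.0 - test.specificity if state is None
         else float(test.sensitivity[state]))
    return bool(rng_stream.uniform() < p)


def classify_followup(findings) -> FollowUpCategory:
    """Map colonoscopy findings to a follow-up category.

    ``findings`` is a sequence of detected lesion states (ints); an empty
    sequence is explicitly allowed and yields NORMAL_10Y.  Precedence:
    cancer > high risk > intermediate > low risk > normal.
    """
    return _classify(findings, SurveillanceThresholds())


def _classify(findings, thresholds: SurveillanceThresholds) -> FollowUpCategory:
    states = list(findings)
    if any(s >= PRECLINICAL_I for s in states):
        return FollowUpCategory.CANCER_REFERRAL
    n_large = sum(1 for s in states if s == LARGE_ADENOMA)
    n_total = len(states)
    if n_large >= thresholds.high_large or n_total >= thresholds.high_total:
        return FollowUpCategory.HIGH_RISK_1Y_COLONOSCOPY
    if n_large >= 1 or n_total >= thresholds.intermediate_total:
        return FollowUpCategory.INTERMEDIATE_3Y_COLONOSCOPY
    if n_total >= 1:
        return FollowUpCategory.LOW_RISK_5Y_TEST
    return FollowUpCategory.NORMAL_10Y


def colonoscopy(person: Person, age: float,
                characteristics: ColonoscopyCharacteristics,
                rng_stream: np.random.Generator, *,
                removal_ages=frozenset(),
                thresholds: SurveillanceThresholds | None = None):
    """One colonoscopy: per-lesion detection plus follow-up category.

    Each present lesion is detected independently with the state-specific
    sensitivity.  An incomplete examination (probability
    1 - completeness) is repeated once in the same sitting-year, giving
    missed lesions a second detection chance; a second failure is treated
    as complete.  Returns ``(detected, category, n_examinations)`` where
    ``detected`` is a list of (lesion index, state).
    """
    thresholds = thresholds or SurveillanceThresholds()
    present = []
    for i, lesion in enumerate(person.lesions):
        if i in removal_ages:
            continue
        s = lesion.state_at(age)
        if s is not None:
            present.append((i, s))
    detected = [(i, s) for i, s in present
                if rng_stream.uniform() < characteristics.sensitivity[s]]
    n_exams = 1
    if rng_stream.uniform() >= characteristics.completeness:
        n_exams = 2
        found = {i for i, _ in detected}
        detected += [(i, s) for i, s in present if i not in found
                     and rng_stream.uniform() < characteristics.sensitivity[s]]
        rng_stream.uniform()  # completeness of the repeat (logged only)
    category = _classify((s for _, s in detected), thresholds)
    return detected, category, n_exams


# ---------------------------------------------------------------------------
# Full overlay


def _screened_crc_death(person: Person, diag_age: float, stage: int,
                        lesion_idx: int, params) -> float:
    death = float(crc_survival_age(diag_age, stage, person.u_cure,
                                   person.u_time, params))
    if lesion_idx == person.crc_diagnosis_lesion and lesion_idx >= 0:
        # lead-time floor: detecting the same lesion earlier never
        # hastens death relative to its clinical course
        death = max(death, person.crc_death_age)
    return death


def apply_screening(person: Person, policy: ScreeningPolicy, params,
                    rng_stream: np.random.Generator, *,
                    record_events: bool = True,
                    max_year: float = np.inf) -> ScreenedOutcome:
    """Run the full screening event loop over one person's life history.

    ``params`` is the person's sex-specific
    :class:`~crcscreen.natural_history.NaturalHistoryParams` (needed for
    the stage-specific survival of screen-detected cancers).  The
    person's no-screening fields are left untouched.
    """
    if person.sex not in policy.participation:
        raise ConfigurationError(
            f"policy has no participation model for sex {person.sex!r}")
    out = ScreenedOutcome()
    hist = ScreeningHistory()
    birth = person.birth_year
    death_t = birth + person.other_cause_death_age
    model = policy.participation_for(person.sex)
    test = policy.test
    colo = policy.colonoscopy

    def emit(kind, t, state="", category=""):
        if record_events:
            out.events.append(ScreeningEvent(
                person_id=person.id, year=int(np.floor(t)), age=t - birth,
                kind=kind, state=state, category=category))

    def clinical_candidate():
        best_t, best_i = np.inf, -1
        for i, lesion in enumerate(person.lesions):
            if i in out.removal_ages or not np.isfinite(lesion.clinical_age):
                continue
            t = birth + lesion.clinical_age
            if t < best_t:
                best_t, best_i = t, i
        return best_t, best_i

    def finish_diagnosis(t, stage, lesion_idx, mode, age=None):
        # ``age`` bypasses the calendar round-trip so a clinical diagnosis
        # reproduces the no-screening course to the last bit
        if age is None:
            age = t - birth
        out.diagnosis_age = age
        out.diagnosis_stage = stage
        out.diagnosis_lesion = lesion_idx
        out.diagnosis_mode = mode
        out.crc_death_age = _screened_crc_death(person, age, stage,
                                                lesion_idx, params)
        hist.diagnosed = True
        kind = {"screen": "screen_detected_CRC",
                "surveillance": "screen_detected_CRC",
                "interval": "interval_CRC",
                "clinical": "clinical_CRC"}[mode]
        emit(kind, t, state=f"stage_{stage}", category=mode)

    def do_colonoscopy(t, kind):
        age = t - birth
        detected, category, n_exams = colonoscopy(
            person, age, colo, rng_stream,
            removal_ages=out.removal_ages, thresholds=policy.thresholds)
        for _ in range(n_exams):
            emit(kind, t)
        hist.last_colonoscopy = t
        cancers = [(i, s) for i, s in detected if s >= PRECLINICAL_I]
        for i, s in detected:
            out.removal_ages[i] = age
            if s < PRECLINICAL_I:
                emit("lesion_removal", t, state=STATE_NAMES[s])
        if cancers:
            i, s = max(cancers, key=lambda x: x[1])
            stage = s - PRECLINICAL_I + 1
            mode = "surveillance" if kind == "surveillance_colonoscopy" else "screen"
            finish_diagnosis(t, stage, i, mode)
            return
        # no cancer: schedule next action from the risk category
        emit("followup", t, category=category.value)
        hist.last_negative_screen = t
        if category in SURVEILLANCE_CATEGORIES:
            hist.surveillance_due = t + FOLLOWUP_INTERVALS[category]
        else:
            hist.surveillance_due = None
            hist.next_screen_due = t + FOLLOWUP_INTERVALS[category]

    # programme round times (mid-year), shared by the whole population
    first_round_t = policy.programme_start_year + 0.5
    cursor = -np.inf          # time just after the last handled event
    last_invitation_t = -np.inf
    eps = 1e-9                # grid-snap tolerance
    step = 1e-6               # cursor advance past a handled event

    def next_round_time():
        """Earliest programme round at which this person is invited."""
        if hist.surveillance_due is not None or hist.diagnosed:
            return np.inf
        t_min = max(cursor, first_round_t, birth + policy.start_age,
                    hist.next_screen_due,
                    hist.last_colonoscopy + policy.exclusion_colonoscopy_years)
        kk = max(0, int(np.ceil((t_min - first_round_t - eps)
                                / policy.interval)))
        t = first_round_t + kk * policy.interval
        if (t >= death_t or t >= max_year
                or t - birth >= policy.stop_age):
            return np.inf
        return t

    while not hist.diagnosed:
        t_clin, clin_idx = clinical_candidate()

        # next surveillance contact, if any
        t_surv = np.inf
        if hist.surveillance_due is not None:
            t_surv = hist.surveillance_due
            if (t_surv - birth >= policy.surveillance_stop_age
                    or t_surv >= death_t or t_surv >= max_year):
                hist.surveillance_due = None
                t_surv = np.inf

        t_round = next_round_time()
        t_next = min(t_surv, t_round)
        if t_clin < min(t_next, death_t):
            if t_clin >= max_year:
                break
            lesion = person.lesions[clin_idx]
            # interval cancer: presents after a negative screen and before
            # the person's next invitation
            mode = ("interval"
                    if (hist.last_negative_screen is not None
                        and last_invitation_t <= hist.last_negative_screen)
                    else "clinical")
            finish_diagnosis(t_clin, lesion.clinical_stage, clin_idx, mode,
                             age=lesion.clinical_age)
            break
        if not np.isfinite(t_next):
            break

        if t_surv <= t_round:
            hist.surveillance_due = None
            do_colonoscopy(t_surv, "surveillance_colonoscopy")
            cursor = t_surv + step
            continue

        # invitation round
        t = t_round
        cursor = t + step
        age = t - birth
        emit("invitation", t)
        last_invitation_t = t
        attend = draw_participation(
            person, 0 if hist.attended_before is None else 1,
            policy, rng_stream, attended_before=hist.attended_before, age=age)
        if not attend:
            hist.attended_before = False
            continue
        hist.attended_before = True
        positive = fit_test(person, age, test, rng_stream,
                            removal_ages=out.removal_ages)
        if not positive:
            emit("FIT_negative", t)
            hist.last_negative_screen = t
            continue
        emit("FIT_positive", t)
        if rng_stream.uniform() >= policy.colonoscopy_adherence:
            continue
        do_colonoscopy(t, "diagnostic_colonoscopy")

    out.death_age = min(person.other_cause_death_age, out.crc_death_age)
    return out
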
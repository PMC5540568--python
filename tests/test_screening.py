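"""Screening overlay: eligibility, participation, FIT, colonoscopy,
follow-up classification and the full event loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcscreen import (ConfigurationError, FollowUpCategory,
                       apply_screening, classify_followup, colonoscopy,
                       draw_participation, eligible_for_invitation, fit_test,
                       make_default_colonoscopy, make_default_policy,
                       make_default_params, make_default_test)
from crcscreen.natural_history import (LARGE_ADENOMA, PRECLINICAL_I,
                                       PRECLINICAL_II, PRECLINICAL_III,
                                       SMALL_ADENOMA, Lesion, Person)
from crcscreen.screening import (ColonoscopyCharacteristics,
                                 ParticipationModel, ScreeningHistory,
                                 ScreeningPolicy, SurveillanceThresholds)
from crcscreen.screening import TestCharacteristics as FITCharacteristics


def make_person(birth_year=1955.0, death_age=90.0, lesions=(), sex="male"):
    return Person(id=0, sex=sex, birth_year=birth_year, frailty=1.0,
                  other_cause_death_age=death_age, lesions=list(lesions),
                  u_cure=0.5, u_time=0.5)


def preclinical_lesion(onset=50.0, pre1=55.0, clinical=58.0, stage=1):
    pre = [np.inf] * 4
    for s in range(stage):
        pre[s] = pre1 + s * 0.5
    return Lesion(onset_age=onset, large_age=onset + 2.0,
                  preclinical_ages=tuple(pre), clinical_age=clinical,
                  clinical_stage=stage, progressive=True)


class TestEligibility:
    def test_below_start_age(self, default_policy):
        person = make_person(birth_year=1960.0)
        assert not eligible_for_invitation(person, 2009.5, default_policy,
                                           ScreeningHistory())

    def test_recent_colonoscopy_excludes(self, default_policy):
        person = make_person(birth_year=1950.0)
        hist = ScreeningHistory(last_colonoscopy=2012.5)
        assert not eligible_for_invitation(person, 2015.5, default_policy,
                                           hist)
        hist = ScreeningHistory(last_colonoscopy=2009.5)
        assert eligible_for_invitation(person, 2015.5, default_policy, hist)

    def test_in_range_no_history_is_eligible(self, default_policy):
        person = make_person(birth_year=1955.0)  # age 54.5 in 2009
        assert eligible_for_invitation(person, 2009.5, default_policy,
                                       ScreeningHistory())

    def test_prior_diagnosis_and_surveillance_exclude(self, default_policy):
        person = make_person(birth_year=1955.0)
        assert not eligible_for_invitation(
            person, 2009.5, default_policy, ScreeningHistory(diagnosed=True))
        assert not eligible_for_invitation(
            person, 2009.5, default_policy,
            ScreeningHistory(surveillance_due=2010.5))

    def test_dead_person_not_eligible(self, default_policy):
        person = make_person(birth_year=1955.0, death_age=50.0)
        assert not eligible_for_invitation(person, 2009.5, default_policy,
                                           ScreeningHistory())


class TestParticipation:
    def test_zero_probability_never_attends(self, default_policy):
        from dataclasses import replace
        policy = replace(default_policy, participation={
            "male": ParticipationModel(first_round=0.0, retention=0.0,
                                       conversion=0.0)})
        person = make_person()
        rng = np.random.default_rng(0)
        assert not any(draw_participation(person, 0, policy, rng)
                       for _ in range(100))

    def test_retention_reproduces_regular_participation(self, default_policy):
        """Round-2 re-attendance among round-1 attenders matches the
        configured retention probability."""
        person = make_person()
        rng = np.random.default_rng(1)
        n = 100_000
        again = sum(draw_participation(person, 1, default_policy, rng,
                                       attended_before=True)
                    for _ in range(n))
        p = default_policy.participation_for("male").retention
        se = np.sqrt(p * (1 - p) / n)
        assert abs(again / n - p) < 3 * se

    def test_absorbing_behaviour_keeps_participant_set(self, default_policy):
        from dataclasses import replace
        policy = replace(default_policy, participation={
            "male": ParticipationModel(first_round=0.5, retention=1.0,
                                       conversion=0.0)})
        person = make_person()
        rng = np.random.default_rng(2)
        for _ in range(50):
            assert draw_participation(person, 3, policy, rng,
                                      attended_before=True)
            assert not draw_participation(person, 3, policy, rng,
                                          attended_before=False)


class TestFitTest:
    def test_perfect_specificity_no_lesions_always_negative(self):
        test = FITCharacteristics(sensitivity=np.zeros(6), specificity=1.0)
        person = make_person()
        rng = np.random.default_rng(0)
        assert not any(fit_test(person, 60.0, test, rng) for _ in range(200))

    def test_full_sensitivity_preclinical_always_positive(self):
        sens = np.array([0.0, 0.0, 1.0, 1.0, 1.0, 1.0])
        test = FITCharacteristics(sensitivity=sens, specificity=1.0)
        person = make_person(lesions=[preclinical_lesion(stage=2)])
        rng = np.random.default_rng(0)
        assert all(fit_test(person, 56.5, test, rng) for _ in range(200))

    def test_false_positive_rate_matches_specificity(self):
        test = FITCharacteristics(sensitivity=np.zeros(6), specificity=0.95)
        person = make_person()
        rng = np.random.default_rng(3)
        n = 100_000
        pos = sum(fit_test(person, 60.0, test, rng) for _ in range(n))
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(pos / n - 0.05) < 3 * se

    def test_most_advanced_lesion_drives_result(self):
        sens = np.array([0.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        test = FITCharacteristics(sensitivity=sens, specificity=1.0)
        small = Lesion(onset_age=50.0)
        large = Lesion(onset_age=52.0, large_age=53.0)
        person = make_person(lesions=[small, large])
        rng = np.random.default_rng(0)
        # at 51 only the small lesion exists -> sensitivity 0 -> negative
        assert not fit_test(person, 51.0, test, rng)
        # at 54 the large lesion dominates -> sensitivity 1 -> positive
        assert fit_test(person, 54.0, test, rng)

    def test_nonmonotone_sensitivity_warns(self):
        with pytest.warns(UserWarning):
            FITCharacteristics(
                sensitivity=np.array([0.9, 0.2, 0.5, 0.6, 0.7, 0.8]),
                specificity=0.95)


class TestClassifyFollowup:
    @pytest.mark.parametrize("states, expected", [
        ([], FollowUpCategory.NORMAL_10Y),
        ([SMALL_ADENOMA], FollowUpCategory.LOW_RISK_5Y_TEST),
        ([SMALL_ADENOMA] * 2, FollowUpCategory.LOW_RISK_5Y_TEST),
        ([LARGE_ADENOMA], FollowUpCategory.INTERMEDIATE_3Y_COLONOSCOPY),
        ([SMALL_ADENOMA] * 3, FollowUpCategory.INTERMEDIATE_3Y_COLONOSCOPY),
        ([LARGE_ADENOMA] * 3, FollowUpCategory.HIGH_RISK_1Y_COLONOSCOPY),
        ([SMALL_ADENOMA] * 5, FollowUpCategory.HIGH_RISK_1Y_COLONOSCOPY),
        ([PRECLINICAL_III, SMALL_ADENOMA, LARGE_ADENOMA],
         FollowUpCategory.CANCER_REFERRAL),
    ])
    def test_size_only_risk_mapping(self, states, expected):
        assert classify_followup(states) == expected

    @given(st.lists(st.sampled_from([SMALL_ADENOMA, LARGE_ADENOMA,
                                     PRECLINICAL_I, PRECLINICAL_II]),
                    max_size=8))
    @settings(max_examples=200, derandomize=True)
    def test_precedence_is_total(self, states):
        cat = classify_followup(states)
        if any(s >= PRECLINICAL_I for s in states):
            assert cat == FollowUpCategory.CANCER_REFERRAL
        elif not states:
            assert cat == FollowUpCategory.NORMAL_10Y
        else:
            assert cat in {FollowUpCategory.LOW_RISK_5Y_TEST,
                           FollowUpCategory.INTERMEDIATE_3Y_COLONOSCOPY,
                           FollowUpCategory.HIGH_RISK_1Y_COLONOSCOPY}


class TestColonoscopy:
    def perfect(self):
        return ColonoscopyCharacteristics(sensitivity=np.ones(6),
                                          completeness=1.0)

    def test_no_lesions_normal_category(self):
        person = make_person()
        detected, cat, n_exams = colonoscopy(person, 60.0, self.perfect(),
                                             np.random.default_rng(0))
        assert detected == []
        assert cat == FollowUpCategory.NORMAL_10Y
        assert n_exams == 1

    def test_single_small_adenoma_low_risk(self):
        person = make_person(lesions=[Lesion(onset_age=55.0)])
        detected, cat, _ = colonoscopy(person, 60.0, self.perfect(),
                                       np.random.default_rng(0))
        assert [s for _, s in detected] == [SMALL_ADENOMA]
        assert cat == FollowUpCategory.LOW_RISK_5Y_TEST

    def test_preclinical_iii_is_cancer_referral(self):
        person = make_person(lesions=[preclinical_lesion(stage=3,
                                                         clinical=70.0)])
        detected, cat, _ = colonoscopy(person, 57.0, self.perfect(),
                                       np.random.default_rng(0))
        assert cat == FollowUpCategory.CANCER_REFERRAL
        assert max(s for _, s in detected) == PRECLINICAL_III

    def test_incomplete_examination_repeated_once(self):
        chars = ColonoscopyCharacteristics(sensitivity=np.ones(6),
                                           completeness=0.0)
        person = make_person(lesions=[Lesion(onset_age=55.0)])
        _, _, n_exams = colonoscopy(person, 60.0, chars,
                                    np.random.default_rng(0))
        assert n_exams == 2


class TestApplyScreening:
    def test_null_participation_reproduces_clinical_course(
            self, default_policy, default_params):
        from dataclasses import replace
        policy = replace(default_policy, participation={
            s: ParticipationModel(first_round=0.0, retention=0.0,
                                  conversion=0.0)
            for s in ("male", "female")})
        lesion = preclinical_lesion(onset=50.0, pre1=56.0, clinical=58.0,
                                    stage=1)
        person = make_person(birth_year=1955.0, lesions=[lesion])
        from crcscreen.natural_history import resolve_clinical_course
        resolve_clinical_course(person, default_params["male"],
                                np.random.default_rng(0))
        out = apply_screening(person, policy, default_params["male"],
                              np.random.default_rng(1))
        assert out.diagnosis_age == person.crc_diagnosis_age
        assert out.diagnosis_stage == person.crc_diagnosis_stage
        assert out.diagnosis_mode == "clinical"
        assert out.crc_death_age == person.crc_death_age

    def perfect_policy(self, default_policy):
        from dataclasses import replace
        return replace(
            default_policy,
            test=FITCharacteristics(sensitivity=np.ones(6), specificity=1.0),
            participation={s: ParticipationModel(first_round=1.0,
                                                 retention=1.0,
                                                 conversion=1.0)
                           for s in ("male", "female")},
            colonoscopy_adherence=1.0,
            colonoscopy=ColonoscopyCharacteristics(sensitivity=np.ones(6),
                                                   completeness=1.0))

    def test_perfect_screening_removes_lesion_at_first_round(
            self, default_policy, default_params):
        policy = self.perfect_policy(default_policy)
        lesion = Lesion(onset_age=52.0)  # small adenoma from age 52
        person = make_person(birth_year=1955.0, lesions=[lesion])
        out = apply_screening(person, policy, default_params["male"],
                              np.random.default_rng(0))
        # first round with the lesion present: 2009.5 (age 54.5)
        assert out.removal_ages.get(0) == pytest.approx(54.5)
        assert out.diagnosis_stage == 0

    def test_perfect_screening_detects_preclinical_cancer(
            self, default_policy, default_params):
        policy = self.perfect_policy(default_policy)
        lesion = Lesion(onset_age=40.0, large_age=45.0,
                        preclinical_ages=(54.0, 56.0, np.inf, np.inf),
                        clinical_age=58.0, clinical_stage=2,
                        progressive=True)
        person = make_person(birth_year=1955.0, lesions=[lesion])
        out = apply_screening(person, policy, default_params["male"],
                              np.random.default_rng(0))
        assert out.diagnosis_mode == "screen"
        assert out.diagnosis_age == pytest.approx(54.5)
        assert out.diagnosis_stage == 1   # caught in stage I before stage II
        assert out.diagnosis_age <= lesion.clinical_age
        assert out.crc_death_age >= person.crc_death_age or np.isinf(
            out.crc_death_age)

    def test_interval_cancer_between_negative_screen_and_next_round(
            self, default_policy, default_params):
        """Negative FIT at 60, presentation at 61.1, next round at 62."""
        from dataclasses import replace
        policy = replace(
            default_policy,
            test=FITCharacteristics(sensitivity=np.zeros(6),
                                     specificity=1.0),
            participation={s: ParticipationModel(first_round=1.0,
                                                 retention=1.0,
                                                 conversion=1.0)
                           for s in ("male", "female")})
        lesion = preclinical_lesion(onset=50.0, pre1=59.0, clinical=61.1,
                                    stage=1)
        person = make_person(birth_year=1949.0, lesions=[lesion])
        out = apply_screening(person, policy, default_params["male"],
                              np.random.default_rng(0))
        assert out.diagnosis_mode == "interval"
        assert out.diagnosis_age == pytest.approx(61.1)

    def test_clinical_mode_when_never_screened_negative(
            self, default_policy, default_params):
        from dataclasses import replace
        policy = replace(default_policy, participation={
            s: ParticipationModel(first_round=0.0, retention=0.0,
                                  conversion=0.0)
            for s in ("male", "female")})
        lesion = preclinical_lesion(onset=50.0, pre1=59.0, clinical=61.1,
                                    stage=1)
        person = make_person(birth_year=1949.0, lesions=[lesion])
        out = apply_screening(person, policy, default_params["male"],
                              np.random.default_rng(0))
        assert out.diagnosis_mode == "clinical"

    def test_sex_mismatch_raises(self, default_params):
        policy = ScreeningPolicy(
            test=make_default_test(),
            participation={"female": ParticipationModel()},
            colonoscopy=make_default_colonoscopy())
        person = make_person(sex="male")
        with pytest.raises(ConfigurationError):
            apply_screening(person, policy, default_params["male"],
                            np.random.default_rng(0))

    def test_events_are_time_ordered_and_consistent(
            self, default_policy, default_params, small_population):
        rng = np.random.default_rng(5)
        checked = 0
        for person in small_population[:400]:
            out = apply_screening(person, default_policy,
                                  default_params[person.sex], rng)
            times = [ev.age for ev in out.events]
            assert times == sorted(times)
            kinds = [ev.kind for ev in out.events]
            # a diagnostic colonoscopy is always preceded by a positive FIT
            for i, k in enumerate(kinds):
                if k == "diagnostic_colonoscopy":
                    assert "FIT_positive" in kinds[:i]
            checked += len(out.events)
        assert checked > 0
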
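from hypothesis import given, settings, strategies as st

from smscare.alarm_engine import Alarm, AlarmRule, Recipient, dispatch, evaluate
from smscare.core_model import AlarmRuleConfig, QuestionId
from conftest import make_session
from oracle import streak_alarm_days, weight_alarm_days


DEFAULTS = AlarmRuleConfig()


def _days(alarms, rule):
    return [a.day_index for a in alarms if a.rule is rule]


class TestSymptomStreaks:
    def test_two_consecutive_yes_fires_on_day_two(self):
        alarms = evaluate(make_session(dyspnea="YYN...."), DEFAULTS)
        assert _days(alarms, AlarmRule.DYSPNEA_STREAK) == [2]

    def test_alternating_yes_no_never_fires(self):
        alarms = evaluate(make_session(dyspnea="YNYNYNY"), DEFAULTS)
        assert _days(alarms, AlarmRule.DYSPNEA_STREAK) == []

    def test_week_of_yes_fires_exactly_once(self):
        alarms = evaluate(make_session(dyspnea="YYYYYYY"), DEFAULTS)
        assert _days(alarms, AlarmRule.DYSPNEA_STREAK) == [2]

    def test_rule_rearms_after_a_break(self):
        alarms = evaluate(make_session(dyspnea="YYNYYNN"), DEFAULTS)
        assert _days(alarms, AlarmRule.DYSPNEA_STREAK) == [2, 5]

    def test_missing_and_invalid_answers_break_streaks(self):
        assert _days(evaluate(make_session(dyspnea="Y.YY..."), DEFAULTS),
                     AlarmRule.DYSPNEA_STREAK) == [4]
        assert _days(evaluate(make_session(dyspnea="YIYIYIY"), DEFAULTS),
                     AlarmRule.DYSPNEA_STREAK) == []

    def test_medication_streak_watches_negative_answers(self):
        alarms = evaluate(make_session(medication="YNNYYYY"), DEFAULTS)
        assert _days(alarms, AlarmRule.MEDICATION_STREAK) == [3]

    def test_fatigue_streak_watches_affirmative_answers(self):
        alarms = evaluate(make_session(fatigue="NNNYYNN"), DEFAULTS)
        assert _days(alarms, AlarmRule.FATIGUE_STREAK) == [5]


class TestNonResponse:
    def test_two_silent_days_fire_once(self):
        session = make_session(n=7)  # nothing answered at all
        alarms = evaluate(session, DEFAULTS)
        assert _days(alarms, AlarmRule.NON_RESPONSE) == [2]

    def test_any_answer_defeats_the_silent_day(self):
        # partial responders are not non-responders
        session = make_session(n=4, fatigue=".N.N")
        alarms = evaluate(session, DEFAULTS)
        assert _days(alarms, AlarmRule.NON_RESPONSE) == []

    def test_invalid_reply_counts_as_responding(self):
        session = make_session(n=4, dyspnea="II..")
        alarms = evaluate(session, DEFAULTS)
        assert _days(alarms, AlarmRule.NON_RESPONSE) == [4]


class TestWeightRule:
    def test_monotone_rise_meets_threshold(self):
        alarms = evaluate(make_session(weights=[70, 71, 72.5]), DEFAULTS)
        assert _days(alarms, AlarmRule.WEIGHT_GAIN) == [3]

    def test_dip_then_surge_is_caught_by_min_in_window(self):
        # last - min = 71.5 - 69 = 2.5 even though last - first is only 1.5
        alarms = evaluate(make_session(weights=[70, 69, 71.5]), DEFAULTS)
        assert _days(alarms, AlarmRule.WEIGHT_GAIN) == [3]

    def test_endpoint_only_variant_ignores_the_dip(self):
        cfg = AlarmRuleConfig(weight_endpoint_only=True)
        alarms = evaluate(make_session(weights=[70, 69, 71.5]), cfg)
        assert _days(alarms, AlarmRule.WEIGHT_GAIN) == []

    def test_missing_or_invalid_weight_breaks_the_window(self):
        assert _days(evaluate(make_session(weights=[70, None, 72.5]), DEFAULTS),
                     AlarmRule.WEIGHT_GAIN) == []
        assert _days(evaluate(make_session(weights=[70, "I", 72.5]), DEFAULTS),
                     AlarmRule.WEIGHT_GAIN) == []

    def test_debounce_one_alarm_per_qualifying_run(self):
        # every 3-day window of this ramp gains 3 kg; one alarm at the first
        alarms = evaluate(make_session(weights=[70, 71.5, 73, 74.5, 76, 77.5, 79]), DEFAULTS)
        assert _days(alarms, AlarmRule.WEIGHT_GAIN) == [3]

    def test_loss_rule_disabled_by_default_and_symmetric_when_enabled(self):
        falling = [75, 73.5, 72, 70.5]
        assert _days(evaluate(make_session(weights=falling), DEFAULTS),
                     AlarmRule.WEIGHT_LOSS) == []
        cfg = AlarmRuleConfig(weight_loss_kg=2.0)
        assert _days(evaluate(make_session(weights=falling), cfg),
                     AlarmRule.WEIGHT_LOSS) == [3]


class TestThresholdSanity:
    def test_threshold_one_fires_on_every_fresh_yes_day(self):
        cfg = AlarmRuleConfig(symptom_streak_days=1)
        alarms = evaluate(make_session(dyspnea="YNYYNNY"), cfg)
        assert _days(alarms, AlarmRule.DYSPNEA_STREAK) == [1, 3, 7]

    def test_threshold_beyond_window_never_fires(self):
        cfg = AlarmRuleConfig(symptom_streak_days=8)
        alarms = evaluate(make_session(dyspnea="YYYYYYY"), cfg)
        assert _days(alarms, AlarmRule.DYSPNEA_STREAK) == []


class TestDispatch:
    def test_empty(self):
        assert dispatch([]) == []

    def test_every_alarm_notifies_patient_and_manager(self):
        alarms = [Alarm("P01", AlarmRule.DYSPNEA_STREAK, 2)] * 7
        notifications = dispatch(alarms)
        assert len(notifications) == 7
        for n in notifications:
            assert n.recipients == {Recipient.PATIENT, Recipient.MANAGER}
        assert [n.alarm for n in notifications] == alarms


# ---------------------------------------------------------------------------
# Oracle equivalence on random grids
# ---------------------------------------------------------------------------

def _marks(days):
    return st.text(alphabet="YN.I", min_size=days, max_size=days)


def _weights(days):
    element = st.one_of(
        st.none(),
        st.just("I"),
        st.floats(min_value=40, max_value=120).map(lambda v: round(v, 1)),
    )
    return st.lists(element, min_size=days, max_size=days)


@st.composite
def _random_case(draw):
    days = draw(st.integers(min_value=1, max_value=14))
    return (
        days,
        draw(_marks(days)),
        draw(_marks(days)),
        draw(_marks(days)),
        draw(_weights(days)),
        draw(st.integers(min_value=1, max_value=4)),  # streak threshold
        draw(st.integers(min_value=2, max_value=4)),  # weight window
    )


class TestOracleEquivalence:
    @settings(max_examples=200, deadline=None)
    @given(_random_case())
    def test_engine_matches_brute_force_run_enumeration(self, case):
        days, dysp, fat, med, weights, streak, window = case
        session = make_session(
            n=days, dyspnea=dysp, fatigue=fat, medication=med, weights=weights
        )
        cfg = AlarmRuleConfig(
            symptom_streak_days=streak,
            nonresponse_streak_days=streak,
            weight_window_days=window,
        )
        alarms = evaluate(session, cfg)

        def flags(marks, symbol):
            return [c == symbol for c in marks]

        numeric = [w if isinstance(w, float) else None for w in weights]
        no_response = [
            len(session.record_for_day(d).answers) == 0 for d in range(1, days + 1)
        ]
        expected = {
            AlarmRule.DYSPNEA_STREAK: streak_alarm_days(flags(dysp, "Y"), streak),
            AlarmRule.FATIGUE_STREAK: streak_alarm_days(flags(fat, "Y"), streak),
            AlarmRule.MEDICATION_STREAK: streak_alarm_days(flags(med, "N"), streak),
            AlarmRule.NON_RESPONSE: streak_alarm_days(no_response, streak),
            AlarmRule.WEIGHT_GAIN: weight_alarm_days(numeric, window, cfg.weight_gain_kg),
        }
        for rule, days_expected in expected.items():
            assert _days(alarms, rule) == days_expected, rule

    @settings(max_examples=100, deadline=None)
    @given(_random_case(), st.data())
    def test_adding_an_answer_never_adds_non_response_alarms(self, case, data):
        days, dysp, fat, med, weights, streak, _ = case
        cfg = AlarmRuleConfig(nonresponse_streak_days=streak)
        session = make_session(n=days, dyspnea=dysp, fatigue=fat, medication=med)
        before = len(_days(evaluate(session, cfg), AlarmRule.NON_RESPONSE))
        day = data.draw(st.integers(min_value=1, max_value=days))
        from smscare.core_model import AnswerValue, ParsedAnswer

        session.record_for_day(day).answers.setdefault(
            QuestionId.FATIGUE, ParsedAnswer(AnswerValue.NO, "NO")
        )
        after = len(_days(evaluate(session, cfg), AlarmRule.NON_RESPONSE))
        assert after <= before

    def test_evaluate_is_pure(self):
        session = make_session(dyspnea="YYNNYY.", weights=[70, 71, 72.5, None, 70, 71, 73])
        first = evaluate(session, DEFAULTS)
        second = evaluate(session, DEFAULTS)
        assert first == second
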
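"""Triage rule engine: per-analyte grading, panel classification,
pattern rules, grace period and the class/interval bijection."""

from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amiomon.rules import (
    ANALYTES,
    Classification,
    Grade,
    LabPanel,
    RuleConfig,
    TechnicalError,
    classify_panel,
    default_profile,
    grade_analyte,
    render_recommendation,
    ukat_from_ul,
)

# Independent restatement of the default band edges, used by the
# brute-force grading oracle below.
DEFAULT_BANDS = {
    # analyte: (ref_low, ref_high, red_low, red_high)
    "tsh": (0.4, 4.0, 0.1, 10.0),
    "ft4": (12.0, 22.0, 9.0, 30.0),
    "ft3": (3.1, 6.8, 2.3, 10.0),
    "ast": (0.0, 0.76, None, 2.28),
    "alt": (0.0, 1.1, None, 3.3),
}


def oracle_grade(analyte: str, value: float) -> str:
    lo, hi, red_lo, red_hi = DEFAULT_BANDS[analyte]
    if lo <= value <= hi:
        return "normal"
    if value > hi:
        return "minor" if value <= red_hi else "definite"
    if red_lo is not None and value < red_lo:
        return "definite"
    return "minor"


def band_points(analyte: str) -> list[float]:
    """Representative values in every band of an analyte (plus boundaries)."""
    lo, hi, red_lo, red_hi = DEFAULT_BANDS[analyte]
    pts = [(lo + hi) / 2, hi, hi * 1.0001 if hi else 0.0, (hi + red_hi) / 2, red_hi, red_hi * 1.5]
    if red_lo is not None:
        pts += [lo, (red_lo + lo) / 2, red_lo, red_lo / 2]
    return pts


class TestGrading:
    @pytest.mark.parametrize(
        "analyte,value,expected",
        [
            ("tsh", 2.2, Grade.NORMAL),  # interior point of the reference range
            ("tsh", 4.0, Grade.NORMAL),  # boundary is inclusive
            ("tsh", 0.4, Grade.NORMAL),
            ("tsh", 7.0, Grade.MINOR),
            ("tsh", 10.0, Grade.MINOR),
            ("tsh", 10.5, Grade.DEFINITE),
            ("tsh", 0.05, Grade.DEFINITE),
            ("alt", 4 * 1.1, Grade.DEFINITE),  # 4x upper limit is past the 3x red edge
            ("alt", 2 * 1.1, Grade.MINOR),
            ("ast", 0.5, Grade.NORMAL),
        ],
    )
    def test_grade_examples(self, config, analyte, value, expected):
        assert grade_analyte(analyte, value, config).grade is expected

    def test_missing_value(self, config):
        assert grade_analyte("tsh", None, config).grade is Grade.MISSING

    def test_unknown_analyte_rejected(self, config):
        with pytest.raises(KeyError):
            grade_analyte("ggt", 1.0, config)

    def test_invalid_value_rejected(self, config):
        with pytest.raises(ValueError):
            grade_analyte("tsh", -1.0, config)
        with pytest.raises(ValueError):
            grade_analyte("tsh", float("nan"), config)

    @pytest.mark.parametrize("analyte", ANALYTES)
    def test_grading_matches_band_oracle(self, config, analyte):
        for v in band_points(analyte):
            assert grade_analyte(analyte, v, config).grade.value == oracle_grade(analyte, v)

    def test_unit_conversion(self):
        assert ukat_from_ul(60.0) == pytest.approx(1.0)


class TestClassifyPanel:
    def test_all_normal_is_class1(self, config, make_panel):
        c = classify_panel(make_panel(), config)
        assert isinstance(c, Classification)
        assert (c.class_id, c.color, c.interval_months) == (1, "green", 6)
        assert c.referral == "none" and not c.order_antibodies

    def test_missing_analyte_is_technical_error(self, config, make_panel):
        out = classify_panel(make_panel(tsh=None), config)
        assert isinstance(out, TechnicalError)
        assert out.missing_analytes == ("tsh",)

    def test_missing_ft3_configurable(self, make_panel):
        lenient = default_profile().model_copy(update={"strict_missing_ft3": False})
        out = classify_panel(make_panel(ft3=None), lenient)
        assert isinstance(out, Classification)
        strict = default_profile()
        assert isinstance(classify_panel(make_panel(ft3=None), strict), TechnicalError)

    def test_aih_pattern(self, config, make_panel):
        c = classify_panel(make_panel(tsh=25.0, ft4=10.0), config)
        assert c.class_id == 3
        assert c.suspected_condition == "AIH"
        assert c.referral == "primary_care"
        assert c.order_antibodies

    def test_ait_pattern(self, config, make_panel):
        c = classify_panel(make_panel(tsh=0.05, ft4=26.0), config)
        assert c.class_id == 3
        assert c.suspected_condition == "AIT"
        assert c.referral == "endocrinologist"

    def test_hepatotoxicity_pattern(self, config, make_panel):
        c = classify_panel(make_panel(ast=3.1, alt=4.5), config)
        assert c.class_id == 3
        assert c.suspected_condition == "hepatotoxicity"
        assert c.referral == "gastroenterology_advice"
        assert not c.order_antibodies

    def test_mixed_condition(self, config, make_panel):
        c = classify_panel(make_panel(tsh=0.05, ft4=26.0, alt=4.5), config)
        assert c.class_id == 3
        assert c.suspected_condition == "mixed"
        assert c.referral == "physician_immediate"

    def test_minor_deviation_is_class2(self, config, make_panel):
        c = classify_panel(make_panel(alt=1.8), config)
        assert (c.class_id, c.interval_months) == (2, 1)

    def test_definite_without_pattern(self, config, make_panel):
        # isolated suppressed TSH with normal free hormones: red, no condition
        c = classify_panel(make_panel(tsh=0.05), config)
        assert c.class_id == 3
        assert c.suspected_condition == "none"
        assert c.referral == "physician_immediate"

    def test_grace_tolerates_isolated_minor_thyroid(self, config, make_panel):
        panel = make_panel(tsh=5.0)
        assert classify_panel(panel, config, months_on_treatment=1).class_id == 1
        assert classify_panel(panel, config, months_on_treatment=4).class_id == 2
        # unknown treatment duration: grace does not apply
        assert classify_panel(panel, config, months_on_treatment=None).class_id == 2
        # a concurrent liver deviation is not an expected amiodarone effect
        assert classify_panel(make_panel(tsh=5.0, alt=1.8), config, months_on_treatment=1).class_id == 2
        # grace never blunts definite pathology
        assert classify_panel(make_panel(tsh=12.0), config, months_on_treatment=1).class_id == 3

    def test_antibody_trigger_red_only(self, make_panel):
        cfg = default_profile().model_copy(update={"antibody_trigger": "red_only"})
        assert not classify_panel(make_panel(tsh=5.0), cfg).order_antibodies
        assert classify_panel(make_panel(tsh=12.0), cfg).order_antibodies

    def test_antibodies_not_ordered_for_liver_only(self, config, make_panel):
        assert not classify_panel(make_panel(alt=1.8), config).order_antibodies

    def test_trab_tpo_do_not_change_class(self, config, make_panel):
        c1 = classify_panel(make_panel(), config)
        c2 = classify_panel(make_panel(trab=5.0, tpo=100.0), config)
        assert c1.class_id == c2.class_id == 1


values = st.one_of(
    st.none(),
    st.floats(min_value=0.0, max_value=50.0, allow_nan=False, allow_infinity=False),
)


class TestInvariants:
    @given(
        tsh=values, ft4=values, ft3=values, ast=values, alt=values,
        months=st.one_of(st.none(), st.integers(min_value=0, max_value=36)),
    )
    @settings(max_examples=300, deadline=None)
    def test_totality_and_bijection(self, config, tsh, ft4, ft3, ast, alt, months):
        """Every complete panel gets exactly one class; incomplete panels
        get the technical-error outcome; class/color/interval stay bijective."""
        panel = LabPanel(
            patient_id="H", sample_date=date(2022, 1, 1),
            tsh=tsh, ft4=ft4, ft3=ft3, ast=ast, alt=alt,
        )
        out = classify_panel(panel, config, months_on_treatment=months)
        complete = all(v is not None for v in (tsh, ft4, ft3, ast, alt))
        if complete:
            assert isinstance(out, Classification)
            assert out.class_id in (1, 2, 3)
            assert {1: 6, 2: 1, 3: 0}[out.class_id] == out.interval_months
            assert {1: "green", 2: "yellow", 3: "red"}[out.class_id] == out.color
        else:
            assert isinstance(out, TechnicalError)

    @given(
        tsh=values, ft4=values, ft3=values, ast=values, alt=values,
        months=st.one_of(st.none(), st.integers(min_value=0, max_value=36)),
    )
    @settings(max_examples=200, deadline=None)
    def test_determinism(self, config, tsh, ft4, ft3, ast, alt, months):
        panel = LabPanel(
            patient_id="H", sample_date=date(2022, 1, 1),
            tsh=tsh, ft4=ft4, ft3=ft3, ast=ast, alt=alt,
        )
        a = classify_panel(panel, config, months_on_treatment=months)
        b = classify_panel(panel, config, months_on_treatment=months)
        assert a == b

    def test_aggregation_is_maximum_severity(self, config, make_panel):
        """Brute-force oracle: the class equals the maximum per-analyte
        severity over a grid covering every band of every analyte."""
        severity_to_class = {"normal": 1, "minor": 2, "definite": 3}
        rank = {"normal": 0, "minor": 1, "definite": 2}
        # vary two analytes jointly over their full band grids, rest normal
        import itertools

        for a1, a2 in itertools.combinations(ANALYTES, 2):
            for v1 in band_points(a1):
                for v2 in band_points(a2):
                    panel = make_panel(**{a1: v1, a2: v2})
                    grades = [oracle_grade(a1, v1), oracle_grade(a2, v2)]
                    expected = severity_to_class[max(grades, key=lambda g: rank[g])]
                    got = classify_panel(panel, config)
                    assert got.class_id == expected, (a1, v1, a2, v2)

    @given(
        analyte=st.sampled_from(list(ANALYTES)),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotonicity_single_analyte(self, config, analyte, data):
        """Moving one analyte into a strictly more severe band never
        decreases the class."""

        def make_panel(**overrides):
            base = dict(patient_id="H", sample_date=date(2022, 1, 1),
                        tsh=2.2, ft4=17.0, ft3=4.95, ast=0.38, alt=0.55)
            base.update(overrides)
            return LabPanel(**base)

        lo, hi, red_lo, red_hi = DEFAULT_BANDS[analyte]
        bands = {
            "normal": (lo, hi),
            "minor": (hi * 1.001 if hi else 1e-6, red_hi),
            "definite": (red_hi * 1.001, red_hi * 3),
        }
        order = ["normal", "minor", "definite"]
        i = data.draw(st.integers(min_value=0, max_value=1))
        v_mild = data.draw(st.floats(*bands[order[i]], allow_nan=False))
        v_severe = data.draw(st.floats(*bands[order[i + 1]], allow_nan=False))
        mild = classify_panel(make_panel(**{analyte: v_mild}), config)
        severe = classify_panel(make_panel(**{analyte: v_severe}), config)
        assert severe.class_id >= mild.class_id


class TestRecommendation:
    def test_deterministic_and_names_interval(self, config, make_panel):
        c = classify_panel(make_panel(), config)
        text = render_recommendation(c)
        assert text == render_recommendation(c)  # byte-identical
        assert "6 months" in text and "referral" in text.lower()

    def test_class2_names_one_month(self, config, make_panel):
        text = classify_panel(make_panel(alt=1.8), config).recommendation
        assert "1 month" in text

    def test_class3_ait_names_endocrinology(self, config, make_panel):
        text = classify_panel(make_panel(tsh=0.05, ft4=26.0), config).recommendation
        assert "endocrinologist" in text


class TestRuleConfig:
    def test_yaml_round_trip_lossless(self, config):
        assert RuleConfig.from_yaml(config.to_yaml()) == config

    def test_invalid_reference_range_rejected(self):
        from amiomon.rules import AnalyteRule

        with pytest.raises(ValueError):
            AnalyteRule(reference_low=5.0, reference_high=4.0, red_low=1.0, red_high=10.0)

    def test_missing_analyte_table_rejected(self, config):
        table = dict(config.analytes)
        del table["alt"]
        with pytest.raises(ValueError):
            RuleConfig(analytes=table)
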
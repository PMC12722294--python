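"""Score-engine unit and property tests (LS, CONUT, PNI, NRI, panel)."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lscohort.scores import (
    ParticipantRecord,
    alcohol_subscore_band,
    conut_group,
    conut_score,
    lifestyle_score,
    lorenz_ideal_weight,
    ls_category,
    ls_excluding_smoking,
    nri_group,
    nri_score,
    pni_group,
    pni_score,
    score_cohort,
    score_panel,
)

from oracles import conut_reference, nri_reference, pni_reference


def make_record(**overrides):
    base = dict(
        id="p1", sex="male", age=55.0, height=176.0, weight=82.0,
        albumin=45.8, total_cholesterol=5.6, hdl=1.6, ldl=3.5,
        triglycerides=1.4, lymphocytes=1.88, systolic_bp=128.0,
        diastolic_bp=80.0, diabetes=False, smoker=False,
        diet_subscore=8.0, pa_subscore=7.0, smoking_subscore=5.0,
        alcohol_g_per_day=12.0, alcohol_subscore=6.0,
        survival_months=110.0, event=False,
    )
    base.update(overrides)
    return ParticipantRecord(**base)


class TestLifestyleScore:
    @pytest.mark.parametrize("subs,expected", [
        ((0, 0, 0, 0), 0),
        ((5, 6, 4, 6), 21),       # first-tercile boundary
        ((20, 16, 15, 15), 66),   # schema maximum
    ])
    def test_sum(self, subs, expected):
        assert lifestyle_score(*subs) == expected

    def test_missing_subscore_gives_nan(self):
        assert math.isnan(lifestyle_score(5, None, 4, 6))

    def test_negative_subscore_rejected(self):
        with pytest.raises(ValueError):
            lifestyle_score(-1, 0, 0, 0)

    @pytest.mark.parametrize("ls,expected", [
        (21, "T1"), (22, "T2"), (32, "T2"), (33, "T3"), (3, "T1"), (66, "T3"),
    ])
    def test_fixed_terciles(self, ls, expected):
        assert ls_category(ls) == expected

    def test_smoking_excluded_variant_is_ls_minus_smoking(self):
        assert ls_excluding_smoking(5, 6, 6) == 17
        assert ls_excluding_smoking(0, 0, 0) == 0
        full = lifestyle_score(5, 6, 4, 6)
        assert full - ls_excluding_smoking(5, 6, 6) == 4


class TestAlcoholBand:
    @pytest.mark.parametrize("intake,sex,expected", [
        (10.0, "female", "not_penalized"),
        (10.1, "female", "penalized"),
        (20.0, "male", "not_penalized"),
        (20.1, "male", "penalized"),
        (0.0, "male", "not_penalized"),
    ])
    def test_thresholds(self, intake, sex, expected):
        assert alcohol_subscore_band(intake, sex) == expected

    def test_negative_intake_rejected(self):
        with pytest.raises(ValueError):
            alcohol_subscore_band(-1.0, "male")


class TestConut:
    @pytest.mark.parametrize("labs,expected", [
        ((45, 5.0, 1.8), 0),    # healthiest band everywhere
        ((24, 2.0, 0.5), 12),   # worst band everywhere
        ((45, 3.8, 1.8), 1),    # only cholesterol scores
    ])
    def test_examples(self, labs, expected):
        assert conut_score(*labs) == expected

    @pytest.mark.parametrize("value,expected", [
        (0, "low"), (1, "moderate"), (2, "moderate"), (3, "high"),
        (12, "high"),
    ])
    def test_grouping(self, value, expected):
        assert conut_group(value) == expected

    def test_group_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            conut_group(13)

    def test_missing_lab_gives_nan(self):
        assert math.isnan(conut_score(45, None, 1.8))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(alb=st.floats(0, 60), chol=st.floats(0, 10), ly=st.floats(0, 5))
    def test_integer_range_and_oracle(self, alb, chol, ly):
        score = conut_score(alb, chol, ly)
        assert score == int(score)
        assert 0 <= score <= 12
        assert score == conut_reference(alb, chol, ly)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(alb=st.floats(10, 60), chol=st.floats(0.5, 10), ly=st.floats(0.1, 5),
           drop=st.floats(0.1, 20))
    def test_worse_labs_never_lower_score(self, alb, chol, ly, drop):
        base = conut_score(alb, chol, ly)
        assert conut_score(max(alb - drop, 0), chol, ly) >= base
        assert conut_score(alb, max(chol - drop, 0), ly) >= base
        assert conut_score(alb, chol, max(ly - drop, 0)) >= base


class TestPniNri:
    def test_pni_examples(self):
        assert pni_score(45.8, 1.88) == pytest.approx(55.2)
        assert pni_score(0, 0) == 0
        assert pni_score(56.35, 0) == pytest.approx(56.35)

    @pytest.mark.parametrize("value,expected", [
        (57, "T1"), (56.35, "T2"), (55, "T2"), (53.25, "T2"), (50, "T3"),
    ])
    def test_pni_groups(self, value, expected):
        assert pni_group(value) == expected

    def test_lorenz_examples(self):
        assert lorenz_ideal_weight(150, "male") == pytest.approx(50.0)
        assert lorenz_ideal_weight(170, "male") == pytest.approx(65.0)
        assert lorenz_ideal_weight(170, "female") == pytest.approx(62.0)

    def test_lorenz_warns_below_valid_regime(self):
        with pytest.warns(UserWarning, match="extrapolated"):
            lorenz_ideal_weight(145, "female")

    def test_nri_examples(self):
        assert nri_score(40, 65, 65) == pytest.approx(101.26)
        assert nri_score(0, 0, 65) == 0
        assert nri_score(45.8, 80.6, 65) == pytest.approx(119.9, abs=0.05)

    @pytest.mark.parametrize("value,expected", [
        (123, "T1"), (122.8, "T2"), (119, "T2"), (115.2, "T2"), (100, "T3"),
    ])
    def test_nri_groups(self, value, expected):
        assert nri_group(value) == expected

    def test_nri_requires_positive_ideal_weight(self):
        with pytest.raises(ValueError):
            nri_score(40, 65, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(alb=st.floats(20, 60), ly=st.floats(0, 5), up=st.floats(0.5, 10))
    def test_pni_strictly_increasing(self, alb, ly, up):
        assert pni_score(alb + up, ly) > pni_score(alb, ly)
        assert pni_score(alb, ly + up) > pni_score(alb, ly)

    def test_reference_formula_agreement(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            alb = rng.uniform(20, 60)
            ly = rng.uniform(0, 5)
            w = rng.uniform(45, 130)
            h = rng.uniform(152, 200)
            sex = rng.choice(["male", "female"])
            assert pni_score(alb, ly) == pytest.approx(
                pni_reference(alb, ly), abs=1e-9)
            assert nri_score(alb, w, lorenz_ideal_weight(h, sex)) == \
                pytest.approx(nri_reference(alb, w, h, sex), abs=1e-9)


class TestPanel:
    def test_full_record_fully_populated(self):
        panel = score_panel(make_record())
        assert panel.ls == 26
        assert panel.ls_tercile == "T2"
        assert panel.conut == 0
        assert panel.conut_group == "low"
        assert panel.pni is not None and panel.nri is not None
        assert panel.framingham_risk is not None
        assert panel.framingham_category is not None

    def test_missing_lymphocytes_nulls_conut_and_pni_only(self):
        panel = score_panel(make_record(lymphocytes=float("nan")))
        assert panel.conut is None and panel.pni is None
        assert panel.nri is not None and panel.ls is not None

    def test_batch_scoring_preserves_order(self):
        rows = [make_record(id=f"p{i}", diet_subscore=float(i)).to_series()
                for i in range(5)]
        scored = score_cohort(pd.DataFrame(rows))
        assert list(scored["id"]) == [f"p{i}" for i in range(5)]
        assert list(scored["ls"]) == [18 + i for i in range(5)]

    def test_record_validation(self):
        with pytest.raises(ValueError):
            make_record(sex="other")
        with pytest.raises(ValueError):
            make_record(height=-1.0)
        with pytest.raises(ValueError):
            make_record(albumin=-0.1)

    def test_albumin_unit_gate_warns_on_g_per_dl(self):
        frame = pd.DataFrame([make_record(albumin=4.6).to_series()])
        with pytest.warns(UserWarning, match="g/L"):
            score_cohort(frame)
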
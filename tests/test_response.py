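"""Response-function families, presets and admissibility checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trapwalk.response import (
    DEFAULT_R_FLOOR,
    RParams,
    SParams,
    ResponseProfile,
    eval_r,
    eval_s,
    get_preset,
    r3_admissibility,
    r3_minimum,
    r_presets,
    s_presets,
)


class TestEvalR:
    @pytest.mark.parametrize(
        "spec, d, expected",
        [
            (RParams("r1", 0.5, 0.5 / 25), 0.0, 0.5),  # published row, b = a/R^2
            (RParams("r1", 0.5, 0.02), 10.0, 0.5 * np.exp(0.2)),
            (RParams("r2", 0.9, 0.8), 0.0, DEFAULT_R_FLOOR),  # 0 clamped to floor
            (RParams("r2", 1.0, 1.0), 4.0, 0.8),
            (RParams("r3", 15.0, 30.0, J=0.01), 22.5, 0.4375),
            (RParams("r4", 0.8, 0.1, J=0.01, q=1.0), 0.0, (0.01 + 1.0) / 2.0),
            (2.5, 17.0, 2.5),  # constant spec
        ],
    )
    def test_values(self, spec, d, expected):
        assert eval_r(spec, d) == pytest.approx(expected, rel=1e-12)

    def test_r3_grid_minimum_matches_closed_form(self):
        """Brute-force grid minimisation agrees with the closed-form minimum
        for 100 random admissible parameter triples."""
        rng = np.random.default_rng(7)
        grid = np.arange(0.0, 60.0, 1e-3)
        for _ in range(100):
            a, b = rng.uniform(1.0, 40.0, size=2)
            if a == b:
                continue
            J = rng.uniform(0.05, 1.0) * (2.0 / abs(a - b)) ** 2
            params = RParams("r3", a, b, J=float(J))
            stat, ok = r3_admissibility(params)
            assert ok
            d_star, min_value = r3_minimum(params)
            vals = eval_r(params, grid)
            i = int(np.argmin(vals))
            assert grid[i] == pytest.approx(d_star, abs=1e-3)
            # closed-form minimum may sit below the clamp floor only when
            # the statistic is at the boundary; here it is admissible
            assert vals[i] == pytest.approx(max(min_value, DEFAULT_R_FLOOR), abs=1e-5)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            eval_r(RParams("r1", 0.5, 0.02), -1.0)

    def test_flagged_preset_clamps_not_raises(self):
        params = get_preset("r3/row3-flagged")
        d_star, min_value = r3_minimum(params)
        assert min_value < 0
        assert eval_r(params, d_star) == DEFAULT_R_FLOOR

    @given(
        a=st.floats(0.01, 50.0),
        b=st.floats(0.01, 50.0),
        J=st.floats(1e-4, 1.0),
        d=st.floats(0.0, 100.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_clamped_floor_property(self, a, b, J, d):
        """r is a standard deviation: every evaluation is finite and >= floor."""
        val = eval_r(RParams("r3", a, b, J=J), d)
        assert np.isfinite(val)
        assert val >= DEFAULT_R_FLOOR


class TestEvalS:
    @pytest.mark.parametrize(
        "spec, d, expected",
        [
            (SParams("s4", 10.0, 5.0, d_max=22.5), 22.5, 10.0),  # peak speed
            (SParams("s2", 20.0, 0.3), 5.0, 4.3),
            (SParams("s1", 6.0, 0.01), 1e12, pytest.approx(0.01, abs=1e-5)),
            (SParams("s3", 100.0, 0.3), 10.0, 1.3),
            (1.5, 3.0, 1.5),
        ],
    )
    def test_values(self, spec, d, expected):
        assert eval_s(spec, d) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("family", ["s1", "s2", "s3"])
    def test_divergent_families_reject_d_zero(self, family):
        with pytest.raises(ValueError, match="diverges"):
            eval_s(SParams(family, 1.0, 0.1), 0.0)

    def test_s4_defined_at_zero(self):
        assert eval_s(SParams("s4", 10.0, 5.0, d_max=22.5), 0.0) > 0

    def test_decay_rate_ordering(self):
        """Scaled to agree at a reference distance d0, the inverse-square
        family decays fastest: smallest value at 2*d0."""
        d0, v, h = 10.0, 2.0, 0.01
        s1 = SParams("s1", (v - h) * np.sqrt(d0), h)
        s2 = SParams("s2", (v - h) * d0, h)
        s3 = SParams("s3", (v - h) * d0**2, h)
        vals = [eval_s(s, 2 * d0) for s in (s1, s2, s3)]
        assert vals[0] > vals[1] > vals[2]


class TestShapes:
    """Shape properties of the four r families."""

    def test_r1_r2_increasing(self):
        d = np.linspace(0.0, 100.0, 2001)
        r1 = eval_r(get_preset("r1/row1"), d)
        r2 = eval_r(get_preset("r2/row1"), d)
        assert np.all(np.diff(r1) > 0)
        assert np.all(np.diff(r2) > 0)

    def test_r2_bounded_by_a_over_b(self):
        p = get_preset("r2/row1")
        d = np.linspace(0.0, 1e6, 101)
        assert np.all(eval_r(p, d) < p.a / p.b)

    def test_r4_asymptote_is_q(self):
        for name in ["r4/row1", "r4/row2", "r4/row2-dazzle", "r4/row3-dazzle"]:
            p = get_preset(name)
            d = 1e5
            assert eval_r(p, d) == pytest.approx(p.q, rel=1e-6)

    def test_all_presets_finite_positive_on_dense_grid(self):
        d = np.linspace(0.0, 100.0, 5001)
        for name, p in r_presets().items():
            vals = eval_r(p, d)
            assert np.all(np.isfinite(vals)) and np.all(vals >= DEFAULT_R_FLOOR), name
        d_pos = d[d > 0]
        for name, p in s_presets().items():
            vals = eval_s(p, d_pos)
            assert np.all(np.isfinite(vals)) and np.all(vals > 0), name


class TestAdmissibility:
    @pytest.mark.parametrize(
        "a, b, J, stat, ok",
        [
            (15.0, 30.0, 0.01, 1.5, True),
            (20.0, 40.0, 0.01, 2.0, True),  # boundary case
            (5.0, 50.0, 0.01, 4.5, False),  # flagged published row
            (7.0, 7.0, 0.3, 0.0, True),  # identical roots
        ],
    )
    def test_statistic(self, a, b, J, stat, ok):
        got_stat, got_ok = r3_admissibility(RParams("r3", a, b, J=J))
        assert got_stat == pytest.approx(stat, abs=1e-12)
        assert got_ok is ok

    @pytest.mark.parametrize(
        "a, b, J, d_star, min_value",
        [
            (15.0, 30.0, 0.01, 22.5, 0.4375),
            (5.0, 20.0, 0.01, 12.5, 0.4375),
            (9.0, 9.0, 0.5, 9.0, 1.0),
        ],
    )
    def test_minimum_closed_form(self, a, b, J, d_star, min_value):
        got_d, got_min = r3_minimum(RParams("r3", a, b, J=J))
        assert got_d == pytest.approx(d_star)
        assert got_min == pytest.approx(min_value)

    def test_wrong_family_rejected(self):
        with pytest.raises(ValueError):
            r3_admissibility(RParams("r1", 1.0, 1.0))


class TestPresets:
    def test_published_rows(self):
        s3 = get_preset("s3")
        assert (s3.c, s3.h) == (100.0, 0.3)
        r1 = get_preset("r1/row1", R=5.0)
        assert (r1.a, r1.b) == (0.5, 0.02)
        s4 = get_preset("s4")
        assert (s4.c, s4.h, s4.d_max) == (10.0, 5.0, 22.5)

    def test_b_formulas_resolved_against_R(self):
        assert get_preset("r1/row1", R=10.0).b == pytest.approx(0.005)
        assert get_preset("r1/row2", R=5.0).b == pytest.approx(1.0 / 15.0)
        assert get_preset("r4/row2", R=5.0).b == pytest.approx(0.06)
        assert get_preset("r4/row4").b == pytest.approx(0.25)

    def test_unknown_name_lists_available(self):
        with pytest.raises(KeyError, match="r1/row1"):
            get_preset("nonexistent")

    def test_registry_sizes(self):
        assert len(r_presets()) == 21
        assert len(s_presets()) == 4


class TestParamValidation:
    @pytest.mark.parametrize(
        "ctor",
        [
            lambda: RParams("r9", 1.0, 1.0),
            lambda: RParams("r1", -1.0, 1.0),
            lambda: RParams("r3", 1.0, 2.0),  # missing J
            lambda: RParams("r1", 1.0, 1.0, J=0.1),  # extraneous J
            lambda: RParams("r4", 1.0, 1.0, J=0.1),  # missing q
            lambda: SParams("s5", 1.0, 1.0),
            lambda: SParams("s4", 1.0, 1.0),  # missing d_max
            lambda: SParams("s1", 1.0, 1.0, d_max=5.0),  # extraneous d_max
            lambda: SParams("s1", 0.0, 1.0),
        ],
    )
    def test_rejected(self, ctor):
        with pytest.raises(ValueError):
            ctor()

    def test_constant_specs_must_be_positive(self):
        with pytest.raises(ValueError):
            eval_r(0.0, 1.0)
        with pytest.raises(ValueError):
            eval_s(-1.0, 1.0)

    def test_profile_describe_roundtrip_keys(self):
        prof = ResponseProfile(get_preset("r4/row1"), 1.0)
        desc = prof.describe()
        assert desc["r"]["family"] == "r4"
        assert desc["s"] == {"constant": 1.0}
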
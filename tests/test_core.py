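import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methclock.core import (
    BetaMatrix,
    ClockDefinition,
    SpeciesCharacteristics,
    TRANSFORM_NAMES,
    TransformError,
    TransformSpec,
    ValidationError,
    inverse_transform_age,
    linear_predictor,
    predict_age,
    transform_age,
)

from conftest import make_betas, make_sheet


SPECIES = SpeciesCharacteristics("sp", max_lifespan=20.0, gestation=0.5, sexual_maturity=2.0)


def age_grid(name, species, n=1000):
    """A grid of valid ages covering each transform's domain."""
    g, L = species.gestation, species.max_lifespan
    if name in ("relative_age", "loglog_relative_age", "relative_adult_age"):
        lo = -g + 1e-6 * (L + g)
        hi = L - 1e-6 * (L + g) if name != "relative_age" else 3 * L
        return np.linspace(lo, hi, n)
    if name == "log_linear":
        return np.linspace(-0.9, 5 * L, n)  # domain a > -k with default k=1
    return np.linspace(-5.0, 5 * L, n)


class TestTransformExamples:
    def test_identity(self):
        assert transform_age(5.0, TransformSpec("identity")) == 5.0
        assert inverse_transform_age(5.0, TransformSpec("identity")) == 5.0

    def test_log_linear_anchor(self):
        spec = TransformSpec("log_linear", {"m": 1.0, "k": 1.0})
        assert transform_age(1.0, spec) == 0.0
        assert inverse_transform_age(0.0, spec) == 1.0

    def test_log_linear_adult_branch(self):
        # (3 - 1) / (1 + 1) = 1.0
        spec = TransformSpec("log_linear", {"m": 1.0, "k": 1.0})
        assert transform_age(3.0, spec) == pytest.approx(1.0)

    def test_relative_age(self):
        spec = TransformSpec("relative_age", {"g": 0.0, "L": 10.0})
        assert transform_age(5.0, spec) == pytest.approx(0.5)

    def test_loglog_round_trip(self):
        spec = TransformSpec("loglog_relative_age", {"g": 0.0, "L": 10.0})
        assert inverse_transform_age(transform_age(5.0, spec), spec) == pytest.approx(5.0)

    def test_unknown_transform_rejected(self):
        with pytest.raises(TransformError, match="unknown transform"):
            TransformSpec("no_such_transform")

    def test_age_at_lifespan_rejected(self):
        spec = TransformSpec("loglog_relative_age", {"g": 0.0, "L": 10.0})
        with pytest.raises(TransformError):
            transform_age(10.0, spec)

    def test_clamp_epsilon_accepts_boundary(self):
        spec = TransformSpec("loglog_relative_age", {"g": 0.0, "L": 10.0}, clamp_epsilon=True)
        assert math.isfinite(transform_age(10.0, spec))

    def test_missing_species_parameter(self):
        with pytest.raises(TransformError, match="needs parameter"):
            transform_age(5.0, TransformSpec("relative_age"), None)

    def test_species_defaults_used(self):
        spec = TransformSpec("relative_age")
        expected = (5.0 + SPECIES.gestation) / (SPECIES.max_lifespan + SPECIES.gestation)
        assert transform_age(5.0, spec, SPECIES) == pytest.approx(expected)

    def test_params_override_species(self):
        spec = TransformSpec("relative_age", {"L": 40.0, "g": 0.0})
        assert transform_age(20.0, spec, SPECIES) == pytest.approx(0.5)

    def test_relative_age_inverse_outside_image(self):
        spec = TransformSpec("relative_age", {"g": 0.0, "L": 10.0})
        with pytest.raises(TransformError):
            inverse_transform_age(-0.1, spec)


class TestTransformProperties:
    @pytest.mark.parametrize("name", TRANSFORM_NAMES)
    def test_round_trip_1000_grid(self, name):
        spec = TransformSpec(name)
        ages = age_grid(name, SPECIES)
        for a in ages:
            x = transform_age(a, spec, SPECIES)
            back = inverse_transform_age(x, spec, SPECIES)
            assert abs(back - a) < 1e-8, (name, a)

    @pytest.mark.parametrize("name", TRANSFORM_NAMES)
    def test_strictly_increasing(self, name):
        spec = TransformSpec(name)
        ages = age_grid(name, SPECIES)
        values = np.array([transform_age(a, spec, SPECIES) for a in ages])
        assert np.all(np.diff(values) > 0), name

    def test_log_linear_c1_at_maturity(self):
        # Continuity and first-derivative continuity at a = m.
        spec = TransformSpec("log_linear", {"m": 2.0, "k": 1.0})
        m, h = 2.0, 1e-7
        below = transform_age(m - h, spec)
        above = transform_age(m + h, spec)
        assert abs(above - below) < 1e-6
        d_below = (transform_age(m, spec) - transform_age(m - h, spec)) / h
        d_above = (transform_age(m + h, spec) - transform_age(m, spec)) / h
        assert d_below == pytest.approx(d_above, rel=1e-5)

    @settings(max_examples=100, deadline=None)
    @given(
        age=st.floats(0.0, 50.0),
        L=st.floats(5.0, 100.0),
        g=st.floats(0.0, 2.0),
        m=st.floats(0.5, 4.0),
    )
    def test_round_trip_hypothesis(self, age, L, g, m):
        sp = SpeciesCharacteristics("x", max_lifespan=L, gestation=g, sexual_maturity=m)
        rel = (age + g) / (L + g)
        for name in TRANSFORM_NAMES:
            if name in ("relative_age", "loglog_relative_age", "relative_adult_age") and rel < 1e-6:
                continue
            if name in ("loglog_relative_age", "relative_adult_age") and age >= L:
                continue
            spec = TransformSpec(name)
            x = transform_age(age, spec, sp)
            assert inverse_transform_age(x, spec, sp) == pytest.approx(age, abs=1e-8)


class TestBetaMatrix:
    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError, match="outside"):
            make_betas([[0.5, 1.2]])

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValidationError, match="duplicate probe"):
            BetaMatrix(np.zeros((2, 1)), ["a", "a"], ["s"])
        with pytest.raises(ValidationError, match="duplicate sample"):
            BetaMatrix(np.zeros((1, 2)), ["a"], ["s", "s"])

    def test_missing_allowed(self):
        bm = make_betas([[0.5, np.nan]])
        assert np.isnan(bm.values[0, 1])


class TestLinearPredictor:
    CLOCK = ClockDefinition("c", intercept=0.5, coefficients={"cg1": 1.0, "cg2": -1.0})

    def test_hand_computed(self):
        value, n_missing = linear_predictor({"cg1": 0.8, "cg2": 0.2}, self.CLOCK)
        assert value == pytest.approx(1.1)
        assert n_missing == 0

    def test_empty_clock_returns_intercept(self):
        clock = ClockDefinition("c", intercept=3.25, coefficients={})
        value, _ = linear_predictor({"cgX": 0.9}, clock)
        assert value == 3.25

    def test_drop_warn_all_missing(self):
        clock = ClockDefinition("c", intercept=0.0, coefficients={"cg1": 2.0})
        value, n_missing = linear_predictor({"cg2": 0.9}, clock, missing_policy="drop_warn")
        assert value == 0.0
        assert n_missing == 1

    def test_strict_raises_on_missing(self):
        with pytest.raises(ValidationError, match="missing under strict"):
            linear_predictor({"cg1": 0.8}, self.CLOCK)

    def test_nan_counts_as_missing(self):
        value, n_missing = linear_predictor(
            {"cg1": 0.8, "cg2": float("nan")}, self.CLOCK, missing_policy="drop_warn"
        )
        assert value == pytest.approx(1.3)
        assert n_missing == 1


class TestPredictAge:
    def test_intercept_only_identity(self):
        betas = make_betas(np.full((2, 4), 0.5))
        clock = ClockDefinition("c", intercept=3.0, coefficients={})
        out = predict_age(betas, clock)
        assert list(out.index) == betas.sample_ids
        assert np.allclose(out["dnam_age"], 3.0)

    def test_order_invariance(self, small_cohort):
        betas = small_cohort.betas
        clock = ClockDefinition(
            "c", intercept=0.1,
            coefficients={betas.probe_ids[3]: 0.7, betas.probe_ids[10]: -0.2},
        )
        base = predict_age(betas, clock)
        rng = np.random.default_rng(0)
        p_order = rng.permutation(betas.n_probes)
        s_order = rng.permutation(betas.n_samples)
        shuffled = BetaMatrix(
            betas.values[np.ix_(p_order, s_order)],
            [betas.probe_ids[i] for i in p_order],
            [betas.sample_ids[j] for j in s_order],
        )
        out = predict_age(shuffled, clock)
        aligned = out.loc[base.index]
        assert np.allclose(aligned["dnam_age"], base["dnam_age"], atol=1e-12)

    def test_drop_warn_equals_strict_when_complete(self, small_cohort):
        betas = small_cohort.betas
        clock = ClockDefinition("c", intercept=0.2, coefficients={betas.probe_ids[0]: 0.4})
        strict = predict_age(betas, clock, missing_policy="strict")
        dropw = predict_age(betas, clock, missing_policy="drop_warn")
        assert (strict["dnam_age"] == dropw["dnam_age"]).all()

    def test_species_transform_needs_sheet(self):
        betas = make_betas(np.full((1, 2), 0.5))
        clock = ClockDefinition(
            "c", intercept=0.5, coefficients={}, transform=TransformSpec("relative_age")
        )
        with pytest.raises(ValidationError, match="species"):
            predict_age(betas, clock)

    def test_species_transform_full_path(self):
        betas = make_betas(np.full((1, 2), 0.5), samples=["s0", "s1"])
        sheet = make_sheet(["s0", "s1"], [2.0, 4.0], species="sp")
        from methclock.core import SpeciesTable

        table = SpeciesTable([SPECIES])
        clock = ClockDefinition(
            "c", intercept=0.5, coefficients={}, transform=TransformSpec("relative_age")
        )
        out = predict_age(betas, clock, sheet, table)
        expected = 0.5 * (SPECIES.max_lifespan + SPECIES.gestation) - SPECIES.gestation
        assert np.allclose(out["dnam_age"], expected)

    def test_clock_round_trip_invariant(self):
        # transform round-trips inside ClockDefinition contract
        clock = ClockDefinition(
            "c", intercept=0.0, coefficients={"cg1": 1.0},
            transform=TransformSpec("log_linear", {"m": 2.0}),
        )
        for a in [0.5, 2.0, 7.5]:
            x = transform_age(a, clock.transform)
            assert inverse_transform_age(x, clock.transform) == pytest.approx(a, abs=1e-8)

    def test_zero_coefficients_not_stored(self):
        clock = ClockDefinition("c", intercept=1.0, coefficients={"cg1": 0.0, "cg2": 0.5})
        assert clock.probe_ids == ["cg2"]
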
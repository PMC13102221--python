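import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gmolesta import (
    OccurrenceParams,
    alpha4_completion,
    density,
    evaluate,
    load_params,
    peak_cdd,
    peak_shares,
    save_params,
)
from gmolesta.errors import ConstraintViolationError, InvalidInputError
from gmolesta.occurrence import load_bundled_params


def _term_oracle(x, p):
    """Independent term-by-term evaluation of the four-component curve."""
    mus = np.cumsum([p.beta1, *p.dbeta])
    total = p.alpha[0] / (1.0 + (x / p.beta1) ** p.gamma[0]) if x > 0 else 0.0
    for k in (1, 2, 3):
        z = (
            p.gamma[k] * (x - mus[k])
            if p.parameterization == "rate"
            else (x - mus[k]) / p.gamma[k]
        )
        total += p.alpha[k] / (1.0 + np.exp(-min(max(z, -700), 700)))
    return total


@st.composite
def valid_params(draw):
    raw = [draw(st.floats(0.05, 1.0)) for _ in range(4)]
    alpha = tuple(np.array(raw) / np.sum(raw))
    mode = draw(st.sampled_from(["rate", "scale"]))
    gamma_rest = (
        [draw(st.floats(0.01, 0.2)) for _ in range(3)]
        if mode == "rate"
        else [draw(st.floats(5.0, 100.0)) for _ in range(3)]
    )
    return OccurrenceParams(
        alpha=alpha,
        beta1=draw(st.floats(50.0, 400.0)),
        dbeta=tuple(draw(st.floats(100.0, 800.0)) for _ in range(3)),
        gamma=(draw(st.floats(-20.0, -2.0)), *gamma_rest),
        parameterization=mode,
    )


class TestEvaluate:
    def test_zero_thermal_time_gives_zero(self, table1):
        assert evaluate(0.0, table1) == pytest.approx(0.0, abs=1e-12)

    def test_saturates_at_one(self, table1):
        assert evaluate(5000.0, table1) == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("mode", ["rate", "scale"])
    def test_half_of_first_peak_at_beta1(self, table1, mode):
        p = table1.with_parameterization(mode)
        val = evaluate(172.23, p)
        assert val == pytest.approx(_term_oracle(172.23, p), abs=1e-12)
        assert val == pytest.approx(0.1376, abs=1e-3)  # alpha1/2 + tiny leakage

    @pytest.mark.parametrize("x", [100.0, 600.0, 1200.0, 1800.0, 2500.0])
    def test_matches_per_term_oracle(self, table1, x):
        assert evaluate(x, table1) == pytest.approx(_term_oracle(x, table1), abs=1e-12)

    def test_negative_x_raises(self, table1):
        with pytest.raises(InvalidInputError):
            evaluate(-1.0, table1)

    @settings(derandomize=True, max_examples=50)
    @given(p=valid_params())
    def test_nondecreasing_and_bounded(self, p):
        x = np.linspace(0.0, 4000.0, 300)
        f = evaluate(x, p)
        assert np.all(np.diff(f) >= -1e-12)
        # at the origin the first component takes its analytic limit (0);
        # the remainder is exactly the later logistics' leakage across 0
        leak = _term_oracle(0.0, p) - 0.0
        assert f[0] == pytest.approx(leak, abs=1e-12)
        assert np.all(f <= 1.0 + 1e-12)

    def test_component_mass_localizes_for_separated_peaks(self):
        p = OccurrenceParams(
            alpha=(0.25, 0.25, 0.25, 0.25),
            beta1=200.0,
            dbeta=(500.0, 500.0, 500.0),
            gamma=(-12.0, 0.08, 0.08, 0.08),
        )
        for k in (2, 3, 4):
            mu = peak_cdd(p, k)
            gain = evaluate(mu + 200.0, p) - evaluate(mu - 200.0, p)
            assert gain == pytest.approx(p.alpha[k - 1], abs=0.01)


class TestPeakCdd:
    def test_published_peak_positions(self, table1):
        assert peak_cdd(table1, 1) == pytest.approx(172.23)
        assert peak_cdd(table1, 2) == pytest.approx(636.31)
        assert peak_cdd(table1, 4) == pytest.approx(1816.02)

    def test_strictly_increasing_in_peak_index(self, table1):
        vals = [peak_cdd(table1, k) for k in (1, 2, 3, 4)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_out_of_range_index_raises(self, table1):
        with pytest.raises(InvalidInputError):
            peak_cdd(table1, 5)


class TestAlpha4Completion:
    @pytest.mark.parametrize(
        "a,expected",
        [
            ((0.2751, 0.3501, 0.1724), 0.2024),
            ((1.0, 0.0, 0.0), 0.0),
            ((0.25, 0.25, 0.25), 0.25),
        ],
    )
    def test_completion(self, a, expected):
        assert alpha4_completion(*a) == pytest.approx(expected, abs=1e-12)

    def test_oversum_raises(self):
        with pytest.raises(ConstraintViolationError):
            alpha4_completion(0.6, 0.3, 0.2)


class TestPeakShares:
    def test_published_shares(self, table1):
        assert peak_shares(table1) == (28, 35, 17, 20)

    def test_uniform_and_degenerate_shares(self):
        uniform = OccurrenceParams(
            alpha=(0.25, 0.25, 0.25, 0.25), beta1=100.0, dbeta=(100.0, 100.0, 100.0),
            gamma=(-8.0, 0.06, 0.06, 0.06),
        )
        assert peak_shares(uniform) == (25, 25, 25, 25)
        lone = OccurrenceParams(
            alpha=(1.0, 0.0, 0.0, 0.0), beta1=100.0, dbeta=(100.0, 100.0, 100.0),
            gamma=(-8.0, 0.06, 0.06, 0.06),
        )
        assert peak_shares(lone) == (100, 0, 0, 0)


class TestDensity:
    @pytest.mark.parametrize("x", [100.0, 600.0, 1200.0, 1800.0])
    def test_matches_central_difference(self, table1, x):
        h = 1e-3
        fd = (evaluate(x + h, table1) - evaluate(x - h, table1)) / (2 * h)
        assert density(x, table1) == pytest.approx(fd, abs=1e-6)

    def test_nonnegative_on_dense_grid(self, table1):
        x = np.linspace(1e-6, 3000.0, 10_000)
        assert np.all(density(x, table1) >= 0)

    def test_integrates_to_total_mass(self, table1):
        x = np.linspace(1e-9, 5000.0, 200_001)
        integral = np.trapezoid(density(x, table1), x)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_nonpositive_x_raises(self, table1):
        with pytest.raises(InvalidInputError):
            density(0.0, table1)


class TestParamsValidation:
    def test_alpha_sum_enforced(self):
        with pytest.raises(ConstraintViolationError):
            OccurrenceParams(alpha=(0.3, 0.3, 0.3, 0.3), beta1=100.0,
                             dbeta=(1.0, 1.0, 1.0), gamma=(-8.0, 0.06, 0.06, 0.06))

    def test_gamma_sign_constraints(self):
        with pytest.raises(ConstraintViolationError):
            OccurrenceParams(alpha=(0.25,) * 4, beta1=100.0, dbeta=(1.0, 1.0, 1.0),
                             gamma=(8.0, 0.06, 0.06, 0.06))


class TestParameterFiles:
    def test_round_trip(self, table1, tmp_path):
        path = tmp_path / "params.yaml"
        save_params(table1, path)
        back = load_params(path)
        assert back == table1

    def test_bundled_file_carries_published_estimates(self, table1):
        assert load_bundled_params() == table1
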
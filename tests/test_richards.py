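import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sodpcr import (
    AmplificationRun,
    FitConfig,
    NoAmplificationError,
    NotConvergedError,
    RichardsFit,
    fit_richards,
    richards_model,
    shape_fingerprint,
)
from conftest import numeric_fingerprint


def _make_run(params, cycles=40, run_id="R"):
    x = np.arange(1, cycles + 1)
    return AmplificationRun(run_id, x, richards_model(x, *params))


class TestModel:
    def test_logistic_midpoint(self):
        # d = 1, Fb = 0: the curve passes through Fmax/2 at x = c
        assert richards_model(20.0, 40.0, 0.0, 2.0, 20.0, 1.0) == pytest.approx(20.0)

    def test_direct_evaluation(self):
        # 2 + 40 * (1 + 1)^(-2)
        assert richards_model(20.0, 40.0, 2.0, 2.0, 20.0, 2.0) == pytest.approx(12.0)

    @pytest.mark.parametrize("d", [0.3, 1.0, 4.0])
    def test_monotone_approach_to_plateau(self, d):
        x = np.linspace(-200, 400, 4000)
        y = richards_model(x, 40.0, 2.0, 2.0, 20.0, d)
        assert np.all(np.diff(y) >= 0)
        assert y[0] == pytest.approx(2.0, abs=1e-6)
        assert y[-1] == pytest.approx(42.0, abs=1e-6)

    def test_no_overflow_far_from_transition(self):
        y = richards_model(np.array([-1e6, 1e6]), 40.0, 2.0, 0.5, 20.0, 3.0)
        assert np.all(np.isfinite(y))


class TestFingerprint:
    def test_symmetric_logistic_values(self):
        fit = RichardsFit(Fmax=40, Fb=0, b=2, c=20, d=1, converged=True,
                          rss=0, n_points=40)
        fp = shape_fingerprint(fit)
        assert fp.Yf == pytest.approx(20.0)
        assert fp.m == pytest.approx(5.0)  # Fmax / (4 b)
        assert fp.Asym == pytest.approx(0.0, abs=1e-9)
        assert fp.x_f == pytest.approx(20.0)

    def test_asymmetric_closed_forms(self):
        fit = RichardsFit(Fmax=40, Fb=0, b=2, c=20, d=2, converged=True,
                          rss=0, n_points=40)
        fp = shape_fingerprint(fit)
        assert fp.Yf == pytest.approx(40 * 1.5**-2, rel=1e-9)    # 17.7778
        assert fp.m == pytest.approx(20 * 1.5**-3, rel=1e-9)     # 5.9259
        assert fp.Asym == pytest.approx(1 / 9, rel=1e-6)         # 0.1111

    def test_gompertz_limit_asymmetry(self):
        fit = RichardsFit(Fmax=40, Fb=0, b=2, c=20, d=1e6, converged=True,
                          rss=0, n_points=40)
        assert shape_fingerprint(fit).Asym == pytest.approx(1 - 2 / np.e, rel=1e-5)

    def test_non_converged_fit_rejected(self):
        fit = RichardsFit(Fmax=40, Fb=0, b=2, c=20, d=1, converged=False,
                          rss=0, n_points=40)
        with pytest.raises(NotConvergedError):
            shape_fingerprint(fit)

    def test_closed_forms_match_numerical_differentiation(self, rng):
        # independent brute-force oracle over random parameter sets
        for _ in range(100):
            fmax = rng.uniform(10, 100)
            fb = rng.uniform(-2, 2)
            b = rng.uniform(0.5, 5)
            c = rng.uniform(10, 30)
            d = rng.uniform(0.2, 5)
            fit = RichardsFit(Fmax=fmax, Fb=fb, b=b, c=c, d=d, converged=True,
                              rss=0, n_points=40)
            fp = shape_fingerprint(fit)
            x_f, yf, m = numeric_fingerprint(fmax, fb, b, c, d)
            assert fp.x_f == pytest.approx(x_f, rel=1e-5)
            assert fp.Yf == pytest.approx(yf, rel=1e-5)
            assert fp.m == pytest.approx(m, rel=1e-5)
            assert fp.Asym == pytest.approx((fmax - 2 * yf) / fmax, abs=1e-5)


class TestFit:
    @pytest.mark.parametrize(
        "params, rel",
        [((40.0, 2.0, 2.0, 20.0, 1.0), 1e-4), ((40.0, 2.0, 2.0, 20.0, 2.0), 1e-3)],
    )
    def test_noiseless_parameter_recovery(self, params, rel):
        fit = fit_richards(_make_run(params))
        assert fit.converged
        est = (fit.Fmax, fit.Fb, fit.b, fit.c, fit.d)
        np.testing.assert_allclose(est, params, rtol=rel)

    def test_refit_idempotence(self):
        fit1 = fit_richards(_make_run((46.0, 0.5, 1.8, 22.0, 1.3)))
        run2 = _make_run((fit1.Fmax, fit1.Fb, fit1.b, fit1.c, fit1.d))
        fit2 = fit_richards(run2)
        np.testing.assert_allclose(
            [fit2.Fmax, fit2.Fb, fit2.b, fit2.c, fit2.d],
            [fit1.Fmax, fit1.Fb, fit1.b, fit1.c, fit1.d],
            rtol=1e-6,
        )

    def test_flat_trace_raises_no_amplification(self):
        run = AmplificationRun("flat", np.arange(1, 41), np.full(40, 1.0))
        with pytest.raises(NoAmplificationError):
            fit_richards(run)

    def test_low_plateau_vs_reference_raises(self):
        run = _make_run((2.0, 0.0, 2.0, 20.0, 1.0))  # plateau 2 vs reference 46
        with pytest.raises(NoAmplificationError):
            fit_richards(run, FitConfig(reference_plateau=46.0))

    def test_too_few_points_rejected(self):
        run = AmplificationRun("short", np.arange(1, 6), np.linspace(0, 10, 5))
        with pytest.raises(ValueError, match=">= 8"):
            fit_richards(run)

    @settings(derandomize=True, deadline=None, max_examples=20)
    @given(
        delta=st.integers(min_value=-5, max_value=15),
        k=st.floats(min_value=0.2, max_value=8.0),
    )
    def test_shift_scale_equivariance(self, delta, k):
        """Cycle shifts move only c; fluorescence scaling scales only heights."""
        params = (46.0, 0.5, 1.8, 20.0, 1.3)
        base = fit_richards(_make_run(params))
        fp0 = shape_fingerprint(base)

        x = np.arange(1, 41)
        shifted = AmplificationRun("s", x + delta, richards_model(x, *params))
        fs = fit_richards(shifted)
        assert fs.c == pytest.approx(base.c + delta, rel=1e-5)
        fps = shape_fingerprint(fs)
        assert fps.Fmax == pytest.approx(fp0.Fmax, rel=1e-5)
        assert fps.Yf == pytest.approx(fp0.Yf, rel=1e-5)
        assert fps.m == pytest.approx(fp0.m, rel=1e-5)

        scaled = AmplificationRun("k", x, richards_model(x, *params) * k)
        fk = fit_richards(scaled)
        fpk = shape_fingerprint(fk)
        assert fk.d == pytest.approx(base.d, rel=1e-4)
        assert fpk.Fmax == pytest.approx(k * fp0.Fmax, rel=1e-4)
        assert fpk.Yf == pytest.approx(k * fp0.Yf, rel=1e-4)
        assert fpk.m == pytest.approx(k * fp0.m, rel=1e-4)
        assert fpk.Asym == pytest.approx(fp0.Asym, abs=1e-6)
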
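import numpy as np
import pytest

from sodpcr import SimulationConfig, richards_model, simulate_plate


def numeric_fingerprint(Fmax, Fb, b, c, d):
    """Brute-force shape fingerprint by numerical differentiation.

    Locates the maximum of the first derivative of the Richards curve on a
    grid refined down to 1e-4 cycles (with a final parabolic interpolation),
    then reads the curve height above background and the tangent slope
    there. Entirely independent of the closed-form expressions.
    """

    def f(x):
        return richards_model(x, Fmax, Fb, b, c, d)

    def deriv(x, h=1e-4):
        return (f(x + h) - f(x - h)) / (2 * h)

    lo, hi = c - 10 * b, c + 10 * b
    for step in (b / 50, b / 2000, 1e-4):
        xs = np.arange(lo, hi, step)
        ds = deriv(xs)
        i = int(np.argmax(ds))
        lo, hi = xs[max(i - 1, 0)], xs[min(i + 1, xs.size - 1)]
    # parabolic vertex through the top three derivative samples
    x3 = xs[i - 1 : i + 2]
    d3 = ds[i - 1 : i + 2]
    denom = d3[0] - 2 * d3[1] + d3[2]
    x_f = x3[1] if denom == 0 else x3[1] + 0.5 * step * (d3[0] - d3[2]) / denom
    return x_f, float(f(x_f) - Fb), float(deriv(x_f))


@pytest.fixture(scope="session")
def default_plate():
    """The default standard-curve design: 6 concentrations x 12 replicates."""
    return simulate_plate(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
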
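import numpy as np
import pytest

from elasmodemo import GrowthParams, VonBertalanffyGrowth
from elasmodemo.simulate import GrowthSimConfig, generate_length_at_age

TRUE_GROWTH = GrowthParams(k=0.12, dw_inf=3000.0, dw0=900.0, sigma2=0.01)


@pytest.fixture(scope="session")
def abundant_records():
    """300 synthetic length-at-age records at known truth, full age range."""
    cfg = GrowthSimConfig(
        params=TRUE_GROWTH, n=300, age_range=(0, 15), size_window=None, seed=7
    )
    return generate_length_at_age(cfg)


@pytest.fixture(scope="session")
def truncated_records():
    """Synthetic records restricted to young ages and the 1100-2400 mm window,
    mimicking a catch sample that never sees large adults."""
    cfg = GrowthSimConfig(
        params=TRUE_GROWTH, n=120, age_range=(0, 8),
        size_window=(1100.0, 2400.0), seed=11,
    )
    return generate_length_at_age(cfg)


@pytest.fixture(scope="session")
def recovery_fit(abundant_records):
    """Uninformative-prior posterior on the abundant synthetic data (shared
    across the recovery and integration tests; ~seconds to sample)."""
    with np.errstate(all="ignore"):
        return VonBertalanffyGrowth(
            priors="uninformative", random_state=3
        ).fit(abundant_records)


@pytest.fixture(scope="session")
def truncated_fits(truncated_records):
    """(uninformative, strong) posterior pair on the truncated data."""
    uninf = VonBertalanffyGrowth(
        priors="uninformative", random_state=5
    ).fit(truncated_records)
    strong = VonBertalanffyGrowth(priors="strong", random_state=5).fit(
        truncated_records
    )
    return uninf, strong


def ols_slope(x, y):
    """Independent closed-form OLS slope: sum((x-xbar)(y-ybar))/sum((x-xbar)^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    return float(np.sum(xc * (y - y.mean())) / np.sum(xc**2))


def bisect_rmax(b, alpha_mat, M, lo=-1.0, hi=5.0, tol=1e-12):
    """Independent bisection oracle for the Euler-Lotka root."""
    import math

    def g(r):
        return (
            math.exp(r * alpha_mat)
            - math.exp(-M) * math.exp(r * (alpha_mat - 1.0))
            - math.exp(-M * alpha_mat) * b
        )

    flo = g(lo)
    assert flo < 0 < g(hi), "oracle bracket must straddle the root"
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if g(mid) * flo <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
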
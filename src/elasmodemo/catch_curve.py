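"""Catch-curve estimation of total mortality Z with bootstrap uncertainty.

A catch curve treats the age composition of an opportunistic, non-selective
catch as a snapshot of the population age structure.  Over the ages that are
fully vulnerable to the fishery, log numbers-at-age decline linearly with
slope -Z, the instantaneous total mortality (year^-1).  Ascending age classes
below the modal ("peak") class reflect lower catchability of the young and
are dropped before the regression; zero-count classes are dropped because the
log of zero is undefined.  Uncertainty is quantified by a deletion bootstrap:
each replicate deletes a fixed fraction of the aged individuals without
replacement, rebuilds the composition, and refits the slope.  Fishing
mortality follows as F = Z - M.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .growth import _as_arrays

__all__ = [
    "AgeComposition",
    "MortalityDraws",
    "CatchCurve",
    "build_age_composition",
    "catch_curve_slope",
    "bootstrap_Z",
    "fishing_mortality",
]

MIN_REGRESSION_CLASSES = 3


@dataclass(frozen=True)
class AgeComposition:
    """Counts of individuals per integer age class.

    Counts may be real-valued (e.g. model-predicted abundances); zero-count
    classes are retained here and only dropped at regression time.
    """

    counts: dict[int, float]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("age composition is empty")
        for age, n in self.counts.items():
            if age < 0 or n < 0:
                raise ValueError(f"invalid composition entry {age}: {n}")
        if not any(n > 0 for n in self.counts.values()):
            raise ValueError("age composition has no positive counts")

    @property
    def ages(self) -> np.ndarray:
        return np.array(sorted(self.counts), dtype=int)

    @property
    def zero_classes(self) -> list[int]:
        """Age classes present in the structure but with zero individuals."""
        return [a for a in sorted(self.counts) if self.counts[a] == 0]

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    def peak_age(self) -> int:
        """Modal age class; ties resolve to the earliest age."""
        best = max(self.counts.values())
        return min(a for a, n in self.counts.items() if n == best)


@dataclass
class MortalityDraws:
    """Bootstrap/Monte Carlo draws of a mortality rate with summaries."""

    draws: np.ndarray
    median: float
    ci_low: float
    ci_high: float
    interval: tuple[float, float]
    n_discarded: int = 0
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_draws(
        cls, draws: np.ndarray, interval: tuple[float, float], n_discarded: int = 0
    ) -> "MortalityDraws":
        draws = np.asarray(draws, dtype=float)
        if draws.size == 0:
            raise ValueError(
                f"no draws retained ({n_discarded} replicates discarded)"
            )
        lo, hi = np.quantile(draws, interval)
        return cls(
            draws=draws,
            median=float(np.median(draws)),
            ci_low=float(lo),
            ci_high=float(hi),
            interval=interval,
            n_discarded=n_discarded,
        )


def build_age_composition(data, exclude_ages=()) -> AgeComposition:
    """Tabulate counts per age class from 0 to the maximum observed age.

    Intermediate ages with no individuals get an explicit zero count;
    ``exclude_ages`` are removed from the structure entirely (the treatment
    given to age classes judged unrepresentative of the population).
    """
    ages, _ = _as_arrays(data) if not _is_age_vector(data) else (
        np.asarray(data, dtype=float),
        None,
    )
    ages = ages.astype(int)
    if ages.size == 0:
        raise ValueError("no records")
    exclude = set(int(a) for a in exclude_ages)
    counts = {a: 0.0 for a in range(int(ages.max()) + 1) if a not in exclude}
    for a in ages:
        if a in counts:
            counts[a] += 1
    if not any(n > 0 for n in counts.values()):
        raise ValueError("all records excluded from the age composition")
    return AgeComposition(counts=counts)


def _is_age_vector(data) -> bool:
    arr = np.asarray(data)
    return arr.ndim == 1 and arr.dtype.kind in "iuf"


def catch_curve_slope(comp: AgeComposition) -> float:
    """Total mortality Z as minus the OLS slope of ln(count) on age.

    Age classes younger than the peak (modal) class are removed — the peak
    itself is retained — then zero-count classes are dropped.  At least
    three classes must remain.
    """
    peak = comp.peak_age()
    ages = [a for a in sorted(comp.counts) if a >= peak and comp.counts[a] > 0]
    if len(ages) < MIN_REGRESSION_CLASSES:
        raise ValueError(
            f"only {len(ages)} usable age classes after peak truncation "
            f"(peak={peak}); need >= {MIN_REGRESSION_CLASSES}"
        )
    x = np.array(ages, dtype=float)
    y = np.log([comp.counts[a] for a in ages])
    res = stats.linregress(x, y)
    return float(-res.slope)


def bootstrap_Z(
    data,
    n_boot: int = 20000,
    drop_fraction: float = 0.2,
    max_age_cutoff: int | None = None,
    exclude_ages=(),
    seed: int | None = None,
    interval: tuple[float, float] = (0.025, 0.975),
) -> MortalityDraws:
    """Deletion-bootstrap distribution of the catch-curve Z.

    Each replicate removes ``floor(drop_fraction * n)`` aged individuals
    without replacement, optionally drops ages >= ``max_age_cutoff``,
    rebuilds the composition (still excluding ``exclude_ages``), applies
    peak truncation and zero-class removal, and refits the log-linear slope.
    Replicates with fewer than three usable classes are discarded and
    counted in ``n_discarded``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not (0 <= drop_fraction < 1):
        raise ValueError("drop_fraction must be in [0, 1)")
    ages = (
        np.asarray(data, dtype=float)
        if _is_age_vector(data)
        else _as_arrays(data)[0]
    ).astype(int)
    n = ages.size
    n_drop = int(np.floor(drop_fraction * n))
    rng = np.random.default_rng(seed)

    draws = []
    n_discarded = 0
    for _ in range(n_boot):
        keep = ages
        if n_drop:
            keep = np.delete(ages, rng.choice(n, size=n_drop, replace=False))
        if max_age_cutoff is not None:
            keep = keep[keep < max_age_cutoff]
        try:
            comp = build_age_composition(keep, exclude_ages=exclude_ages)
            draws.append(catch_curve_slope(comp))
        except ValueError:
            n_discarded += 1
    return MortalityDraws.from_draws(
        np.array(draws), interval=interval, n_discarded=n_discarded
    )


def fishing_mortality(
    z_draws,
    m_draws,
    seed: int | None = None,
    n_pairs: int | None = None,
    interval: tuple[float, float] = (0.05, 0.95),
) -> MortalityDraws:
    """Distribution of fishing mortality F = Z - M from independent draws.

    The two draw vectors are independently resampled with replacement to a
    common length and differenced elementwise.  Negative values are
    retained: with Z and M both uncertain, the F interval can cross zero.
    """
    z = np.asarray(z_draws, dtype=float).reshape(-1)
    m = np.asarray(m_draws, dtype=float).reshape(-1)
    if z.size == 0 or m.size == 0:
        raise ValueError("z_draws and m_draws must be non-empty")
    n = n_pairs or max(z.size, m.size)
    rng = np.random.default_rng(seed)
    f = z[rng.integers(0, z.size, n)] - m[rng.integers(0, m.size, n)]
    return MortalityDraws.from_draws(f, interval=interval)


class CatchCurve(BaseEstimator):
    """Bootstrap catch-curve estimator of total mortality Z.

    Parameters mirror :func:`bootstrap_Z`.  ``fit`` accepts a 1-d vector of
    integer ages (one per individual), a sequence of length-at-age records,
    or a DataFrame with an ``age_years`` column.

    Attributes
    ----------
    z_full_ : float
        Point estimate from the full (undeleted) data.
    z_draws_ : ndarray; z_median_, z_ci_ : summaries of the bootstrap.
    composition_ : AgeComposition built from the full data.
    n_discarded_ : replicates dropped for having < 3 usable age classes.
    """

    def __init__(
        self,
        n_boot: int = 20000,
        drop_fraction: float = 0.2,
        max_age_cutoff: int | None = None,
        exclude_ages: tuple = (),
        interval: tuple = (0.025, 0.975),
        random_state: int | None = None,
    ):
        self.n_boot = n_boot
        self.drop_fraction = drop_fraction
        self.max_age_cutoff = max_age_cutoff
        self.exclude_ages = exclude_ages
        self.interval = interval
        self.random_state = random_state

    def fit(self, X, y=None):
        ages = (
            np.asarray(X, dtype=float)
            if _is_age_vector(X)
            else _as_arrays(X)[0]
        ).astype(int)
        full = ages if self.max_age_cutoff is None else ages[ages < self.max_age_cutoff]
        self.composition_ = build_age_composition(full, exclude_ages=self.exclude_ages)
        self.z_full_ = catch_curve_slope(self.composition_)
        boot = bootstrap_Z(
            ages,
            n_boot=self.n_boot,
            drop_fraction=self.drop_fraction,
            max_age_cutoff=self.max_age_cutoff,
            exclude_ages=self.exclude_ages,
            seed=self.random_state,
            interval=self.interval,
        )
        self.z_draws_ = boot.draws
        self.z_median_ = boot.median
        self.z_ci_ = (boot.ci_low, boot.ci_high)
        self.n_discarded_ = boot.n_discarded
        self.n_features_in_ = 1
        return self

    def draws_frame(self) -> pd.DataFrame:
        """Bootstrap draws as a tidy frame (``replicate, Z``)."""
        return pd.DataFrame(
            {"replicate": np.arange(self.z_draws_.size), "Z": self.z_draws_}
        )
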
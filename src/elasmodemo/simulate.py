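"""Synthetic length-at-age data, age compositions, and fished populations.

These generators reproduce the statistical structure the analysis assumes,
so every pipeline stage can be exercised against known truth without any
field data:

* length-at-age records with lognormal multiplicative error around a von
  Bertalanffy mean, optionally truncated to a size window (the real catch
  sample spanned only 1100-2400 mm disc width, well short of the species
  maximum);
* multinomial age compositions from an exponentially decaying age structure
  with a logistic selectivity ogive (young classes are less catchable);
* a deterministic fished-cohort model in which total mortality M + F applies
  from the recruitment age onward, used to show that steep right-hand limbs
  of a catch curve can arise from fishing alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catch_curve import AgeComposition, build_age_composition
from .growth import GrowthParams, LengthAtAgeRecord, vb_mean

__all__ = [
    "GrowthSimConfig",
    "PopulationSimConfig",
    "generate_length_at_age",
    "generate_age_composition",
    "simulate_fished_population",
    "selectivity_at_age",
]

#: Defaults imitating the described devil-ray catch sample.  The original
#: per-age counts are not public; these are assumptions, not data.
DEFAULT_GROWTH_TRUTH = GrowthParams(k=0.12, dw_inf=3000.0, dw0=900.0, sigma2=0.01)


@dataclass(frozen=True)
class GrowthSimConfig:
    """Configuration for the length-at-age generator."""

    params: GrowthParams = DEFAULT_GROWTH_TRUTH
    n: int = 60
    age_range: tuple[int, int] = (0, 14)
    size_window: tuple[float, float] | None = (1100.0, 2400.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.age_range[0] < 0 or self.age_range[1] < self.age_range[0]:
            raise ValueError(f"invalid age_range {self.age_range}")
        if self.size_window is not None and self.size_window[1] <= self.size_window[0]:
            raise ValueError(f"invalid size_window {self.size_window}")


@dataclass(frozen=True)
class PopulationSimConfig:
    """Configuration for age-structure and catch-composition generators."""

    M: float = 0.087
    F: float = 0.163
    full_recruitment_age: int = 0
    selectivity_steepness: float = np.inf  # inf = knife-edge at recruitment
    max_age: int = 20
    n_sampled: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.M < 0 or self.F < 0:
            raise ValueError("mortality rates must be >= 0")
        if self.max_age < 1:
            raise ValueError("max_age must be >= 1")
        if self.n_sampled < 1:
            raise ValueError("n_sampled must be >= 1")
        if self.full_recruitment_age < 0:
            raise ValueError("full_recruitment_age must be >= 0")


def generate_length_at_age(cfg: GrowthSimConfig) -> list[LengthAtAgeRecord]:
    """Draw aged individuals with lognormal error around the VB curve.

    Ages are uniform over ``age_range`` (integer band counts); disc width is
    ``exp(ln(vb_mean(age)) + eps)`` with ``eps ~ Normal(0, sigma2)``.
    Records outside ``size_window`` are rejected and redrawn; a window so
    narrow that >99% of proposals are rejected raises.
    """
    rng = np.random.default_rng(cfg.seed)
    sd = np.sqrt(cfg.params.sigma2)
    records: list[LengthAtAgeRecord] = []
    n_rejected = 0
    while len(records) < cfg.n:
        m = cfg.n - len(records)
        ages = rng.integers(cfg.age_range[0], cfg.age_range[1] + 1, size=m)
        mu = vb_mean(ages, cfg.params)
        widths = np.exp(np.log(mu) + rng.normal(0.0, sd, size=m))
        if cfg.size_window is not None:
            lo, hi = cfg.size_window
            ok = (widths >= lo) & (widths <= hi)
        else:
            ok = np.ones(m, dtype=bool)
        n_rejected += int(m - ok.sum())
        records.extend(
            LengthAtAgeRecord(int(a), float(w))
            for a, w in zip(ages[ok], widths[ok])
        )
        proposals = len(records) + n_rejected
        if proposals >= 100 * cfg.n and n_rejected / proposals > 0.99:
            raise RuntimeError(
                f"size window {cfg.size_window} rejects >99% of proposals "
                f"({n_rejected}/{proposals})"
            )
    return records


def selectivity_at_age(ages, full_recruitment_age: int, steepness: float) -> np.ndarray:
    """Logistic ascending limb reaching exactly 1 at the recruitment age.

    Below full recruitment the ogive is a logistic curve (midpoint one year
    before full recruitment) rescaled so selectivity is 1 at recruitment and
    stays flat thereafter.  ``steepness = inf`` gives knife-edge selection.
    """
    ages = np.asarray(ages, dtype=float)
    R = float(full_recruitment_age)
    if np.isinf(steepness):
        return np.where(ages >= R, 1.0, 0.0)
    raw = 1.0 / (1.0 + np.exp(-steepness * (ages - (R - 1.0))))
    at_r = 1.0 / (1.0 + np.exp(-steepness))
    return np.where(ages >= R, 1.0, raw / at_r)


def _equilibrium_catch_proportions(cfg: PopulationSimConfig) -> np.ndarray:
    """Expected catch proportion per age: sel(a) * exp(-(M+F)*a), normalised."""
    ages = np.arange(cfg.max_age + 1)
    sel = selectivity_at_age(ages, cfg.full_recruitment_age, cfg.selectivity_steepness)
    p = sel * np.exp(-(cfg.M + cfg.F) * ages)
    total = p.sum()
    if total <= 0:
        raise ValueError("all catch proportions are zero under this configuration")
    return p / total


def generate_age_composition(cfg: PopulationSimConfig) -> AgeComposition:
    """Multinomial catch sample from the equilibrium age structure."""
    p = _equilibrium_catch_proportions(cfg)
    rng = np.random.default_rng(cfg.seed)
    counts = rng.multinomial(cfg.n_sampled, p)
    return AgeComposition(counts={int(a): float(c) for a, c in enumerate(counts)})


@dataclass
class FishedPopulation:
    """Deterministic cohort trajectory under fishing plus a catch sample."""

    trajectory: pd.DataFrame  # index: year, columns: age 0..max_age abundance
    equilibrium: AgeComposition  # fished equilibrium age structure (real-valued)
    sample: AgeComposition  # multinomial catch sample from the equilibrium
    config: PopulationSimConfig = field(repr=False, default=None)


def simulate_fished_population(
    cfg: PopulationSimConfig, n_years: int = 25
) -> FishedPopulation:
    """Project a cohort model from the unfished state under mortality M + F.

    Recruitment is constant (one unit per year).  Survival applies M to
    every age and adds F from ``full_recruitment_age`` onward, so the
    fished equilibrium abundance-at-age declines at rate M below
    recruitment and at M + F above it; with F = 0 the structure declines at
    rate M exactly.  Returns the year-by-age trajectory, the equilibrium
    structure, and a multinomial catch sample of ``n_sampled`` individuals
    (catch at age proportional to selectivity times abundance).
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    ages = np.arange(cfg.max_age + 1)
    R = cfg.full_recruitment_age
    z_at_age = cfg.M + np.where(ages >= R, cfg.F, 0.0)
    surv = np.exp(-z_at_age)

    # unfished starting structure: decay at M only
    n_at_age = np.exp(-cfg.M * ages)
    rows = [n_at_age.copy()]
    for _ in range(n_years):
        nxt = np.empty_like(n_at_age)
        nxt[0] = 1.0
        nxt[1:] = n_at_age[:-1] * surv[:-1]
        n_at_age = nxt
        rows.append(n_at_age.copy())
    trajectory = pd.DataFrame(rows, columns=[int(a) for a in ages])
    trajectory.index.name = "year"

    # exact fished equilibrium (independent of n_years)
    eq = np.exp(-(cfg.M * ages + cfg.F * np.maximum(ages - R, 0)))
    sel = selectivity_at_age(ages, R, cfg.selectivity_steepness)
    catch = sel * eq
    equilibrium = AgeComposition(
        counts={int(a): float(c) for a, c in zip(ages, catch)}
    )
    rng = np.random.default_rng(cfg.seed)
    sample_counts = rng.multinomial(cfg.n_sampled, catch / catch.sum())
    sample = AgeComposition(
        counts={int(a): float(c) for a, c in enumerate(sample_counts)}
    )
    return FishedPopulation(
        trajectory=trajectory, equilibrium=equilibrium, sample=sample, config=cfg
    )


def records_to_frame(records) -> pd.DataFrame:
    """Length-at-age records as a DataFrame with the standard column names."""
    return pd.DataFrame(
        {
            "age_years": [r.age for r in records],
            "disc_width_mm": [r.disc_width for r in records],
        }
    )


def composition_ages(comp: AgeComposition, rng=None) -> np.ndarray:
    """Expand a (integer-count) composition back into one age per individual."""
    ages = []
    for a in sorted(comp.counts):
        ages.extend([a] * int(round(comp.counts[a])))
    return np.array(ages, dtype=int)
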
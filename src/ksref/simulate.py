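"""Synthetic mixed-distribution datasets and the simulation-study harness.

The generator emulates routine laboratory data for three archetypal analytes:

* "hemoglobin"  — Gaussian physiological distribution, mu = 14.0, sigma = 0.98
  (reference interval 12.0-16.0 g/dL), n_total = 10,000, values at 2 decimals;
* "tsh"         — log-normal physiological distribution with 2.5th/97.5th
  percentiles 0.25-4.0 U/l, n_total = 50,000, values at 3 decimals;
* "ggt"         — log-normal physiological distribution with percentiles
  10-50 U/l, n_total = 25,000, integer values.

A scenario contaminates the physiological distribution with a configurable
fraction (0-30%) of "abnormal" results drawn from a second distribution while
keeping the total sample count fixed, runs the estimator over repeated cycles
(full study scale: 100), and summarizes the per-cycle reference limits by
their median, 5th-95th percentile range, and the fraction falling within
stated "narrow" margins around the true limits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core import Dataset, EstimationError, KsrefError, ValidationError, validate_dataset
from .estimator import EstimateResult, SearchConfig, Z_REFERENCE, estimate

__all__ = [
    "DistributionSpec",
    "ScenarioSpec",
    "ScenarioSummary",
    "distribution_from_interval",
    "generate",
    "run_scenario",
    "analyte_scenario",
    "hemoglobin_grid",
    "ANALYTES",
]

logger = logging.getLogger(__name__)

_FAMILIES = ("gaussian", "lognormal")
MAX_RESAMPLE_ATTEMPTS = 1000


@dataclass(frozen=True)
class DistributionSpec:
    """A Gaussian or log-normal component distribution.

    ``mu``/``sigma`` live in natural space for the Gaussian family and in log
    space (meanlog/sdlog) for the log-normal family.
    """

    family: str
    mu: float
    sigma: float

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValidationError(f"family must be one of {_FAMILIES}, got {self.family!r}")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")

    @property
    def p2_5(self) -> float:
        return self._quantile(-Z_REFERENCE)

    @property
    def p97_5(self) -> float:
        return self._quantile(Z_REFERENCE)

    def _quantile(self, z: float) -> float:
        x = self.mu + z * self.sigma
        return math.exp(x) if self.family == "lognormal" else x

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        draws = rng.normal(self.mu, self.sigma, size=size)
        if self.family == "lognormal":
            return np.exp(draws)
        return draws


def distribution_from_interval(family: str, p2_5: float, p97_5: float) -> DistributionSpec:
    """Derive a component distribution from its 2.5th/97.5th percentiles.

    Gaussian: ``mu = (p2_5 + p97_5)/2``, ``sigma = (p97_5 - p2_5)/(2*1.959964)``;
    log-normal: the same formulas applied to the log percentiles.
    """
    if not (p2_5 < p97_5):
        raise ValidationError("require p2_5 < p97_5")
    if family == "lognormal":
        if p2_5 <= 0:
            raise ValidationError("log-normal percentiles must be positive")
        lo, hi = math.log(p2_5), math.log(p97_5)
    elif family == "gaussian":
        lo, hi = p2_5, p97_5
    else:
        raise ValidationError(f"family must be one of {_FAMILIES}, got {family!r}")
    return DistributionSpec(
        family=family, mu=(lo + hi) / 2.0, sigma=(hi - lo) / (2.0 * Z_REFERENCE)
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """One contamination scenario of the simulation study.

    ``abnormal_fraction`` of the ``n_total`` samples are drawn from the
    abnormal distribution (rounded to the nearest integer count); the total
    dataset size never varies with the fraction.
    """

    physiological: DistributionSpec
    abnormal: DistributionSpec | None
    abnormal_fraction: float
    n_total: int
    decimals: int
    cycles: int = 100
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.abnormal_fraction <= 0.30):
            raise ValidationError("abnormal_fraction must lie in [0, 0.30]")
        if self.abnormal_fraction > 0 and self.abnormal is None:
            raise ValidationError("abnormal distribution required when fraction > 0")
        if self.n_total < 1 or self.cycles < 1:
            raise ValidationError("n_total and cycles must be positive")

    @property
    def n_abnormal(self) -> int:
        return int(round(self.abnormal_fraction * self.n_total))


@dataclass(frozen=True)
class ScenarioSummary:
    """Cross-cycle summary of estimated reference limits for one scenario."""

    median_lower: float
    median_upper: float
    lower_ci90: tuple
    upper_ci90: tuple
    within_margin_lower: float
    within_margin_upper: float
    n_cycles: int
    n_failed: int
    estimates: tuple  # of (lower, upper) per successful cycle


def _draw_positive(spec: DistributionSpec, rng: np.random.Generator, size: int, decimals: int) -> np.ndarray:
    """Draw ``size`` values, resampling any that would round nonpositive."""
    out = spec.rvs(rng, size)
    bad = np.round(out, decimals) <= 0.0
    attempts = 0
    while bad.any():
        attempts += 1
        if attempts > MAX_RESAMPLE_ATTEMPTS:
            raise EstimationError(
                "could not draw positive values after "
                f"{MAX_RESAMPLE_ATTEMPTS} resampling rounds: the {spec.family} "
                f"component (mu={spec.mu}, sigma={spec.sigma}) is pathologically placed"
            )
        out[bad] = spec.rvs(rng, int(bad.sum()))
        bad = np.round(out, decimals) <= 0.0
    return out


def generate(scenario: ScenarioSpec, cycle: int) -> Dataset:
    """Generate one cycle's mixed dataset, deterministic in (seed, cycle)."""
    rng = np.random.default_rng((scenario.seed, cycle))
    n_abn = scenario.n_abnormal
    n_phys = scenario.n_total - n_abn
    parts = [_draw_positive(scenario.physiological, rng, n_phys, scenario.decimals)]
    if n_abn > 0:
        parts.append(_draw_positive(scenario.abnormal, rng, n_abn, scenario.decimals))
    values = np.concatenate(parts)
    return validate_dataset(values, scenario.decimals)


def run_scenario(
    scenario: ScenarioSpec,
    config: SearchConfig | None = None,
    margins: tuple | None = None,
) -> ScenarioSummary:
    """Estimate each cycle's dataset and aggregate the reference limits.

    ``margins`` is an optional pair of (lo, hi) intervals — for the lower and
    upper limit respectively — against which the within-margin fractions are
    computed; without margins those fractions are NaN.  Cycles are independent
    (per-cycle RNG streams) so the summary is order-invariant.  More than 20%
    per-cycle estimation failures abort the scenario.
    """
    config = config or SearchConfig()
    pairs: list[tuple] = []
    n_failed = 0
    for cycle in range(scenario.cycles):
        ds = generate(scenario, cycle)
        try:
            res: EstimateResult = estimate(ds, config)
        except KsrefError as exc:
            n_failed += 1
            logger.warning("cycle %d estimation failed: %s", cycle, exc)
            continue
        pairs.append((res.lower_limit, res.upper_limit))
    if n_failed > 0.20 * scenario.cycles:
        raise EstimationError(
            f"scenario failed: {n_failed}/{scenario.cycles} cycles produced no estimate"
        )
    lows = np.array([p[0] for p in pairs])
    ups = np.array([p[1] for p in pairs])
    lo_ci = np.quantile(lows, [0.05, 0.95])
    up_ci = np.quantile(ups, [0.05, 0.95])
    if margins is not None:
        (mlo_l, mlo_h), (mup_l, mup_h) = margins
        wm_low = float(np.mean((lows >= mlo_l) & (lows <= mlo_h)))
        wm_up = float(np.mean((ups >= mup_l) & (ups <= mup_h)))
    else:
        wm_low = wm_up = float("nan")
    return ScenarioSummary(
        median_lower=float(np.median(lows)),
        median_upper=float(np.median(ups)),
        lower_ci90=(float(lo_ci[0]), float(lo_ci[1])),
        upper_ci90=(float(up_ci[0]), float(up_ci[1])),
        within_margin_lower=wm_low,
        within_margin_upper=wm_up,
        n_cycles=scenario.cycles,
        n_failed=n_failed,
        estimates=tuple(pairs),
    )


# ---------------------------------------------------------------------------
# shipped analyte defaults


@dataclass(frozen=True)
class _Analyte:
    physiological: DistributionSpec
    n_total: int
    decimals: int
    true_interval: tuple
    margins: tuple  # narrow-limit bands for (lower, upper)


ANALYTES: dict[str, _Analyte] = {
    "hemoglobin": _Analyte(
        physiological=DistributionSpec("gaussian", 14.0, 0.98),
        n_total=10_000,
        decimals=2,
        true_interval=(12.0, 16.0),
        margins=((11.8, 12.2), (15.8, 16.2)),
    ),
    "tsh": _Analyte(
        physiological=distribution_from_interval("lognormal", 0.25, 4.0),
        n_total=50_000,
        decimals=3,
        true_interval=(0.25, 4.0),
        margins=((0.2, 0.3), (3.8, 4.2)),
    ),
    "ggt": _Analyte(
        physiological=distribution_from_interval("lognormal", 10.0, 50.0),
        n_total=25_000,
        decimals=0,
        true_interval=(10.0, 50.0),
        margins=((8.0, 12.0), (48.0, 52.0)),
    ),
}


def analyte_scenario(
    name: str,
    abnormal: DistributionSpec | None = None,
    abnormal_fraction: float = 0.0,
    cycles: int = 100,
    seed: int = 0,
    n_total: int | None = None,
) -> ScenarioSpec:
    """A ScenarioSpec prefilled with the shipped defaults for one analyte."""
    try:
        a = ANALYTES[name]
    except KeyError:
        raise ValidationError(
            f"unknown analyte {name!r}; available: {sorted(ANALYTES)}"
        ) from None
    return ScenarioSpec(
        physiological=a.physiological,
        abnormal=abnormal,
        abnormal_fraction=abnormal_fraction,
        n_total=n_total if n_total is not None else a.n_total,
        decimals=a.decimals,
        cycles=cycles,
        seed=seed,
    )


def hemoglobin_grid(cycles: int = 100, seed: int = 0) -> list[ScenarioSpec]:
    """The shipped default contamination grid for "hemoglobin".

    Abnormal-low Gaussian with 95% interval 8.0-12.0 g/dL mixed in at
    fractions 0, 0.05, ..., 0.30; total size fixed at 10,000.
    """
    abnormal = distribution_from_interval("gaussian", 8.0, 12.0)
    grid = []
    for k in range(7):
        frac = round(0.05 * k, 2)
        grid.append(
            analyte_scenario(
                "hemoglobin",
                abnormal=abnormal if frac > 0 else None,
                abnormal_fraction=frac,
                cycles=cycles,
                seed=seed,
            )
        )
    return grid
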
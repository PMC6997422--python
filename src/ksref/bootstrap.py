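"""Percentile-bootstrap confidence intervals for the estimated reference limits.

Each replicate resamples the input values with replacement (the full multiset,
so rounding is re-applied per replicate), re-runs the complete nested
estimation — lambda grid included — and the confidence interval for each limit
is taken from the empirical percentiles of the replicate estimates.  Replicate
RNG streams are keyed by (seed, replicate index), so results do not depend on
execution order or the number of worker threads.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np

from .core import Dataset, EstimationError, KsrefError, validate_dataset
from .estimator import EstimateResult, SearchConfig, estimate

__all__ = ["ConfidenceIntervals", "bootstrap_ci"]

logger = logging.getLogger(__name__)

#: replicates may fail individually; above this fraction the CI is refused
MAX_FAILURE_FRACTION = 0.20


@dataclass(frozen=True)
class ConfidenceIntervals:
    """Percentile-bootstrap CIs for the lower and upper reference limit."""

    level: float
    replicates: int
    lower_limit_ci: tuple
    upper_limit_ci: tuple
    replicate_estimates: tuple  # of (lower, upper) pairs, successful replicates
    n_failed: int


def _one_replicate(dataset: Dataset, config: SearchConfig, seed: int, r: int):
    rng = np.random.default_rng((seed, r))
    idx = rng.integers(0, dataset.n_total, size=dataset.n_total)
    resampled = validate_dataset(dataset.values[idx], dataset.decimals)
    return estimate(resampled, config)


def bootstrap_ci(
    dataset: Dataset,
    config: SearchConfig | None = None,
    replicates: int = 100,
    level: float = 0.90,
    seed: int = 0,
    threads: int = 1,
) -> ConfidenceIntervals:
    """Bootstrap both reference limits by re-estimating on resampled data.

    Parameters
    ----------
    replicates : int
        Number of bootstrap resamples (>= 2).
    level : float
        Central coverage of the percentile interval, e.g. 0.90 for the
        5th-95th percentiles of the replicate limits.
    seed : int
        Root seed; replicate ``r`` uses the RNG stream keyed by ``(seed, r)``.
    threads : int
        Worker threads; the result is identical for any thread count.

    Raises
    ------
    EstimationError
        If more than 20% of replicates fail to produce an estimate (individual
        failures are logged and excluded otherwise).
    """
    config = config or SearchConfig()
    if replicates < 2:
        raise EstimationError("bootstrap requires at least 2 replicates")
    if not (0.0 < level < 1.0):
        raise EstimationError(f"CI level must lie in (0, 1), got {level!r}")

    def run(r: int):
        try:
            return _one_replicate(dataset, config, seed, r)
        except KsrefError as exc:  # pragma: no cover - rare on sane inputs
            logger.warning("bootstrap replicate %d failed: %s", r, exc)
            return None

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            outcomes = list(pool.map(run, range(replicates)))
    else:
        outcomes = [run(r) for r in range(replicates)]

    ok: list[EstimateResult] = [o for o in outcomes if o is not None]
    n_failed = replicates - len(ok)
    if n_failed > MAX_FAILURE_FRACTION * replicates:
        raise EstimationError(
            f"bootstrap failed: {n_failed}/{replicates} replicates "
            f"({n_failed / replicates:.0%}) did not produce an estimate"
        )

    pairs = tuple((r.lower_limit, r.upper_limit) for r in ok)
    lows = np.array([p[0] for p in pairs])
    ups = np.array([p[1] for p in pairs])
    alpha = (1.0 - level) / 2.0
    lo_ci = np.quantile(lows, [alpha, 1.0 - alpha])
    up_ci = np.quantile(ups, [alpha, 1.0 - alpha])
    return ConfidenceIntervals(
        level=level,
        replicates=replicates,
        lower_limit_ci=(float(lo_ci[0]), float(lo_ci[1])),
        upper_limit_ci=(float(up_ci[0]), float(up_ci[1])),
        replicate_estimates=pairs,
        n_failed=n_failed,
    )
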
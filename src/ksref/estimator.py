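"""Penalized Kolmogorov-Smirnov estimation of reference intervals.

The physiological component of a mixed dataset is modelled as a power-normal
distribution: Gaussian with parameters (mu, sigma) after Box-Cox
transformation with lambda in [0, 1].  A truncation interval T = [t1, t2] is
assumed to contain a negligible proportion of abnormal results.  The
estimator minimizes

    KS = sup_{x in T} |D_T(x) - F_T(x)| / sqrt(n) + p1 + p2

where D_T is the conditional (renormalized) empirical CDF inside T, F_T the
conditional Gaussian CDF, and n the number of samples inside T.  The penalty
terms guard against fits that claim more physiological mass outside T than
was observed: with c = (n / n_total) / (Phi(t2) - Phi(t1)) the implied
physiological fraction of the dataset,

    p1 = max(0, sup_{x < t1} c*Phi(x) - D(x)) / sqrt(n)
    p2 = max(0, sup_{x > t2} D(x) - (1 - c*(1 - Phi(x)))) / sqrt(n)

so abnormal mass in the tails is penalty-free while an implausibly wide
Gaussian is not.  Negative suprema are ignored.

The search is nested: a brute-force grid over lambda (coarse step 0.1, then
a fine 0.01 pass around the coarse winner), a brute-force grid over all
truncation-limit pairs drawn from percentile bands of the data (defaults:
t1 in the 5th-30th, t2 in the 70th-95th percentile band), and a Nelder-Mead
fit of (mu, sigma) for each (lambda, T) candidate.  Reference limits are the
back-transformed mu -/+ z*sigma with z = 1.959964 (central 95% interval).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
from scipy.special import ndtr

from . import _kernel
from .core import (
    Dataset,
    EstimationError,
    GaussianParams,
    TruncationInterval,
    ValidationError,
    boxcox,
    inverse_boxcox,
)

__all__ = [
    "SearchConfig",
    "ObjectiveBreakdown",
    "EstimateResult",
    "objective",
    "truncation_candidates",
    "fit_gaussian",
    "estimate",
]

logger = logging.getLogger(__name__)

#: z-quantile of the central 95% interval (2.5th/97.5th percentiles).
Z_REFERENCE = 1.959964


@dataclass(frozen=True)
class SearchConfig:
    """Tunable parameters of the nested optimization.

    The percentile bands bound the brute-force truncation search; the lambda
    steps define the coarse/fine brute-force grids; ``min_n_inside`` rejects
    truncation candidates with too few samples for a stable KS statistic;
    ``max_candidates_per_side`` thins dense candidate grids (by evenly spaced
    quantile ranks) to bound run time.  ``nm_warm_start`` seeds each
    candidate's Nelder-Mead fit from the previous candidate's optimum when
    that evaluates better than the robust initializer; disable it to start
    every fit from (median, IQR/1.349) alone.
    """

    t1_percentile_range: tuple = (0.05, 0.30)
    t2_percentile_range: tuple = (0.70, 0.95)
    lambda_coarse_step: float = 0.1
    lambda_fine_step: float = 0.01
    max_candidates_per_side: int = 40
    nm_tolerance: float = 1e-7
    nm_max_iter: int = 500
    min_n_inside: int = 50
    reference_z: float = Z_REFERENCE
    nm_warm_start: bool = True

    def __post_init__(self):
        lo1, hi1 = self.t1_percentile_range
        lo2, hi2 = self.t2_percentile_range
        if not (0.0 < lo1 <= hi1 < lo2 <= hi2 < 1.0):
            raise ValidationError(
                "percentile ranges must satisfy 0 < t1_lo <= t1_hi < t2_lo <= t2_hi < 1"
            )
        if self.lambda_coarse_step <= 0 or self.lambda_fine_step <= 0:
            raise ValidationError("lambda grid steps must be positive")
        if self.lambda_fine_step > self.lambda_coarse_step:
            raise ValidationError("fine lambda step must not exceed the coarse step")
        if self.min_n_inside < 1:
            raise ValidationError("min_n_inside must be >= 1")
        if self.max_candidates_per_side < 2:
            raise ValidationError("max_candidates_per_side must be >= 2")
        if self.nm_tolerance <= 0 or self.nm_max_iter < 1:
            raise ValidationError("invalid Nelder-Mead settings")
        if not (0.0 < self.reference_z):
            raise ValidationError("reference_z must be positive")

    # -- flat key=value (de)serialization, used by the CLI --config flag ----
    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = v
        return d

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                v = getattr(self, f.name)
                if isinstance(v, tuple):
                    v = ",".join(repr(x) for x in v)
                fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_file(cls, path) -> "SearchConfig":
        kwargs = {}
        field_types = {f.name: f for f in fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
                key, raw = (s.strip() for s in line.split("=", 1))
                if key not in field_types:
                    raise ValidationError(f"{path}:{lineno}: unknown key {key!r}")
                default = getattr(cls, key, None)
                if key.endswith("percentile_range"):
                    parts = [float(s) for s in raw.split(",")]
                    if len(parts) != 2:
                        raise ValidationError(f"{path}:{lineno}: expected two numbers")
                    kwargs[key] = tuple(parts)
                elif isinstance(default, bool):
                    kwargs[key] = raw.lower() in ("1", "true", "yes", "on")
                elif isinstance(default, int):
                    kwargs[key] = int(raw)
                else:
                    kwargs[key] = float(raw)
        return cls(**kwargs)


@dataclass(frozen=True)
class ObjectiveBreakdown:
    """The minimization target split into its three non-negative terms."""

    ks_main: float
    p1: float
    p2: float

    @property
    def total(self) -> float:
        return self.ks_main + self.p1 + self.p2


@dataclass(frozen=True)
class EstimateResult:
    """Optimized parameters and the back-transformed reference limits."""

    lam: float
    gauss: GaussianParams
    trunc: TruncationInterval
    objective: ObjectiveBreakdown
    lower_limit: float
    upper_limit: float


# ---------------------------------------------------------------------------
# objective


def _hist_arrays(dataset: Dataset):
    cum = np.cumsum(dataset.counts).astype(np.float64)
    return dataset.distinct_values, cum, float(dataset.n_total)


def _edge_arrays(dataset: Dataset, lam: float):
    """Transformed lower/upper bin edges of the distinct rounded values.

    A value rounded to ``k`` at ``decimals`` precision represents the bin
    ``[k - h/2, k + h/2)`` with ``h = 10**-decimals``; the right-continuous
    ECDF at ``k`` therefore carries the continuum mass up to the upper edge,
    and the Gaussian CDF is evaluated there.
    """
    h = 10.0 ** (-dataset.decimals)
    eu = np.ascontiguousarray(boxcox(dataset.distinct_values + 0.5 * h, lam))
    el = np.ascontiguousarray(boxcox(dataset.distinct_values - 0.5 * h, lam))
    return eu, el


_INF_BREAKDOWN = ObjectiveBreakdown(ks_main=np.inf, p1=0.0, p2=0.0)


def objective(
    dataset: Dataset,
    lam: float,
    gauss: GaussianParams,
    trunc: TruncationInterval,
) -> ObjectiveBreakdown:
    """Exact penalized-KS breakdown at the given parameters.

    Degenerate configurations (no samples inside T, or a truncation interval
    carrying Gaussian probability mass below 1e-6) yield an infinite
    ``ks_main`` rather than an error, so optimizers can step through them.
    """
    distinct, cum, n_total = _hist_arrays(dataset)
    zs = boxcox(distinct, lam)
    i1 = int(np.searchsorted(zs, trunc.t1, side="left"))
    i2 = int(np.searchsorted(zs, trunc.t2, side="right")) - 1
    if i2 < i1:
        return _INF_BREAKDOWN
    base = cum[i1 - 1] if i1 > 0 else 0.0
    n_in = cum[i2] - base
    if trunc.n_inside >= 0 and int(n_in) != int(trunc.n_inside):
        raise ValidationError(
            f"truncation interval claims n_inside={trunc.n_inside} but the dataset "
            f"contains {int(n_in)} samples in [{trunc.t1}, {trunc.t2}]"
        )
    eu, el = _edge_arrays(dataset, lam)
    sig = gauss.sigma
    p_lo = float(ndtr((el[i1] - gauss.mu) / sig))
    p_hi = float(ndtr((eu[i2] - gauss.mu) / sig))
    q = p_hi - p_lo
    if q < 1e-6 or n_in <= 0:
        return _INF_BREAKDOWN
    c = (n_in / n_total) / q
    sq = np.sqrt(n_in)

    phi = ndtr((eu - gauss.mu) / sig)
    f_t = (phi[i1 : i2 + 1] - p_lo) / q
    d_t = (cum[i1 : i2 + 1] - base) / n_in
    ks = float(np.max(np.abs(d_t - f_t))) / sq

    p1 = 0.0
    if i1 > 0:
        p1 = max(0.0, float(np.max(c * phi[:i1] - cum[:i1] / n_total))) / sq
    p2 = 0.0
    if i2 + 1 < zs.size:
        surv = 1.0 - c * (1.0 - phi[i2 + 1 :])
        p2 = max(0.0, float(np.max(cum[i2 + 1 :] / n_total - surv))) / sq
    return ObjectiveBreakdown(ks_main=ks, p1=p1, p2=p2)


# ---------------------------------------------------------------------------
# truncation candidates


def _candidate_sides(dataset: Dataset, config: SearchConfig):
    """Index sets of eligible t1/t2 values (percentile-rank based, lambda-free).

    Percentile ranks are invariant under the monotone Box-Cox map, so the same
    candidate pairs are examined at every lambda and objective totals remain
    comparable across the lambda grid.
    """
    cum = np.cumsum(dataset.counts)
    ranks = cum / dataset.n_total
    lo1, hi1 = config.t1_percentile_range
    lo2, hi2 = config.t2_percentile_range
    side1 = np.flatnonzero((ranks >= lo1) & (ranks <= hi1))
    side2 = np.flatnonzero((ranks >= lo2) & (ranks <= hi2))

    def thin(idx):
        if idx.size > config.max_candidates_per_side:
            pos = np.unique(
                np.round(
                    np.linspace(0, idx.size - 1, config.max_candidates_per_side)
                ).astype(int)
            )
            return idx[pos]
        return idx

    return thin(side1), thin(side2)


def _candidate_index_pairs(dataset: Dataset, config: SearchConfig):
    side1, side2 = _candidate_sides(dataset, config)
    if side1.size == 0 or side2.size == 0:
        raise EstimationError(
            "no truncation candidates: dataset too small or too discrete for the "
            "configured percentile ranges"
        )
    cum = np.cumsum(dataset.counts)
    i1g, i2g = np.meshgrid(side1, side2, indexing="ij")
    i1g = i1g.ravel()
    i2g = i2g.ravel()
    base = np.where(i1g > 0, cum[np.maximum(i1g - 1, 0)], 0)
    n_in = cum[i2g] - base
    keep = n_in >= config.min_n_inside
    i1g, i2g = i1g[keep], i2g[keep]
    if i1g.size == 0:
        raise EstimationError(
            "no truncation candidate holds at least "
            f"{config.min_n_inside} samples: dataset too small or too discrete"
        )
    order = np.lexsort((i2g, i1g))
    return i1g[order].astype(np.int64), i2g[order].astype(np.int64)


def truncation_candidates(
    dataset: Dataset, lam: float, config: SearchConfig | None = None
) -> list[TruncationInterval]:
    """All truncation intervals the brute-force search will examine.

    Candidate limits are distinct transformed values whose percentile rank
    falls in the configured bands; dense sides are thinned to
    ``max_candidates_per_side`` evenly spaced quantile ranks; pairs holding
    fewer than ``min_n_inside`` samples are dropped.
    """
    config = config or SearchConfig()
    c1, c2 = _candidate_index_pairs(dataset, config)
    zs = boxcox(dataset.distinct_values, lam)
    cum = np.cumsum(dataset.counts)
    out = []
    for i1, i2 in zip(c1, c2):
        base = int(cum[i1 - 1]) if i1 > 0 else 0
        out.append(
            TruncationInterval(
                t1=float(zs[i1]), t2=float(zs[i2]), n_inside=int(cum[i2]) - base
            )
        )
    return out


# ---------------------------------------------------------------------------
# fitting


def _locate(zs: np.ndarray, trunc: TruncationInterval):
    i1 = int(np.searchsorted(zs, trunc.t1, side="left"))
    i2 = int(np.searchsorted(zs, trunc.t2, side="right")) - 1
    if i2 < i1:
        raise EstimationError("truncation interval contains no data")
    return i1, i2


def fit_gaussian(
    dataset: Dataset,
    lam: float,
    trunc: TruncationInterval,
    config: SearchConfig | None = None,
) -> tuple[GaussianParams, ObjectiveBreakdown]:
    """Nelder-Mead fit of (mu, sigma) for a fixed lambda and truncation interval.

    Starts from the robust initializer (weighted median and IQR/1.349 of the
    transformed values inside T); if the first run terminates on the iteration
    cap, one restart from (mean, SD) inside T is attempted.  The returned
    breakdown is evaluated with the exact objective at the optimum.
    """
    config = config or SearchConfig()
    distinct, cum, n_total = _hist_arrays(dataset)
    zs = boxcox(distinct, lam)
    counts = dataset.counts.astype(np.float64)
    i1, i2 = _locate(zs, trunc)
    eu, el = _edge_arrays(dataset, lam)
    mu, sig, f = _kernel._fit_candidate(
        eu,
        el,
        counts,
        cum,
        n_total,
        i1,
        i2,
        config.nm_tolerance,
        config.nm_max_iter,
        0.0,
        -1.0,
        False,
        _kernel.PHI_TABLE,
    )
    if f >= _kernel.BIG or sig <= 0.0:
        raise EstimationError(
            "Gaussian fit failed: objective degenerate for every simplex step"
        )
    gauss = GaussianParams(mu=float(mu), sigma=float(sig))
    return gauss, objective(dataset, lam, gauss, trunc)


def _lambda_grid(start: float, stop: float, step: float):
    n = int(round((stop - start) / step))
    return [round(start + k * step, 12) for k in range(n + 1)]


def estimate(dataset: Dataset, config: SearchConfig | None = None) -> EstimateResult:
    """Full nested optimization: lambda grid x truncation grid x (mu, sigma) fit.

    The coarse lambda grid {0, 0.1, ..., 1} is scanned first; a fine grid
    (step ``lambda_fine_step``) spanning one coarse step around the coarse
    winner follows.  The global winner defines (lambda, mu, sigma, T); ties
    within 1e-12 on the objective prefer the wider truncation interval, then
    the smaller lambda.  Reference limits are
    ``inverse_boxcox(mu -/+ z*sigma, lambda)``.

    The result is deterministic for a fixed dataset and configuration and
    independent of input-row order (the histogram is order-free).
    """
    config = config or SearchConfig()
    distinct, cum, n_total = _hist_arrays(dataset)
    counts = dataset.counts.astype(np.float64)
    c1, c2 = _candidate_index_pairs(dataset, config)
    logger.info(
        "truncation search: %d candidate pairs over %d distinct values",
        c1.size,
        distinct.size,
    )

    results: dict[float, tuple] = {}

    def eval_lambda(lam: float):
        if lam in results:
            return
        eu, el = _edge_arrays(dataset, lam)
        f, mu, sig, j = _kernel._scan_candidates(
            eu,
            el,
            counts,
            cum,
            n_total,
            c1,
            c2,
            config.nm_tolerance,
            config.nm_max_iter,
            config.nm_warm_start,
            _kernel.PHI_TABLE,
        )
        results[lam] = (float(f), float(mu), float(sig), int(j))

    coarse = _lambda_grid(0.0, 1.0, config.lambda_coarse_step)
    for lam in coarse:
        eval_lambda(lam)

    def pick(cands: list[float]) -> float:
        best = None
        for lam in sorted(cands):
            f, mu, sig, j = results[lam]
            if j < 0:
                continue
            i1, i2 = c1[j], c2[j]
            n_in = cum[i2] - (cum[i1 - 1] if i1 > 0 else 0.0)
            if best is None or f < best[1] - _kernel.TIE_TOL:
                best = (lam, f, n_in)
            elif f <= best[1] + _kernel.TIE_TOL and n_in > best[2]:
                best = (lam, f, n_in)
        if best is None:
            raise EstimationError(
                "estimation failed: every (lambda, truncation) candidate was degenerate"
            )
        return best[0]

    lam_star = pick(coarse)
    half = int(round(config.lambda_coarse_step / config.lambda_fine_step)) - 1
    fine = [
        round(lam_star + k * config.lambda_fine_step, 12)
        for k in range(-half, half + 1)
    ]
    for lam in fine:
        if 0.0 <= lam <= 1.0:
            eval_lambda(lam)

    lam_best = pick(list(results))
    f, mu, sig, j = results[lam_best]
    i1, i2 = int(c1[j]), int(c2[j])
    zs = boxcox(distinct, lam_best)
    base = int(np.cumsum(dataset.counts)[i1 - 1]) if i1 > 0 else 0
    trunc = TruncationInterval(
        t1=float(zs[i1]),
        t2=float(zs[i2]),
        n_inside=int(np.cumsum(dataset.counts)[i2]) - base,
    )
    gauss = GaussianParams(mu=mu, sigma=sig)
    breakdown = objective(dataset, lam_best, gauss, trunc)
    z = config.reference_z
    lower = inverse_boxcox(mu - z * sig, lam_best)
    upper = inverse_boxcox(mu + z * sig, lam_best)
    logger.info(
        "estimate: lambda=%.2f mu=%.6g sigma=%.6g T=[%.6g, %.6g] n=%d KS=%.6g "
        "-> interval [%.6g, %.6g]",
        lam_best,
        mu,
        sig,
        trunc.t1,
        trunc.t2,
        trunc.n_inside,
        breakdown.total,
        lower,
        upper,
    )
    return EstimateResult(
        lam=lam_best,
        gauss=gauss,
        trunc=trunc,
        objective=breakdown,
        lower_limit=lower,
        upper_limit=upper,
    )
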
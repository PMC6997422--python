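"""Core data structures and transforms for indirect reference-interval estimation.

Routine clinical-laboratory data mix physiological results with abnormal ones
(disease, treatment effects).  Indirect methods estimate the distribution of
the physiological component — and hence the 2.5th/97.5th-percentile reference
interval — directly from such mixed data.  This module provides the shared
building blocks: a validated, histogrammed dataset; the Box-Cox power
transform that maps right-skewed analytes toward normality; and the empirical
cumulative distribution function (ECDF) in transformed space.

Conventions
-----------
* All measurements must be strictly positive (a Box-Cox requirement).
* Values are rounded to a fixed decimal precision and represented as a
  distinct-value histogram; the ECDF is the right-continuous cumulative
  histogram with ties aggregated at the rounded value.
* The Box-Cox parameter ``lambda`` is restricted to [0, 1], spanning
  log-normal (0) to Gaussian (1) shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import boxcox as _sp_boxcox
from scipy.special import inv_boxcox as _sp_inv_boxcox

__all__ = [
    "KsrefError",
    "ValidationError",
    "EstimationError",
    "NotInvertibleError",
    "Dataset",
    "GaussianParams",
    "TruncationInterval",
    "validate_dataset",
    "boxcox",
    "inverse_boxcox",
    "ecdf",
]


class KsrefError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(KsrefError, ValueError):
    """Invalid input data or parameters."""


class EstimationError(KsrefError, RuntimeError):
    """The estimation procedure could not produce a result."""


class NotInvertibleError(EstimationError):
    """A transformed-space limit cannot be mapped back to analyte units.

    For ``lambda > 0`` the inverse Box-Cox transform requires
    ``lambda * y + 1 > 0``; a fitted limit violating this indicates an
    implausible fit rather than a recoverable numeric issue.
    """


def _check_lambda(lam: float) -> float:
    lam = float(lam)
    if not np.isfinite(lam) or not (0.0 <= lam <= 1.0):
        raise ValidationError(f"Box-Cox lambda must lie in [0, 1], got {lam!r}")
    return lam


def boxcox(x, lam: float):
    """Box-Cox transform ``(x**lam - 1)/lam`` (natural log at ``lam == 0``).

    Parameters
    ----------
    x : float or array-like
        Strictly positive value(s) in analyte units.
    lam : float
        Skewness parameter in [0, 1].

    Returns
    -------
    float or ndarray
        Transformed value(s); scalar input yields a Python float.
    """
    lam = _check_lambda(lam)
    arr = np.asarray(x, dtype=float)
    if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr <= 0.0)):
        raise ValidationError("Box-Cox transform requires strictly positive, finite input")
    out = _sp_boxcox(arr, lam)
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def inverse_boxcox(y, lam: float):
    """Inverse of :func:`boxcox`: map transformed values back to analyte units.

    Raises
    ------
    NotInvertibleError
        If ``lam > 0`` and ``lam * y + 1 <= 0`` (the transformed value lies
        outside the image of the positive half-line).
    """
    lam = _check_lambda(lam)
    arr = np.asarray(y, dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValidationError("inverse Box-Cox requires finite input")
    if lam > 0.0 and np.any(lam * arr + 1.0 <= 0.0):
        raise NotInvertibleError(
            f"limit not invertible: lambda*y + 1 <= 0 for lambda={lam}"
        )
    out = _sp_inv_boxcox(arr, lam)
    if np.isscalar(y) or arr.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class Dataset:
    """A validated set of laboratory results with its distinct-value histogram.

    Attributes
    ----------
    values : ndarray
        The validated input measurements (analyte units, unrounded); resampling
        procedures operate on this multiset so rounding is re-applied per
        resample.
    decimals : int
        Rounding precision used for histogramming.
    distinct_values : ndarray
        Sorted unique rounded values.
    counts : ndarray
        Multiplicity of each distinct rounded value; ``sum(counts) == n_total``.
    """

    values: np.ndarray
    decimals: int
    distinct_values: np.ndarray
    counts: np.ndarray

    @property
    def n_total(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class GaussianParams:
    """Location/scale of the fitted Gaussian in Box-Cox-transformed space."""

    mu: float
    sigma: float

    def __post_init__(self):
        if not np.isfinite(self.mu) or not np.isfinite(self.sigma):
            raise ValidationError("Gaussian parameters must be finite")
        if self.sigma <= 0.0:
            raise ValidationError(f"sigma must be positive, got {self.sigma!r}")


@dataclass(frozen=True)
class TruncationInterval:
    """A truncation interval in transformed space.

    ``[t1, t2]`` is the sub-range assumed to contain a negligible proportion
    of abnormal results; ``n_inside`` counts samples with ``t1 <= x <= t2``.
    """

    t1: float
    t2: float
    n_inside: int

    def __post_init__(self):
        if not (self.t1 < self.t2):
            raise ValidationError(
                f"truncation interval requires t1 < t2, got [{self.t1}, {self.t2}]"
            )

    @classmethod
    def from_bounds(cls, dataset: "Dataset", lam: float, t1: float, t2: float) -> "TruncationInterval":
        """Build an interval and count the dataset's samples inside it."""
        zs = boxcox(dataset.distinct_values, lam)
        cum = np.cumsum(dataset.counts)
        i1 = int(np.searchsorted(zs, t1, side="left"))
        i2 = int(np.searchsorted(zs, t2, side="right")) - 1
        if i2 < i1:
            n_inside = 0
        else:
            n_inside = int(cum[i2] - (cum[i1 - 1] if i1 > 0 else 0))
        return cls(t1=float(t1), t2=float(t2), n_inside=n_inside)


def _readonly(arr: np.ndarray) -> np.ndarray:
    arr = np.array(arr, copy=True)
    arr.flags.writeable = False
    return arr


def validate_dataset(raw_values, decimals: int) -> Dataset:
    """Validate raw measurements and build the distinct-value histogram.

    Every value must be finite and strictly positive; values that round to
    zero at the requested precision are rejected as well, since they would
    be indistinguishable from nonpositive input downstream.

    Raises
    ------
    ValidationError
        On empty input, non-finite entries, or nonpositive values.  The error
        names the first offending row (0-based); if your analyte legitimately
        contains zeros, apply and document a positive offset before analysis.
    """
    decimals = int(decimals)
    if decimals < 0:
        raise ValidationError(f"decimals must be non-negative, got {decimals}")
    arr = np.asarray(raw_values, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError("empty input: no values to analyse")
    bad = ~np.isfinite(arr)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(f"non-finite value at row {row}: {arr[row]!r}")
    nonpos = arr <= 0.0
    if nonpos.any():
        row = int(np.flatnonzero(nonpos)[0])
        raise ValidationError(
            f"nonpositive value at row {row}: {arr[row]!r}; the Box-Cox transform "
            "requires positive input — apply and document a positive offset if needed"
        )
    rounded = np.round(arr, decimals)
    zeroed = rounded <= 0.0
    if zeroed.any():
        row = int(np.flatnonzero(zeroed)[0])
        raise ValidationError(
            f"value at row {row} ({arr[row]!r}) rounds to zero at {decimals} decimals"
        )
    distinct, counts = np.unique(rounded, return_counts=True)
    return Dataset(
        values=_readonly(arr),
        decimals=decimals,
        distinct_values=_readonly(distinct),
        counts=_readonly(counts.astype(np.int64)),
    )


def ecdf(dataset: Dataset, x, lam: float):
    """Empirical CDF of the transformed histogram, evaluated at ``x``.

    ``D(x)`` is the fraction of rounded values whose Box-Cox transform is
    ``<= x`` (right-continuous step function).
    """
    zs = boxcox(dataset.distinct_values, lam)
    cum = np.cumsum(dataset.counts)
    idx = np.searchsorted(zs, np.asarray(x, dtype=float), side="right")
    frac = np.where(idx > 0, cum[np.maximum(idx - 1, 0)], 0) / dataset.n_total
    if np.isscalar(x) or np.asarray(x).ndim == 0:
        return float(frac)
    return frac
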
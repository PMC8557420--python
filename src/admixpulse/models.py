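"""Closed-form distributions for the extended admixture pulse model.

The model describes gene flow from a donor into a recipient population
whose per-generation migration rate follows a rescaled Gamma density with
mean ``t_m`` (generations before sampling) and shape ``k``; the total
migrant fraction is ``alpha``.  Conditional on entering ``t`` generations
ago, an introgressed segment has an exponentially distributed genetic
length with rate ``t`` (one expected crossover per Morgan per generation),
so marginally segment lengths follow a Lomax (Pareto type II)
distribution with shape ``k + 1`` and scale ``k / t_m``.  The instantaneous
("simple") pulse is the ``k -> inf`` limit with exponential segment
lengths; constant ongoing migration at rate ``m`` is the ``k = 1``,
``t_m = 1/m`` case.

Admixture duration is summarised as ``t_d = 4 t_m / sqrt(k)``, four
conditional standard deviations of the entry-time distribution.

Units: all lengths and genetic distances are in Morgan, all times in
generations.  Centimorgan appear only at I/O boundaries (see
:mod:`admixpulse.io`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PulseParams",
    "ALDModelParams",
    "segment_pdf_simple",
    "segment_pdf_extended",
    "segment_moments",
    "segment_time_pdf",
    "migration_density",
    "ald_simple",
    "ald_extended",
    "ald_from_segment_density",
    "segment_density_from_ald",
    "effective_migration",
    "convert_duration",
    "convert_shape",
    "generations_to_years",
    "generations_to_ky",
]


def _check_positive(name: str, value: float) -> None:
    if not np.all(np.asarray(value) > 0):
        raise ValueError(f"{name} must be > 0, got {value}")


def _check_nonnegative_lengths(l) -> np.ndarray:
    arr = np.asarray(l, dtype=float)
    if np.any(arr < 0):
        raise ValueError("segment lengths / distances must be >= 0")
    return arr


@dataclass(frozen=True)
class PulseParams:
    """Admixture-history parameters.

    Parameters
    ----------
    t_m:
        Mean admixture time in generations before sampling (> 0).
    k:
        Gamma shape of the migration-rate density (>= 1).  Large ``k``
        approaches an instantaneous pulse; ``k = 1`` is the constant
        migration limit.
    alpha:
        Total introgressed fraction, in (0, 1).
    """

    t_m: float
    k: float = 1e8
    alpha: float = 0.03

    def __post_init__(self) -> None:
        _check_positive("t_m", self.t_m)
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @property
    def t_d(self) -> float:
        """Admixture duration t_d = 4 t_m / sqrt(k), generations."""
        return convert_duration(self.t_m, self.k)

    @classmethod
    def from_duration(cls, t_m: float, t_d: float, alpha: float = 0.03) -> "PulseParams":
        """Build parameters from (t_m, t_d) via k = 16 t_m^2 / t_d^2."""
        return cls(t_m=t_m, k=convert_shape(t_m, t_d), alpha=alpha)


@dataclass(frozen=True)
class ALDModelParams:
    """Parameters of the ancestry-LD decay curve D(l) = A (1 + t_m l / k)^(-k) + c.

    ``A`` is the amplitude (intercept above background) and ``c`` a
    constant background-LD offset.  Only ``t_m`` and ``k`` of ``pulse``
    are used.
    """

    pulse: PulseParams
    A: float = 1.0
    c: float = 0.0

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError(f"amplitude A must be >= 0, got {self.A}")

    def __call__(self, l) -> np.ndarray:
        return ald_extended(l, self.pulse.t_m, self.pulse.k, self.A, self.c)


def segment_pdf_simple(l, t_m: float):
    """Density of segment length under an instantaneous pulse: t_m exp(-t_m l).

    ``l`` in Morgan, ``t_m`` in generations; all segments entered exactly
    ``t_m`` generations before sampling.
    """
    _check_positive("t_m", t_m)
    arr = _check_nonnegative_lengths(l)
    out = t_m * np.exp(-t_m * arr)
    return out if arr.ndim else float(out)


def segment_pdf_extended(l, t_m: float, k: float):
    """Lomax density of segment length under the extended pulse.

    Lomax with shape ``k + 1`` and scale ``k / t_m``:
    ``(k+1) (k/t_m)^(k+1) (k/t_m + l)^(-(k+2))``, evaluated in a form
    stable for very large ``k`` (where it converges to the exponential
    density of the simple pulse).
    """
    _check_positive("t_m", t_m)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    arr = _check_nonnegative_lengths(l)
    # (k+1)/scale * (1 + l/scale)^-(k+2) with scale = k/t_m, via log1p
    out = (k + 1.0) / k * t_m * np.exp(-(k + 2.0) * np.log1p(t_m * arr / k))
    return out if arr.ndim else float(out)


def segment_moments(t_m: float, k: float) -> tuple[float, float]:
    """Mean and variance of the extended-pulse segment length.

    The mean is ``1/t_m`` for every ``k`` (identical to the simple
    pulse); the variance ``(k+1) / ((k-1) t_m^2)`` is inflated by the
    spread of entry times, diverges at ``k = 1`` and tends to the simple
    pulse value ``1/t_m^2`` as ``k -> inf``.
    """
    _check_positive("t_m", t_m)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k == 1:
        raise ValueError("variance is infinite at k = 1 (constant migration limit)")
    mean = 1.0 / t_m
    var = (k + 1.0) / ((k - 1.0) * t_m**2)
    return mean, var


def segment_time_pdf(t, t_m: float, k: float):
    """Density of a segment's entry time: Gamma(shape k+1, rate k/t_m).

    Length-biased relative to the migration density (longer-ago migrants
    contribute proportionally more segments), with mean (k+1)/k * t_m.
    """
    _check_positive("t_m", t_m)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("time must be >= 0")
    out = stats.gamma.pdf(arr, a=k + 1.0, scale=t_m / k)
    return out if arr.ndim else float(out)


def migration_density(t, t_m: float, k: float, alpha: float = 0.03):
    """Migrant fraction per generation: alpha * Gamma(shape k, rate k/t_m).

    Integrates to ``alpha`` over t in [0, inf); the mean migration time
    is ``t_m``.
    """
    _check_positive("t_m", t_m)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("time must be >= 0")
    out = alpha * stats.gamma.pdf(arr, a=k, scale=t_m / k)
    return out if arr.ndim else float(out)


def ald_simple(l, t_m: float, A: float = 1.0, c: float = 0.0):
    """Weighted-LD decay under an instantaneous pulse: A exp(-t_m l) + c."""
    _check_positive("t_m", t_m)
    arr = _check_nonnegative_lengths(l)
    out = A * np.exp(-t_m * arr) + c
    return out if arr.ndim else float(out)


def ald_extended(l, t_m: float, k: float, A: float = 1.0, c: float = 0.0):
    """Weighted-LD decay under the extended pulse: A (1 + t_m l / k)^(-k) + c.

    Evaluated through ``log1p`` so the ``k -> inf`` exponential limit is
    reached without overflow.
    """
    _check_positive("t_m", t_m)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    arr = _check_nonnegative_lengths(l)
    out = A * np.exp(-k * np.log1p(t_m * arr / k)) + c
    return out if arr.ndim else float(out)


def ald_from_segment_density(
    pdf: Callable[[float], float],
    l,
    expected_segments: float = 1.0,
    genome_size: float = 1.0,
) -> np.ndarray | float:
    """Ancestry-LD curve from a segment-length density by quadrature.

    Computes ``E(K)/G * int_l^inf P(x) (x - l) dx``: the expected overlap
    of a random position pair at distance ``l`` with a single segment,
    scaled by segment density per Morgan.  For the extended-pulse Lomax
    density the result is proportional to ``(1 + t_m l / k)^(-k)``; at
    ``l = 0`` it reduces to ``E(K)/G`` times the mean segment length.
    """
    arr = _check_nonnegative_lengths(l)
    scale = expected_segments / genome_size

    def one(li: float) -> float:
        val, _err = integrate.quad(
            lambda x: pdf(x) * (x - li), li, np.inf, limit=200
        )
        if val < -1e-12:
            raise ValueError("segment density appears negative or non-integrable")
        return scale * val

    if arr.ndim == 0:
        return one(float(arr))
    return np.array([one(li) for li in arr])


def segment_density_from_ald(
    ald: Callable[[np.ndarray], np.ndarray],
    l,
    step: float = 1e-6,
    normalize_grid: np.ndarray | None = None,
) -> np.ndarray | float:
    """Segment-length density (up to scale) as the second derivative of ALD.

    Uses a central finite difference with spacing ``step`` (Morgan).  The
    ALD curve is the doubly integrated tail of the length density, so
    ``P(l) ~ D''(l)``.  If ``normalize_grid`` is given, the result is
    renormalized to integrate to one over that grid (trapezoid rule).

    A warning is logged when the difference produces materially negative
    values, the signature of a step too coarse for the curvature.
    """
    arr = np.asarray(l, dtype=float)
    lo = np.maximum(arr - step, 0.0)
    hi = arr + step
    d2 = (np.asarray(ald(lo)) - 2.0 * np.asarray(ald(arr)) + np.asarray(ald(hi))) / step**2
    mx = np.max(np.abs(d2)) if np.size(d2) else 0.0
    if mx > 0 and np.min(d2) < -1e-3 * mx:
        logger.warning(
            "second-difference of ALD curve is negative at some points; "
            "step=%g may be too coarse for the curvature", step
        )
    if normalize_grid is not None:
        grid = np.asarray(normalize_grid, dtype=float)
        vals = segment_density_from_ald(ald, grid, step=step)
        total = np.trapezoid(vals, grid)
        if total <= 0:
            raise ValueError("ALD second derivative does not normalize on this grid")
        d2 = d2 / total
    return d2 if arr.ndim else float(d2)


def effective_migration(m: Callable[[float], float], t: float) -> float:
    """Migration rate corrected for later replacement.

    ``m_e(t) = m(t) exp(-int_0^t m(s) ds)``: the density of the event
    that material entered at time ``t`` before sampling and no migrant
    material replaced it more recently.  For constant ``m`` this is the
    exponential last-migration density ``m exp(-m t)``.
    """
    if t < 0:
        raise ValueError("time must be >= 0")
    if t == 0:
        return float(m(0.0))
    total, _err = integrate.quad(m, 0.0, t, limit=200)
    return float(m(t)) * math.exp(-total)


def convert_duration(t_m: float, k: float) -> float:
    """Admixture duration t_d = 4 t_m / sqrt(k)."""
    _check_positive("t_m", t_m)
    _check_positive("k", k)
    return 4.0 * t_m / math.sqrt(k)


def convert_shape(t_m: float, t_d: float) -> float:
    """Gamma shape k = 16 t_m^2 / t_d^2 from a duration.

    Raises when ``t_d > 4 t_m``, which would imply k < 1 (more spread
    than the constant-migration limit permits).
    """
    _check_positive("t_m", t_m)
    _check_positive("t_d", t_d)
    if t_d > 4.0 * t_m:
        raise ValueError(
            f"t_d={t_d} exceeds 4*t_m={4.0 * t_m}; implied shape k < 1 is outside the model"
        )
    return 16.0 * t_m**2 / t_d**2


def generations_to_years(t: float, generation_time: float = 29.0) -> float:
    """Convert generations to years (default human generation time 29 y)."""
    if t < 0 or generation_time <= 0:
        raise ValueError("t must be >= 0 and generation_time > 0")
    return t * generation_time


def generations_to_ky(t: float, generation_time: float = 29.0) -> int:
    """Generations to thousand years, rounded to the nearest integer."""
    return round(generations_to_years(t, generation_time) / 1000.0)
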
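"""Synthetic admixture segments, ALD curves, and migration schedules.

Generates data under the extended-pulse model: entry times from the
length-biased Gamma(k+1, rate k/t_m) distribution, conditional segment
lengths from an exponential with rate equal to the time elapsed between
entry and sampling, ALD decay curves with optional Gaussian noise, and
discretized per-generation migration schedules suitable as pulse events
for coalescent simulators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .models import PulseParams, ALDModelParams, migration_density

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentSet",
    "MigrationSchedule",
    "draw_segment_times",
    "draw_segment_lengths",
    "simulate_segments",
    "simulate_ald_curve",
    "make_migration_schedule",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SegmentSet:
    """A collection of introgressed-segment lengths.

    Attributes
    ----------
    lengths:
        Segment genetic lengths in Morgan, all > 0.
    times:
        Optional per-segment entry times, generations before present;
        must all exceed ``sampling_time``.
    sampling_time:
        Generations before present at which the admixed population was
        sampled (0 = present-day sample).
    genome_size:
        Optional total genome map length G in Morgan.
    """

    lengths: np.ndarray
    times: np.ndarray | None = None
    sampling_time: float = 0.0
    genome_size: float | None = None

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.lengths.ndim != 1:
            raise ValueError("lengths must be one-dimensional")
        if np.any(self.lengths <= 0) or not np.all(np.isfinite(self.lengths)):
            raise ValueError("segment lengths must be finite and > 0")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != self.lengths.shape:
                raise ValueError("times must match lengths in shape")
            if np.any(self.times <= self.sampling_time):
                raise ValueError(
                    "all entry times must predate the sampling time"
                )

    @property
    def n(self) -> int:
        return self.lengths.size

    def __len__(self) -> int:
        return self.n


@dataclass
class MigrationSchedule:
    """Per-generation migrant fractions summing to the total fraction alpha."""

    generations: np.ndarray  # integer generations before present
    rates: np.ndarray        # migrant fraction per generation
    alpha: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=int)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.generations.shape != self.rates.shape:
            raise ValueError("generations and rates must match in shape")
        if np.any(self.rates < 0) or np.any(self.rates > 1):
            raise ValueError("migration rates must lie in [0, 1]")
        if abs(self.rates.sum() - self.alpha) > 1e-12:
            raise ValueError("rates must sum to alpha")


def draw_segment_times(n: int, params: PulseParams, seed=None) -> np.ndarray:
    """Draw ``n`` segment entry times from Gamma(shape k+1, rate k/t_m)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _rng(seed)
    return rng.gamma(shape=params.k + 1.0, scale=params.t_m / params.k, size=n)


def draw_segment_lengths(
    times: np.ndarray, sampling_time: float = 0.0, seed=None
) -> SegmentSet:
    """Draw one segment length per entry time.

    Conditional on entering ``T_i`` generations before present and being
    observed in a sample taken ``sampling_time`` generations before
    present, a segment's length is exponential with rate
    ``T_i - sampling_time`` (one expected crossover per Morgan per
    elapsed generation).
    """
    times = np.asarray(times, dtype=float)
    elapsed = times - sampling_time
    if np.any(elapsed <= 0):
        raise ValueError(
            "every entry time must exceed the sampling time; segments "
            "entering after sampling cannot be observed"
        )
    rng = _rng(seed)
    lengths = rng.exponential(scale=1.0 / elapsed)
    return SegmentSet(lengths=lengths, times=times, sampling_time=sampling_time)


def simulate_segments(
    n: int,
    params: PulseParams,
    sampling_time: float = 0.0,
    seed=None,
    condition_on_sampling: bool = False,
) -> SegmentSet:
    """Draw entry times and lengths in one step.

    With ``condition_on_sampling``, entry times that postdate the
    sampling time are rejection-resampled, i.e. the entry-time
    distribution is conditioned on the segment being present in the
    sample.  Without it, such draws raise (the default contract of
    :func:`draw_segment_lengths`).
    """
    rng = _rng(seed)
    times = draw_segment_times(n, params, rng)
    if condition_on_sampling:
        bad = times <= sampling_time
        while np.any(bad):
            times[bad] = draw_segment_times(int(bad.sum()), params, rng)
            bad = times <= sampling_time
    return draw_segment_lengths(times, sampling_time, rng)


def simulate_ald_curve(
    params: ALDModelParams,
    grid_cm: np.ndarray,
    noise_sd: float = 0.0,
    seed=None,
):
    """Synthetic weighted-LD decay curve on a grid of distances (cM).

    Evaluates the extended-pulse decay and adds i.i.d. Gaussian noise of
    standard deviation ``noise_sd``; a stand-in for weighted-LD output
    computed from genotype panels.  Returns an :class:`admixpulse.io.ALDCurve`.
    """
    from .io import ALDCurve  # local import to avoid cycle

    grid_cm = np.asarray(grid_cm, dtype=float)
    if grid_cm.ndim != 1 or np.any(np.diff(grid_cm) <= 0):
        raise ValueError("distance grid must be strictly increasing")
    values = params(grid_cm / 100.0)
    if noise_sd:
        values = values + _rng(seed).normal(0.0, noise_sd, size=grid_cm.size)
    return ALDCurve(distances_cm=grid_cm, values=values, d0=float(grid_cm[0]))


def make_migration_schedule(
    params: PulseParams,
    window: tuple[float, float] | None = None,
) -> MigrationSchedule:
    """Discretize the Gamma migration density onto integer generations.

    Rates at integer generations within ``window`` (default
    ``[t_m - t_d/2, t_m + t_d/2]``, clipped to >= 1) are proportional to
    the migration density and rescaled to sum exactly to ``alpha``.  A
    duration of one generation collapses the window to the single
    generation nearest ``t_m``, recovering the instantaneous pulse.  A
    window excluding more than 1% of the Gamma mass is logged as a
    warning (the default +-t_d/2 window covers about 95%).
    """
    t_m, k, alpha = params.t_m, params.k, params.alpha
    t_d = params.t_d
    if window is None:
        window = (t_m - t_d / 2.0, t_m + t_d / 2.0)
    lo = max(1.0, window[0])
    hi = max(lo, window[1])
    gens = np.arange(int(np.ceil(lo)), int(np.floor(hi)) + 1)
    if gens.size == 0:
        gens = np.array([max(1, round(t_m))])
    mass = stats.gamma.cdf(hi, a=k, scale=t_m / k) - stats.gamma.cdf(
        lo, a=k, scale=t_m / k
    )
    if mass < 0.99:
        logger.warning(
            "migration-schedule window [%g, %g] excludes %.1f%% of the "
            "migration density mass; rates renormalized to alpha=%g",
            lo, hi, 100 * (1 - mass), alpha,
        )
    weights = migration_density(gens.astype(float), t_m, k, alpha)
    if weights.sum() <= 0:
        # window in the far tail: fall back to uniform weights
        weights = np.ones_like(gens, dtype=float)
    rates = alpha * weights / weights.sum()
    return MigrationSchedule(generations=gens, rates=rates, alpha=alpha, window=(lo, hi))
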
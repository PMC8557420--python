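"""File formats and genetic-distance utilities.

Readers and writers for HapMap-style recombination maps, segment tables
(TSV), and two-column weighted-LD decay curves (ALDER-style text with
``#`` comment lines).  Genetic distances are centimorgan in every file
format and Morgan everywhere else in the package; the factor of 100 is
applied here and only here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SegmentSet, MigrationSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "RecombinationMap",
    "ALDCurve",
    "read_recombination_map",
    "assign_genetic_length",
    "filter_segments",
    "read_ald_curve",
    "write_ald_curve",
    "read_segments",
    "write_segments",
    "write_migration_schedule",
]


@dataclass
class RecombinationMap:
    """A cumulative genetic map: physical position (bp) -> map position (cM)."""

    positions_bp: np.ndarray
    map_cm: np.ndarray

    def __post_init__(self) -> None:
        self.positions_bp = np.asarray(self.positions_bp, dtype=float)
        self.map_cm = np.asarray(self.map_cm, dtype=float)
        if self.positions_bp.size < 2:
            raise ValueError("a recombination map needs at least two points")
        if np.any(np.diff(self.positions_bp) <= 0):
            raise ValueError("physical positions must be strictly increasing")
        if np.any(np.diff(self.map_cm) < 0):
            raise ValueError("cumulative map must be non-decreasing")

    @property
    def mean_rate_cm_per_mb(self) -> float:
        """Total cM over total Mb across the covered span."""
        span_mb = (self.positions_bp[-1] - self.positions_bp[0]) / 1e6
        return (self.map_cm[-1] - self.map_cm[0]) / span_mb

    def interpolate_cm(self, pos_bp) -> np.ndarray | float:
        """Map position (cM) at physical positions, clamped at map ends."""
        pos = np.asarray(pos_bp, dtype=float)
        if np.any(pos < self.positions_bp[0]) or np.any(pos > self.positions_bp[-1]):
            warnings.warn(
                "query outside the covered map span; clamping to map ends",
                stacklevel=2,
            )
        out = np.interp(pos, self.positions_bp, self.map_cm)
        return out if pos.ndim else float(out)


def read_recombination_map(path) -> RecombinationMap:
    """Read a HapMap-format genetic map.

    Whitespace-delimited text with a header line and columns
    position (bp), rate (cM/Mb), cumulative map (cM); an optional
    leading chromosome column is detected and ignored.  Malformed or
    non-monotone rows raise errors naming the offending line.
    """
    path = Path(path)
    rows: list[tuple[float, float, float]] = []
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) == 4:
                fields = fields[1:]  # leading chromosome column
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 or 4 columns, got {len(fields)}"
                )
            try:
                pos, rate, cum = (float(v) for v in fields)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-numeric value ({err})") from None
            if rate < 0:
                raise ValueError(f"{path}:{lineno}: negative recombination rate {rate}")
            if rows and pos <= rows[-1][0]:
                raise ValueError(f"{path}:{lineno}: positions not strictly increasing")
            if rows and cum < rows[-1][2]:
                raise ValueError(f"{path}:{lineno}: cumulative map decreases")
            rows.append((pos, rate, cum))
    if len(rows) < 2:
        raise ValueError(f"{path}: map needs at least two data rows")
    arr = np.array(rows)
    return RecombinationMap(positions_bp=arr[:, 0], map_cm=arr[:, 2])


def assign_genetic_length(
    start_bp: float,
    end_bp: float,
    rec_map: RecombinationMap | None = None,
    constant_rate_cm_per_mb: float | None = None,
) -> float:
    """Genetic length (Morgan) of a physical interval.

    Either interpolates a recombination map (difference of cumulative
    cM, clamped at the map ends) or applies a constant rate in cM/Mb.
    """
    if end_bp < start_bp:
        raise ValueError(f"inverted interval [{start_bp}, {end_bp}]")
    if (rec_map is None) == (constant_rate_cm_per_mb is None):
        raise ValueError("provide exactly one of rec_map or constant_rate_cm_per_mb")
    if rec_map is not None:
        cm = rec_map.interpolate_cm(end_bp) - rec_map.interpolate_cm(start_bp)
    else:
        cm = (end_bp - start_bp) / 1e6 * constant_rate_cm_per_mb
    return cm / 100.0


def filter_segments(segments: SegmentSet, min_cm: float, max_cm: float) -> SegmentSet:
    """Keep segments with length in [min_cm, max_cm] centimorgan.

    The numbers removed at each end are logged.  Standard cutoffs of
    0.05 and 1.2 cM exclude lengths where segment calling is unreliable.
    Note the fitters apply no truncation correction to the likelihood
    after cutoffs; estimates from heavily filtered data are biased.
    """
    if min_cm < 0 or max_cm <= min_cm:
        raise ValueError("require 0 <= min_cm < max_cm")
    cm = segments.lengths * 100.0
    keep = (cm >= min_cm) & (cm <= max_cm)
    n_below = int(np.sum(cm < min_cm))
    n_above = int(np.sum(cm > max_cm))
    logger.info(
        "segment filter [%g, %g] cM removed %d short and %d long of %d segments",
        min_cm, max_cm, n_below, n_above, segments.n,
    )
    if not np.any(keep):
        warnings.warn("all segments removed by length filter", stacklevel=2)
        return _empty_like(segments)
    return SegmentSet(
        lengths=segments.lengths[keep],
        times=None if segments.times is None else segments.times[keep],
        sampling_time=segments.sampling_time,
        genome_size=segments.genome_size,
    )


def _empty_like(segments: SegmentSet) -> SegmentSet:
    out = SegmentSet.__new__(SegmentSet)
    out.lengths = np.empty(0)
    out.times = None
    out.sampling_time = segments.sampling_time
    out.genome_size = segments.genome_size
    return out


@dataclass
class ALDCurve:
    """A weighted-LD decay curve on a grid of genetic distances (cM).

    ``d0`` is the minimum genetic distance retained; shorter-range LD is
    excluded because it may reflect incomplete lineage sorting rather
    than gene flow.
    """

    distances_cm: np.ndarray
    values: np.ndarray
    d0: float = 0.0

    def __post_init__(self) -> None:
        self.distances_cm = np.asarray(self.distances_cm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.distances_cm.shape != self.values.shape or self.distances_cm.ndim != 1:
            raise ValueError("distances and values must be matching 1-d arrays")
        order = np.argsort(self.distances_cm)
        self.distances_cm = self.distances_cm[order]
        self.values = self.values[order]
        if np.any(np.diff(self.distances_cm) <= 0):
            raise ValueError("distances must be distinct")
        if not (np.all(np.isfinite(self.distances_cm)) and np.all(np.isfinite(self.values))):
            raise ValueError("curve contains non-finite values")
        if self.distances_cm.size and self.distances_cm[0] < self.d0:
            raise ValueError("curve contains distances below d0")

    @property
    def n(self) -> int:
        return self.distances_cm.size

    def with_d0(self, d0: float) -> "ALDCurve":
        """Return a copy with points below ``d0`` (cM) removed."""
        keep = self.distances_cm >= d0
        if not np.any(keep):
            raise ValueError(f"no curve points at or beyond d0={d0} cM")
        return ALDCurve(self.distances_cm[keep], self.values[keep], d0=d0)


def read_ald_curve(path, d0: float = 0.05) -> ALDCurve:
    """Read a two-column (distance cM, weighted LD) text curve.

    Lines starting with ``#`` are ignored (ALDER-style headers); rows
    below ``d0`` are dropped; rows are sorted by distance.  Non-numeric
    rows raise an error naming the line.
    """
    path = Path(path)
    dist, vals = [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            try:
                d, v = float(fields[0]), float(fields[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric row {stripped!r}") from None
            dist.append(d)
            vals.append(v)
    dist_arr = np.array(dist)
    keep = dist_arr >= d0
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info("dropped %d curve points below d0=%g cM", n_dropped, d0)
    if not np.any(keep):
        raise ValueError(f"{path}: no curve points remain at or beyond d0={d0} cM")
    return ALDCurve(distances_cm=dist_arr[keep], values=np.array(vals)[keep], d0=d0)


def write_ald_curve(curve: ALDCurve, path) -> None:
    """Write a curve as two tab-separated columns with a ``#`` header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# weighted LD decay curve; d0={curve.d0} cM\n")
        fh.write("# distance_cM\tweighted_LD\n")
        for d, v in zip(curve.distances_cm, curve.values):
            fh.write(f"{float(d)!r}\t{float(v)!r}\n")


def write_segments(segments: SegmentSet, path) -> None:
    """Write a segment table as TSV (lengths in cM, times in generations).

    Physical coordinates, when present on the set, are 0-based
    half-open; this writer emits length_cM and optionally
    entry_time_gen.
    """
    path = Path(path)
    cols = {"length_cM": segments.lengths * 100.0}
    if segments.times is not None:
        cols["entry_time_gen"] = segments.times
    df = pd.DataFrame(cols)
    with path.open("w") as fh:
        fh.write(f"# sampling_time_gen={segments.sampling_time!r}\n")
        if segments.genome_size is not None:
            fh.write(f"# genome_size_morgan={segments.genome_size!r}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_segments(path) -> SegmentSet:
    """Read a segment TSV written by :func:`write_segments` (or compatible).

    Requires a ``length_cM`` column; ``entry_time_gen`` is optional.
    ``#`` lines may carry sampling-time and genome-size metadata.
    """
    path = Path(path)
    sampling_time = 0.0
    genome_size = None
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "sampling_time_gen=" in line:
                sampling_time = float(line.split("=", 1)[1])
            elif "genome_size_morgan=" in line:
                genome_size = float(line.split("=", 1)[1])
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if "length_cM" not in df.columns:
        raise ValueError(f"{path}: missing required column 'length_cM'")
    times = df["entry_time_gen"].to_numpy() if "entry_time_gen" in df.columns else None
    return SegmentSet(
        lengths=df["length_cM"].to_numpy() / 100.0,
        times=times,
        sampling_time=sampling_time,
        genome_size=genome_size,
    )


def write_migration_schedule(schedule: MigrationSchedule, path) -> None:
    """Write a per-generation migration schedule as TSV.

    Columns generation, migrant_fraction: directly consumable as
    per-generation pulse events by standard coalescent simulators.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# total_fraction={schedule.alpha!r} "
                 f"window=[{schedule.window[0]!r},{schedule.window[1]!r}]\n")
        fh.write("generation\tmigrant_fraction\n")
        for g, r in zip(schedule.generations, schedule.rates):
            fh.write(f"{int(g)}\t{float(r)!r}\n")
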
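"""Genomic window coordinate system.

The whole pipeline operates on a fixed grid of sliding windows: every
per-sample quantity (read count, normalized ratio, log2 fold change) is a
vector indexed by grid window.  This module builds the grid from a genome
layout, annotates GC content from a reference sequence, assigns chromosome
arms, and masks windows overlapping excluded regions (centromeres, telomeres,
repeats) or excluded chromosomes (sex chromosomes by default).

Coordinates are 0-based, half-open throughout, matching BED.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "WindowGrid",
    "RegionMask",
    "build_window_grid",
    "annotate_gc",
    "mask_windows",
    "read_layout",
    "read_arm_bed",
]

#: chromosomes masked out by default ("chr"-prefixed and bare names both match)
DEFAULT_EXCLUDED_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})

#: windows with more than this fraction of non-ACGT bases get an undefined GC
#: fraction and are masked
DEFAULT_MAX_AMBIGUOUS_FRACTION = 0.2


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths, centromere split coordinates, exclusions.

    Parameters
    ----------
    chromosomes:
        Ordered ``(name, length)`` pairs.  Only chromosomes listed here are
        ever windowed; mitochondrial and unplaced contigs should simply be
        left out.
    arm_boundaries:
        Map chromosome name -> centromere split coordinate in bp.  Windows
        whose midpoint lies left of the boundary are on the p arm.
    excluded_chromosomes:
        Chromosomes whose windows are masked wholesale (default: sex
        chromosomes).
    """

    chromosomes: tuple[tuple[str, int], ...]
    arm_boundaries: Mapping[str, int]
    excluded_chromosomes: frozenset[str] = DEFAULT_EXCLUDED_CHROMOSOMES

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            split = self.arm_boundaries.get(name)
            if split is not None and not (0 < split < length):
                raise ValueError(
                    f"arm boundary for {name} must lie strictly inside (0, {length})"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    def length_of(self, chromosome: str) -> int:
        for name, length in self.chromosomes:
            if name == chromosome:
                return length
        raise KeyError(chromosome)


@dataclass(frozen=True)
class RegionMask:
    """Excluded-region intervals (centromeres, telomeres, repeats...).

    Intervals are ``(chromosome, start, end, label)`` with 0-based half-open
    coordinates; overlaps between intervals are allowed.
    """

    intervals: tuple[tuple[str, int, int, str], ...] = ()

    def __post_init__(self) -> None:
        for chrom, start, end, _ in self.intervals:
            if start >= end:
                raise ValueError(f"empty mask interval {chrom}:{start}-{end}")

    @classmethod
    def from_bed(cls, path) -> "RegionMask":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                label = parts[3] if len(parts) > 3 else "other"
                rows.append((parts[0], int(parts[1]), int(parts[2]), label))
        return cls(tuple(rows))


@dataclass
class WindowGrid:
    """Ordered sliding windows over a :class:`GenomeLayout`.

    Window attributes are stored as parallel numpy arrays; ``masked`` windows
    are excluded from all downstream statistics but keep their slot so that
    per-sample vectors stay aligned with the grid.
    """

    layout: GenomeLayout
    window_size: int
    step: int
    chromosome: np.ndarray  # str array
    start: np.ndarray  # int64
    end: np.ndarray  # int64
    gc_fraction: np.ndarray  # float64, NaN = undefined
    arm: np.ndarray  # str array, 'p' or 'q'
    masked: np.ndarray  # bool

    @property
    def n_windows(self) -> int:
        return len(self.start)

    @property
    def unmasked(self) -> np.ndarray:
        return ~self.masked

    @property
    def n_unmasked(self) -> int:
        return int(self.unmasked.sum())

    def chromosome_indices(self, chromosome: str) -> np.ndarray:
        return np.flatnonzero(self.chromosome == chromosome)

    def arm_indices(self, chromosome: str, arm: str) -> np.ndarray:
        return np.flatnonzero((self.chromosome == chromosome) & (self.arm == arm))

    def copy(self) -> "WindowGrid":
        return WindowGrid(
            layout=self.layout,
            window_size=self.window_size,
            step=self.step,
            chromosome=self.chromosome.copy(),
            start=self.start.copy(),
            end=self.end.copy(),
            gc_fraction=self.gc_fraction.copy(),
            arm=self.arm.copy(),
            masked=self.masked.copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chromosome,
                "start": self.start,
                "end": self.end,
                "gc": self.gc_fraction,
                "arm": self.arm,
                "masked": self.masked.astype(int),
            }
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, layout: GenomeLayout, window_size: int, step: int) -> "WindowGrid":
        df = pd.read_csv(path, sep="\t")
        return cls(
            layout=layout,
            window_size=window_size,
            step=step,
            chromosome=df["chrom"].to_numpy(dtype=object),
            start=df["start"].to_numpy(dtype=np.int64),
            end=df["end"].to_numpy(dtype=np.int64),
            gc_fraction=df["gc"].to_numpy(dtype=float),
            arm=df["arm"].to_numpy(dtype=object),
            masked=df["masked"].to_numpy(dtype=bool),
        )


def build_window_grid(
    layout: GenomeLayout, window_size: int = 100_000, step: int = 50_000
) -> WindowGrid:
    """Tile every layout chromosome with fixed-size stepped windows.

    Windows start at 0, ``step``, ``2*step``, ...; a trailing remainder
    shorter than ``window_size`` is dropped so all windows are directly
    comparable for GC correction.  A window straddling the arm boundary is
    assigned the arm of its midpoint and masked (it overlaps the centromere
    region).  Chromosomes shorter than ``window_size`` contribute zero
    windows, with a warning.
    """
    if window_size <= 0 or step <= 0:
        raise ValueError("window_size and step must be positive")
    if step > window_size:
        raise ValueError("step must not exceed window_size")

    chroms: list[str] = []
    starts: list[np.ndarray] = []
    arms: list[np.ndarray] = []
    maskeds: list[np.ndarray] = []
    for name, length in layout.chromosomes:
        if length < window_size:
            warnings.warn(
                f"chromosome {name} (length {length}) is shorter than the "
                f"window size {window_size}; it contributes zero windows"
            )
            continue
        s = np.arange(0, length - window_size + 1, step, dtype=np.int64)
        e = s + window_size
        mid = s + window_size // 2
        split = layout.arm_boundaries.get(name)
        if split is None:
            arm = np.full(len(s), "q", dtype=object)
            straddle = np.zeros(len(s), dtype=bool)
        else:
            arm = np.where(mid < split, "p", "q").astype(object)
            straddle = (s < split) & (e > split)
        chroms.append(name)
        starts.append(s)
        arms.append(arm)
        maskeds.append(straddle)

    if starts:
        start = np.concatenate(starts)
        chromosome = np.concatenate(
            [np.full(len(s), c, dtype=object) for c, s in zip(chroms, starts)]
        )
        arm = np.concatenate(arms)
        masked = np.concatenate(maskeds)
    else:
        start = np.empty(0, dtype=np.int64)
        chromosome = np.empty(0, dtype=object)
        arm = np.empty(0, dtype=object)
        masked = np.empty(0, dtype=bool)

    return WindowGrid(
        layout=layout,
        window_size=window_size,
        step=step,
        chromosome=chromosome,
        start=start,
        end=start + window_size,
        gc_fraction=np.full(len(start), np.nan),
        arm=arm,
        masked=masked,
    )


def _gc_of_sequence(seq: str) -> tuple[float, float]:
    """Return (gc_fraction, ambiguous_fraction); gc is NaN when no ACGT base."""
    s = seq.upper()
    counts = {b: s.count(b) for b in "ACGT"}
    informative = sum(counts.values())
    amb = 1.0 - informative / len(s) if len(s) else 1.0
    if informative == 0:
        return float("nan"), amb
    return (counts["G"] + counts["C"]) / informative, amb


def annotate_gc(
    grid: WindowGrid,
    reference,
    max_ambiguous_fraction: float = DEFAULT_MAX_AMBIGUOUS_FRACTION,
) -> WindowGrid:
    """Annotate each window with its GC fraction from a reference sequence.

    ``reference`` may be a path to an indexed FASTA, an open
    :class:`pysam.FastaFile`, or a plain ``{chromosome: sequence}`` mapping
    (handy for tests).  GC is (G+C)/(A+C+G+T), case-insensitive; windows
    whose ambiguous-base fraction exceeds ``max_ambiguous_fraction`` get an
    undefined GC fraction and are masked.
    """
    if isinstance(reference, Mapping):
        fetch = lambda c, s, e: reference[c][s:e]  # noqa: E731
        has = lambda c: c in reference  # noqa: E731
    else:
        if isinstance(reference, (str, bytes)) or hasattr(reference, "__fspath__"):
            import pysam

            reference = pysam.FastaFile(str(reference))
        fetch = reference.fetch
        has = lambda c: c in reference.references  # noqa: E731

    for chrom in dict.fromkeys(grid.chromosome.tolist()):
        if not has(chrom):
            raise KeyError(f"chromosome {chrom!r} missing from the reference")

    out = grid.copy()
    for i in range(grid.n_windows):
        seq = fetch(grid.chromosome[i], int(grid.start[i]), int(grid.end[i]))
        gc, amb = _gc_of_sequence(seq)
        if amb > max_ambiguous_fraction or not np.isfinite(gc):
            out.gc_fraction[i] = np.nan
            out.masked[i] = True
        else:
            out.gc_fraction[i] = gc
    return out


def mask_windows(grid: WindowGrid, mask: RegionMask | None = None) -> WindowGrid:
    """Mask windows overlapping excluded regions or excluded chromosomes.

    A window is masked if it overlaps any mask interval by at least 1 bp or
    lies on an excluded chromosome.  Masking is monotone: already-masked
    windows stay masked.  Mask intervals on chromosomes absent from the grid
    are ignored with a warning.
    """
    out = grid.copy()
    known = set(dict.fromkeys(grid.chromosome.tolist()))
    if mask is not None:
        for chrom, istart, iend, _ in mask.intervals:
            if chrom not in known:
                warnings.warn(f"mask interval on unknown chromosome {chrom!r} ignored")
                continue
            idx = grid.chromosome == chrom
            overlap = idx & (grid.start < iend) & (grid.end > istart)
            out.masked |= overlap
    excluded = grid.layout.excluded_chromosomes
    if excluded:
        out.masked |= np.isin(grid.chromosome.astype(str), list(excluded))
    return out


def read_layout(path, excluded_chromosomes: Iterable[str] | None = None,
                arm_bed=None) -> GenomeLayout:
    """Read a layout from a two-column TSV (chrom, length), arms from BED.

    The arm BED carries two rows per chromosome labelled ``p`` and ``q`` in
    the name column; the arm boundary is the end of the p interval.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "length"], usecols=[0, 1])
    chroms = tuple((str(r.chrom), int(r.length)) for r in df.itertuples())
    boundaries: dict[str, int] = {}
    if arm_bed is not None:
        boundaries = read_arm_bed(arm_bed)
    excl = (
        frozenset(excluded_chromosomes)
        if excluded_chromosomes is not None
        else DEFAULT_EXCLUDED_CHROMOSOMES
    )
    return GenomeLayout(chroms, boundaries, excl)


def read_arm_bed(path) -> dict[str, int]:
    boundaries: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, name = line.split("\t")[:4]
            if name == "p":
                boundaries[chrom] = int(end)
    return boundaries
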
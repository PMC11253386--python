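"""Per-window read counting for shallow-WGS copy-number profiling.

A read is assigned to every grid window containing its leftmost aligned
position; with the default 100 kb / 50 kb stepped grid an interior read
therefore increments two windows.  Counting by leftmost position (rather than
by overlap length) is the standard convention for shallow-WGS CNV binning and
is unambiguous for overlapping windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import WindowGrid

__all__ = [
    "CoverageProfile",
    "EmptyProfileError",
    "count_reads",
    "downsample_counts",
    "read_count_table",
    "write_count_table",
]


class EmptyProfileError(RuntimeError):
    """Raised when counting yields zero accepted reads."""


@dataclass
class CoverageProfile:
    """Raw per-window read counts for one sample.

    ``counts`` is aligned with the grid (masked windows included);
    ``library_size`` is the sum of all window counts at counting time.
    """

    sample_id: str
    counts: np.ndarray  # int64, length == grid.n_windows
    library_size: int
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("negative read counts")


def _resolve_reference_name(chrom: str, references: set[str]) -> str | None:
    """Harmonize optional 'chr' prefixes between grid and alignment header."""
    if chrom in references:
        return chrom
    if chrom.startswith("chr") and chrom[3:] in references:
        return chrom[3:]
    if "chr" + chrom in references:
        return "chr" + chrom
    return None


def count_reads(
    alignment,
    grid: WindowGrid,
    min_mapq: int = 30,
    drop_duplicates: bool = True,
    sample_id: str | None = None,
) -> CoverageProfile:
    """Count accepted reads per grid window from a coordinate-sorted BAM.

    ``alignment`` is a path to an indexed BAM or an open
    :class:`pysam.AlignmentFile`.  Reads that are unmapped, secondary,
    supplementary, below ``min_mapq``, or duplicate (when
    ``drop_duplicates``) are excluded.  Each accepted read increments every
    window containing its leftmost aligned position.
    """
    import pysam

    close = False
    if not isinstance(alignment, pysam.AlignmentFile):
        alignment = pysam.AlignmentFile(str(alignment))
        close = True
    try:
        if not alignment.has_index():
            raise RuntimeError("alignment file must be coordinate-sorted and indexed")
        references = set(alignment.references)
        counts = np.zeros(grid.n_windows, dtype=np.int64)
        for chrom in dict.fromkeys(grid.chromosome.tolist()):
            ref = _resolve_reference_name(chrom, references)
            if ref is None:
                raise KeyError(f"grid chromosome {chrom!r} absent from alignment header")
            positions = []
            for read in alignment.fetch(ref):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if read.mapping_quality < min_mapq:
                    continue
                if drop_duplicates and read.is_duplicate:
                    continue
                positions.append(read.reference_start)
            if not positions:
                continue
            pos = np.sort(np.asarray(positions, dtype=np.int64))
            idx = grid.chromosome_indices(chrom)
            lo = np.searchsorted(pos, grid.start[idx], side="left")
            hi = np.searchsorted(pos, grid.end[idx], side="left")
            counts[idx] = hi - lo
    finally:
        if close:
            alignment.close()

    library_size = int(counts.sum())
    if library_size == 0:
        raise EmptyProfileError("empty profile: zero accepted reads")
    if sample_id is None:
        sample_id = "sample"
    return CoverageProfile(sample_id=sample_id, counts=counts, library_size=library_size)


def downsample_counts(
    profile: CoverageProfile, target_fraction: float, seed: int
) -> CoverageProfile:
    """Binomially thin window counts to emulate depth down-sampling.

    Each count is replaced by a Binomial(count, target_fraction) draw, the
    window-level equivalent of retaining each read independently with
    probability ``target_fraction``.  ``target_fraction == 1`` is the exact
    identity.
    """
    if not (0 < target_fraction <= 1):
        raise ValueError("target_fraction must be in (0, 1]")
    if target_fraction == 1.0:
        return CoverageProfile(profile.sample_id, profile.counts.copy(), profile.library_size)
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(profile.counts, target_fraction)
    return CoverageProfile(
        sample_id=profile.sample_id,
        counts=thinned,
        library_size=int(thinned.sum()),
    )


def write_count_table(profile: CoverageProfile, grid: WindowGrid, path) -> None:
    pd.DataFrame(
        {
            "chrom": grid.chromosome,
            "start": grid.start,
            "end": grid.end,
            "count": profile.counts,
        }
    ).to_csv(path, sep="\t", index=False)


def read_count_table(path, grid: WindowGrid, sample_id: str | None = None) -> CoverageProfile:
    """Read a per-window count TSV; its rows must match the grid exactly."""
    df = pd.read_csv(path, sep="\t")
    if len(df) != grid.n_windows:
        raise ValueError(
            f"count table has {len(df)} rows but the grid has {grid.n_windows} windows"
        )
    same = (
        (df["chrom"].to_numpy(dtype=object) == grid.chromosome)
        & (df["start"].to_numpy() == grid.start)
        & (df["end"].to_numpy() == grid.end)
    )
    if not same.all():
        i = int(np.flatnonzero(~same)[0])
        raise ValueError(
            "count table does not match grid; first discrepancy at row "
            f"{i}: table {df['chrom'][i]}:{df['start'][i]}-{df['end'][i]} vs "
            f"grid {grid.chromosome[i]}:{grid.start[i]}-{grid.end[i]}"
        )
    counts = df["count"].to_numpy(dtype=np.int64)
    if sample_id is None:
        sample_id = str(path)
    return CoverageProfile(sample_id=sample_id, counts=counts, library_size=int(counts.sum()))
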
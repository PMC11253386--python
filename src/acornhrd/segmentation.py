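"""Part two of the scoring algorithm: segmentation and LCNA counting.

The per-window CNV ratios are log2-transformed, de-overlapped (the stepped
grid is reduced to disjoint windows), segmented arm by arm with circular
binary segmentation (CBS), smoothed by merging near-identical neighbours, and
scanned for large-scale copy-number alteration (LCNA) events: copy-altered
segments longer than 10 Mb, bounded within chromosome arms.  The HRD score is
the genome-wide count of such events; scores >= 10 classify as HRD-high.

CBS here is the classic recursive procedure: over all arcs (i, j] of the
series, find the one maximizing the mean-shift statistic

    T(i, j) = |sum(x[i:j]) * n - k * sum(x)| / sqrt(k * (n - k)),  k = j - i,

which is the two-sample z statistic between the arc and its complement up to
a factor constant under permutation.  The best arc is accepted as a pair of
change-points when its permutation p-value is below ``alpha``; the procedure
recurses on the resulting pieces.  Permutations are evaluated in vectorized
chunks with sequential early stopping: a split is rejected as soon as the
exceedance count can no longer come in under ``alpha``, and accepted early
when the Clopper-Pearson upper bound on the p-value falls below ``alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .genome import WindowGrid
from .normalization import RatioProfile

__all__ = [
    "Segment",
    "SegmentSet",
    "HRDResult",
    "log2_transform",
    "deoverlap",
    "segment_arm",
    "segment_profile",
    "merge_segments",
    "recenter_segments",
    "call_lcna",
    "hrd_score",
    "classify_hrd",
]

DEFAULT_ALPHA = 0.01
DEFAULT_N_PERM = 1000
DEFAULT_MIN_WIDTH = 3
DEFAULT_MERGE_DELTA = 0.3
DEFAULT_ALT_THRESHOLD = 0.2
DEFAULT_LCNA_MIN_LENGTH = 10_000_000
DEFAULT_HRD_THRESHOLD = 10

_PERM_CHUNK = 100
_EARLY_ACCEPT_MIN = 300  # permutations before early acceptance is considered
_EARLY_ACCEPT_CONF = 0.99


@dataclass
class Segment:
    chromosome: str
    arm: str
    start: int
    end: int
    n_windows: int
    mean_log2: float
    altered: bool = False
    is_lcna: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentSet:
    sample_id: str
    segments: list[Segment]
    parameters: dict = field(default_factory=dict)

    def to_seg_rows(self) -> list[dict]:
        return [
            {
                "sample": self.sample_id,
                "chrom": s.chromosome,
                "arm": s.arm,
                "start": s.start,
                "end": s.end,
                "n_windows": s.n_windows,
                "mean_log2": s.mean_log2,
                "altered": int(s.altered),
                "is_lcna": int(s.is_lcna),
            }
            for s in self.segments
        ]


@dataclass
class HRDResult:
    sample_id: str
    hrd_score: int
    threshold: int
    status: str  # "high" | "low"


def log2_transform(profile: RatioProfile) -> RatioProfile:
    """log2 fold change of the CNV ratios."""
    if profile.stage != "cnv_ratio":
        raise ValueError("log2_transform expects a cnv_ratio profile")
    vals = profile.values
    bad = np.isfinite(vals) & (vals <= 0)
    if bad.any():
        raise ValueError("non-positive CNV ratio reached log2 transform (mask leak)")
    out = np.full_like(vals, np.nan)
    ok = np.isfinite(vals)
    out[ok] = np.log2(vals[ok])
    return profile._advance(out, "log2")


def deoverlap(profile: RatioProfile, grid: WindowGrid) -> RatioProfile:
    """Reduce the stepped grid to disjoint windows for segmentation.

    Keeps every (window_size / step)-th defined window per chromosome arm;
    consecutive kept windows are then at least one window size apart, hence
    genomically disjoint.  Identity when step == window_size.
    """
    if profile.stage != "log2":
        raise ValueError("deoverlap expects a log2 profile")
    if grid.window_size % grid.step != 0:
        raise ValueError("grid step must divide window size")
    r = grid.window_size // grid.step
    if r == 1:
        return RatioProfile(profile.sample_id, profile.values.copy(), "log2")
    keep = np.zeros(len(profile.values), dtype=bool)
    for chrom in dict.fromkeys(grid.chromosome.tolist()):
        for arm in ("p", "q"):
            idx = grid.arm_indices(chrom, arm)
            if len(idx) == 0:
                continue
            defined = idx[np.isfinite(profile.values[idx])]
            keep[defined[::r]] = True
    values = np.where(keep, profile.values, np.nan)
    return RatioProfile(profile.sample_id, values, "log2")


# ---------------------------------------------------------------------------
# CBS core


def _max_arc_stat(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Exhaustive max of the arc statistic; returns (stat, i, j) for arc (i, j]."""
    n = len(x)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    tot = cs[-1]
    best, bi, bj = -1.0, 0, n
    for k in range(min_width, n - min_width + 1):
        arc = cs[k:] - cs[:-k]
        stat = np.abs(arc * n - k * tot) / math.sqrt(k * (n - k))
        m = int(np.argmax(stat))
        if stat[m] > best:
            best, bi, bj = float(stat[m]), m, m + k
    return best, bi, bj


def _perm_max_stats(x: np.ndarray, n_chunk: int, min_width: int, rng) -> np.ndarray:
    """Max arc statistic for ``n_chunk`` random permutations of ``x``."""
    n = len(x)
    perms = rng.permuted(np.tile(x, (n_chunk, 1)), axis=1)
    cs = np.concatenate((np.zeros((n_chunk, 1)), np.cumsum(perms, axis=1)), axis=1)
    tot = cs[0, -1]  # permutation-invariant
    best = np.zeros(n_chunk)
    for k in range(min_width, n - min_width + 1):
        arc = cs[:, k:] - cs[:, :-k]
        cand = np.abs(arc * n - k * tot).max(axis=1) / math.sqrt(k * (n - k))
        np.maximum(best, cand, out=best)
    return best


def _split_significant(
    x: np.ndarray, obs: float, alpha: float, n_perm: int, min_width: int, rng
) -> bool:
    """Sequential permutation test of the observed max arc statistic."""
    if obs <= 0:
        return False
    reject_at = int(math.ceil(alpha * n_perm))  # exceedances making p >= alpha certain
    count = 0
    done = 0
    while done < n_perm:
        m = min(_PERM_CHUNK, n_perm - done)
        perm_max = _perm_max_stats(x, m, min_width, rng)
        count += int((perm_max >= obs - 1e-12).sum())
        done += m
        if count >= reject_at:
            return False
        if done >= _EARLY_ACCEPT_MIN:
            # Clopper-Pearson upper bound on the exceedance probability
            upper = sps.beta.ppf(_EARLY_ACCEPT_CONF, count + 1, done - count)
            if upper < alpha:
                return True
    return count / n_perm < alpha


def _cbs_breakpoints(
    x: np.ndarray, alpha: float, n_perm: int, min_width: int, rng
) -> list[int]:
    """Recursive CBS; returns sorted interior breakpoints of ``x``."""
    breaks: list[int] = []
    stack: list[tuple[int, int]] = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        n = hi - lo
        if n < 2 * min_width:
            continue
        seg = x[lo:hi]
        obs, i, j = _max_arc_stat(seg, min_width)
        if not _split_significant(seg, obs, alpha, n_perm, min_width, rng):
            continue
        # snap edge-hugging change-points so no piece is shorter than min_width
        if i < min_width:
            i = 0
        if n - j < min_width:
            j = n
        if i == 0 and j == n:
            continue
        pieces = []
        if i > 0:
            breaks.append(lo + i)
            pieces.append((lo, lo + i))
        if j < n:
            breaks.append(lo + j)
            pieces.append((lo + j, hi))
        pieces.append((lo + i, lo + j))
        # deterministic order: process leftmost piece first
        for piece in sorted(pieces, reverse=True):
            stack.append(piece)
    return sorted(breaks)


def _segments_from_breaks(
    chromosome: str,
    arm: str,
    values: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    breaks: list[int],
) -> list[Segment]:
    bounds = [0] + breaks + [len(values)]
    segs = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        segs.append(
            Segment(
                chromosome=chromosome,
                arm=arm,
                start=int(starts[lo]),
                end=int(ends[hi - 1]),
                n_windows=hi - lo,
                mean_log2=float(values[lo:hi].mean()),
            )
        )
    return segs


def segment_arm(
    values: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    chromosome: str = "chr1",
    arm: str = "p",
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    min_width: int = DEFAULT_MIN_WIDTH,
    seed: int = 0,
    sample_id: str = "sample",
) -> SegmentSet:
    """CBS on one chromosome arm's ordered window series."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if min_width < 2:
        raise ValueError("min_width must be >= 2")
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    breaks = _cbs_breakpoints(values, alpha, n_perm, min_width, rng)
    segs = _segments_from_breaks(chromosome, arm, values, np.asarray(starts), np.asarray(ends), breaks)
    params = {"alpha": alpha, "n_perm": n_perm, "min_width": min_width, "seed": seed}
    return SegmentSet(sample_id=sample_id, segments=segs, parameters=params)


def segment_profile(
    profile: RatioProfile,
    grid: WindowGrid,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    min_width: int = DEFAULT_MIN_WIDTH,
    seed: int = 0,
) -> SegmentSet:
    """Arm-wise CBS over a de-overlapped log2 profile.

    Arms are processed in grid order with one seeded generator, so a fixed
    seed yields an identical SegmentSet across runs.
    """
    if profile.stage != "log2":
        raise ValueError("segment_profile expects a log2 profile")
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    for chrom in dict.fromkeys(grid.chromosome.tolist()):
        for arm in ("p", "q"):
            idx = grid.arm_indices(chrom, arm)
            if len(idx) == 0:
                continue
            idx = idx[np.isfinite(profile.values[idx])]
            if len(idx) == 0:
                continue
            vals = profile.values[idx]
            breaks = _cbs_breakpoints(vals, alpha, n_perm, min_width, rng)
            segments.extend(
                _segments_from_breaks(chrom, arm, vals, grid.start[idx], grid.end[idx], breaks)
            )
    params = {"alpha": alpha, "n_perm": n_perm, "min_width": min_width, "seed": seed}
    return SegmentSet(sample_id=profile.sample_id, segments=segments, parameters=params)


def merge_segments(segset: SegmentSet, merge_delta: float = DEFAULT_MERGE_DELTA) -> SegmentSet:
    """Fuse adjacent same-arm segments whose levels differ by < merge_delta.

    The closest adjacent pair is fused first (window-count-weighted mean
    level), iterating to a fixpoint; re-running the merge is the identity.
    """
    merged: list[Segment] = []
    groups: dict[tuple[str, str], list[Segment]] = {}
    for s in segset.segments:
        groups.setdefault((s.chromosome, s.arm), []).append(s)
    for key in groups:
        segs = [replace(s) for s in groups[key]]
        while len(segs) > 1:
            deltas = [
                abs(segs[i].mean_log2 - segs[i + 1].mean_log2) for i in range(len(segs) - 1)
            ]
            i = int(np.argmin(deltas))
            if deltas[i] >= merge_delta:
                break
            a, b = segs[i], segs[i + 1]
            n = a.n_windows + b.n_windows
            segs[i : i + 2] = [
                Segment(
                    chromosome=a.chromosome,
                    arm=a.arm,
                    start=a.start,
                    end=b.end,
                    n_windows=n,
                    mean_log2=(a.mean_log2 * a.n_windows + b.mean_log2 * b.n_windows) / n,
                )
            ]
        merged.extend(segs)
    params = dict(segset.parameters, merge_delta=merge_delta)
    return SegmentSet(sample_id=segset.sample_id, segments=merged, parameters=params)


def recenter_segments(segset: SegmentSet, method: str = "median") -> SegmentSet:
    """Re-center segment levels so the copy-neutral state sits at log2 = 0.

    Library-size normalization pins the *mean* ratio at 1, so in aneuploid
    genomes the copy-neutral level drifts away from log2 = 0 by the log of
    the average ploidy change; with absolute-level LCNA calling that drift
    would miscount events.  Following common shallow-WGS practice the
    profile is re-anchored at the modal segment level, estimated as the
    median of per-segment mean levels (segments are predominantly neutral).
    ``method="none"`` disables re-centering.
    """
    if method == "none" or not segset.segments:
        return segset
    if method != "median":
        raise ValueError("method must be 'median' or 'none'")
    center = float(np.median([s.mean_log2 for s in segset.segments]))
    segs = [replace(s, mean_log2=s.mean_log2 - center) for s in segset.segments]
    params = dict(segset.parameters, recenter=method, recenter_shift=center)
    return SegmentSet(sample_id=segset.sample_id, segments=segs, parameters=params)


def call_lcna(
    segset: SegmentSet,
    alt_threshold: float = DEFAULT_ALT_THRESHOLD,
    lcna_min_length: int = DEFAULT_LCNA_MIN_LENGTH,
    mode: str = "altered",
) -> SegmentSet:
    """Flag large-scale copy-number alteration events.

    ``altered`` mode (default): a segment is copy-altered when
    |mean_log2| >= alt_threshold, and an LCNA event when additionally its
    genomic length is strictly greater than ``lcna_min_length``.

    ``breakpoint`` mode (classic large-scale state transition): an event is
    a level change of at least ``alt_threshold`` between two adjacent
    same-arm segments that are each longer than ``lcna_min_length``; the
    event is flagged on the left segment of the pair.
    """
    if mode not in ("altered", "breakpoint"):
        raise ValueError("mode must be 'altered' or 'breakpoint'")
    segs = [replace(s) for s in segset.segments]
    for s in segs:
        s.altered = abs(s.mean_log2) >= alt_threshold
        s.is_lcna = False
    if mode == "altered":
        for s in segs:
            s.is_lcna = s.altered and s.length > lcna_min_length
    else:
        for a, b in zip(segs[:-1], segs[1:]):
            if a.chromosome != b.chromosome or a.arm != b.arm:
                continue
            if (
                a.length > lcna_min_length
                and b.length > lcna_min_length
                and abs(a.mean_log2 - b.mean_log2) >= alt_threshold
            ):
                a.is_lcna = True
    params = dict(
        segset.parameters,
        alt_threshold=alt_threshold,
        lcna_min_length=lcna_min_length,
        lcna_mode=mode,
    )
    return SegmentSet(sample_id=segset.sample_id, segments=segs, parameters=params)


def hrd_score(segset: SegmentSet) -> HRDResult:
    """HRD score: the genome-wide count of LCNA events."""
    score = sum(1 for s in segset.segments if s.is_lcna)
    return HRDResult(
        sample_id=segset.sample_id,
        hrd_score=score,
        threshold=DEFAULT_HRD_THRESHOLD,
        status="unclassified",
    )


def classify_hrd(
    score: int, threshold: int = DEFAULT_HRD_THRESHOLD, sample_id: str = "sample"
) -> HRDResult:
    """HRD-high iff score >= threshold (boundary inclusive)."""
    if score < 0:
        raise ValueError("HRD score must be non-negative")
    status = "high" if score >= threshold else "low"
    return HRDResult(sample_id=sample_id, hrd_score=int(score), threshold=threshold, status=status)
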
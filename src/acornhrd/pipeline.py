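"""End-to-end convenience wrappers tying the pipeline stages together."""

from __future__ import annotations

from .config import RunConfig
from .coverage import CoverageProfile
from .genome import WindowGrid
from .normalization import (
    BaselineModel,
    build_baseline,
    cnv_ratio,
    gc_correct,
    normalize_library,
)
from .segmentation import (
    HRDResult,
    SegmentSet,
    call_lcna,
    classify_hrd,
    deoverlap,
    hrd_score,
    log2_transform,
    merge_segments,
    recenter_segments,
    segment_profile,
)

__all__ = ["baseline_from_counts", "score_sample"]


def baseline_from_counts(
    profiles: list[CoverageProfile],
    grid: WindowGrid,
    config: RunConfig | None = None,
) -> BaselineModel:
    """Library-normalize and GC-correct each control, then take medians."""
    config = config or RunConfig()
    corrected = [
        gc_correct(normalize_library(p, grid), grid, lowess_frac=config.lowess_frac)
        for p in profiles
    ]
    return build_baseline(corrected, low_signal_floor=config.low_signal_floor)


def score_sample(
    profile: CoverageProfile,
    baseline: BaselineModel,
    grid: WindowGrid,
    config: RunConfig | None = None,
) -> tuple[HRDResult, SegmentSet]:
    """Run the full scoring pipeline on one tumor coverage profile.

    Normalization -> GC correction -> CNV ratio against the baseline ->
    log2 -> de-overlap -> arm-wise CBS -> merge -> LCNA calling -> HRD
    score and high/low classification.
    """
    config = config or RunConfig()
    lib = normalize_library(profile, grid)
    corrected = gc_correct(lib, grid, lowess_frac=config.lowess_frac)
    ratios = cnv_ratio(corrected, baseline)
    logr = deoverlap(log2_transform(ratios), grid)
    segs = segment_profile(
        logr,
        grid,
        alpha=config.alpha,
        n_perm=config.n_perm,
        min_width=config.min_width,
        seed=config.seed,
    )
    segs = merge_segments(segs, merge_delta=config.merge_delta)
    segs = recenter_segments(segs, method=config.recenter)
    segs = call_lcna(
        segs,
        alt_threshold=config.alt_threshold,
        lcna_min_length=config.lcna_min_length,
        mode=config.lcna_mode,
    )
    score = hrd_score(segs).hrd_score
    result = classify_hrd(score, threshold=config.hrd_threshold, sample_id=profile.sample_id)
    return result, segs
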
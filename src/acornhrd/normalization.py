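"""Part one of the scoring algorithm: from raw window counts to CNV ratios.

Stages, in order:

1. ``libnorm`` — library-size normalization: each unmasked window count is
   divided by the mean unmasked count, so the profile's mean is exactly 1 and
   the result is invariant to sequencing depth.
2. ``gc_corrected`` — a LOWESS trend of the normalized value on window GC
   fraction is fitted and divided out (multiplicative correction); the
   corrected profile is rescaled so its median equals the pre-correction
   median, keeping copy-neutral at ~1.
3. ``cnv_ratio`` — the sample's GC-corrected value divided, window by window,
   by the panel-of-normals baseline median.  A diploid-identical sample gives
   ratios ~1 everywhere.

Masked windows carry NaN and are excluded from every statistic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .coverage import CoverageProfile
from .genome import WindowGrid

__all__ = [
    "RatioProfile",
    "BaselineModel",
    "normalize_library",
    "gc_correct",
    "build_baseline",
    "cnv_ratio",
]

STAGES = ("libnorm", "gc_corrected", "cnv_ratio", "log2")

#: baseline medians below this floor are flagged low-signal and excluded,
#: preventing ratio blow-ups in mappability deserts
DEFAULT_LOW_SIGNAL_FLOOR = 0.1

#: LOWESS fitted-trend values at or below this are treated as degenerate and
#: the affected windows are masked
TREND_EPSILON = 1e-2


@dataclass
class RatioProfile:
    """Per-window real values for one sample at a tagged pipeline stage."""

    sample_id: str
    values: np.ndarray  # float64, NaN on masked/undefined windows
    stage: str

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        self.values = np.asarray(self.values, dtype=float)

    def _advance(self, values: np.ndarray, stage: str) -> "RatioProfile":
        if STAGES.index(stage) <= STAGES.index(self.stage):
            raise ValueError(f"stage may only advance ({self.stage!r} -> {stage!r})")
        return RatioProfile(self.sample_id, values, stage)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class BaselineModel:
    """Panel-of-normals baseline: per-window median GC-corrected ratio."""

    median_ratio: np.ndarray  # float64, NaN where undefined
    n_samples: int
    low_signal_mask: np.ndarray  # bool
    low_signal_floor: float = DEFAULT_LOW_SIGNAL_FLOOR

    def write_tsv(self, grid: WindowGrid, path, sidecar: dict | None = None) -> None:
        pd.DataFrame(
            {
                "chrom": grid.chromosome,
                "start": grid.start,
                "end": grid.end,
                "median_ratio": self.median_ratio,
                "low_signal": self.low_signal_mask.astype(int),
            }
        ).to_csv(path, sep="\t", index=False)
        meta = {"n_samples": self.n_samples, "low_signal_floor": self.low_signal_floor}
        if sidecar:
            meta.update(sidecar)
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def read_tsv(cls, path) -> "BaselineModel":
        df = pd.read_csv(path, sep="\t")
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {"n_samples": 1, "low_signal_floor": DEFAULT_LOW_SIGNAL_FLOOR}
        return cls(
            median_ratio=df["median_ratio"].to_numpy(dtype=float),
            n_samples=int(meta["n_samples"]),
            low_signal_mask=df["low_signal"].to_numpy(dtype=bool),
            low_signal_floor=float(meta.get("low_signal_floor", DEFAULT_LOW_SIGNAL_FLOOR)),
        )


def normalize_library(profile: CoverageProfile, grid: WindowGrid) -> RatioProfile:
    """Divide each unmasked count by the mean unmasked count (mean -> 1)."""
    unmasked = grid.unmasked
    total = profile.counts[unmasked].sum()
    if total <= 0:
        raise ValueError("zero library size on unmasked windows")
    mean = total / unmasked.sum()
    values = np.full(grid.n_windows, np.nan)
    values[unmasked] = profile.counts[unmasked] / mean
    return RatioProfile(profile.sample_id, values, "libnorm")


def gc_correct(
    profile: RatioProfile,
    grid: WindowGrid,
    lowess_frac: float = 0.3,
    iterations: int = 3,
) -> RatioProfile:
    """Divide out the LOWESS trend of value on GC fraction.

    The corrected profile is rescaled so its median over defined windows
    equals the pre-correction median exactly.  Windows where the fitted
    trend is <= ``TREND_EPSILON`` become undefined (NaN).  If the GC spread
    is degenerate the correction is the identity, with a warning.
    """
    if profile.stage != "libnorm":
        raise ValueError("gc_correct expects a libnorm-stage profile")
    if not (0 < lowess_frac <= 1):
        raise ValueError("lowess_frac must be in (0, 1]")
    valid = profile.defined & np.isfinite(grid.gc_fraction)
    n_valid = int(valid.sum())
    if n_valid < 10:
        raise ValueError("too few windows with defined GC for correction")
    if n_valid < 100:
        warnings.warn("fewer than 100 GC-annotated windows; correction may be unstable")

    gc = grid.gc_fraction[valid]
    y = profile.values[valid]
    spread = gc.max() - gc.min()
    if spread < 1e-9:
        warnings.warn("degenerate GC spread; GC correction is the identity")
        return profile._advance(profile.values.copy(), "gc_corrected")

    fit = lowess(
        y,
        gc,
        frac=lowess_frac,
        it=iterations,
        delta=0.01 * spread,
        return_sorted=False,
    )
    corrected = np.full_like(profile.values, np.nan)
    good = fit > TREND_EPSILON
    corrected_vals = np.full(n_valid, np.nan)
    corrected_vals[good] = y[good] / fit[good]
    corrected[valid] = corrected_vals
    # exact median-preservation convention: copy-neutral stays at the same level
    med_before = np.median(y[good]) if good.any() else np.nan
    med_after = np.nanmedian(corrected)
    if np.isfinite(med_after) and med_after > 0:
        corrected *= med_before / med_after
    return profile._advance(corrected, "gc_corrected")


def build_baseline(
    profiles: list[RatioProfile],
    low_signal_floor: float = DEFAULT_LOW_SIGNAL_FLOOR,
) -> BaselineModel:
    """Per-window median of GC-corrected ratios across baseline samples."""
    if not profiles:
        raise ValueError("need at least one baseline profile")
    n = len(profiles[0].values)
    for p in profiles:
        if p.stage != "gc_corrected":
            raise ValueError("baseline profiles must be gc_corrected")
        if len(p.values) != n:
            raise ValueError("baseline profiles disagree on grid size")
    stack = np.vstack([p.values for p in profiles])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        median = np.nanmedian(stack, axis=0)
    low = ~np.isfinite(median) | (median < low_signal_floor)
    return BaselineModel(
        median_ratio=median,
        n_samples=len(profiles),
        low_signal_mask=low,
        low_signal_floor=low_signal_floor,
    )


def cnv_ratio(sample: RatioProfile, baseline: BaselineModel) -> RatioProfile:
    """Window-wise sample / baseline-median ratio (~1 when copy-neutral)."""
    if sample.stage != "gc_corrected":
        raise ValueError("cnv_ratio expects a gc_corrected profile")
    if len(sample.values) != len(baseline.median_ratio):
        raise ValueError("sample and baseline grids differ")
    values = np.full_like(sample.values, np.nan)
    ok = sample.defined & ~baseline.low_signal_mask
    values[ok] = sample.values[ok] / baseline.median_ratio[ok]
    return sample._advance(values, "cnv_ratio")
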
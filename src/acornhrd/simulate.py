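"""Synthetic shallow-WGS coverage with planted copy-number ground truth.

Every pipeline stage is testable without any sequencing data: the generator
emits per-window read counts for baseline panels and tumors on a toy genome,
with library-size variation, a smooth GC-bias curve, Poisson or
negative-binomial counting noise, tumor-purity dilution, and planted
copy-number segments of known length and level.  The expected HRD score of a
simulated tumor is pure geometry on the planted truth segments — independent
of the pipeline — so score-recovery tests are genuine round trips.

Default conditions emulate ~1x whole-genome sequencing on 100-kb windows
(about 600 read starts per window for ~150 bp reads) with a panel of 50
baseline controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import CoverageProfile
from .genome import GenomeLayout, WindowGrid, build_window_grid, mask_windows
from .segmentation import DEFAULT_ALT_THRESHOLD, DEFAULT_LCNA_MIN_LENGTH

__all__ = [
    "TruthSegment",
    "SimulationConfig",
    "toy_layout",
    "make_simulation_grid",
    "simulate_baseline_panel",
    "simulate_tumor",
    "plant_events",
    "simulate_cohort",
    "cohort_ii_event_counts",
]


def toy_layout(
    n_chromosomes: int = 2,
    chromosome_length: int = 120_000_000,
    arm_split: int = 60_000_000,
) -> GenomeLayout:
    """Small test genome: 2 chromosomes x 120 Mb with arms split at 60 Mb.

    Large enough to hold several >10 Mb events per arm, small enough for
    seconds-scale tests.  No excluded chromosomes.
    """
    chroms = tuple((f"chr{i + 1}", chromosome_length) for i in range(n_chromosomes))
    return GenomeLayout(chroms, {c: arm_split for c, _ in chroms}, frozenset())


@dataclass(frozen=True)
class TruthSegment:
    """A planted copy-number segment with known relative level."""

    chromosome: str
    arm: str
    start: int
    end: int
    copy_ratio: float  # e.g. 1.5 one-copy gain, 0.5 one-copy loss on diploid

    @property
    def length(self) -> int:
        return self.end - self.start

    def counts_toward_lcna(
        self,
        alt_threshold: float = DEFAULT_ALT_THRESHOLD,
        lcna_min_length: int = DEFAULT_LCNA_MIN_LENGTH,
    ) -> bool:
        return (
            abs(math.log2(self.copy_ratio)) >= alt_threshold
            and self.length > lcna_min_length
        )


@dataclass
class SimulationConfig:
    """Conditions of a simulated shallow-WGS experiment."""

    layout: GenomeLayout = field(default_factory=toy_layout)
    window_size: int = 100_000
    step: int = 50_000
    depth: float = 600.0  # mean read starts per window at copy-neutral (~1x WGS)
    gc_bias: tuple[float, float] = (1.0, -2.0)  # linear, quadratic coefficient
    gc_center: float = 0.45
    noise: str = "poisson"  # "poisson" | "nbinom"
    dispersion: float = 0.0  # NB2: var = mu + dispersion * mu^2
    purity: float = 1.0
    n_baseline: int = 50
    library_sigma: float = 0.15  # lognormal sd of per-sample library factor

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0 <= self.purity <= 1):
            raise ValueError("purity must be in [0, 1]")
        if self.noise not in ("poisson", "nbinom"):
            raise ValueError("noise must be 'poisson' or 'nbinom'")
        if self.noise == "nbinom" and self.dispersion <= 0:
            raise ValueError("negative-binomial noise needs dispersion > 0")


def make_simulation_grid(config: SimulationConfig, seed: int = 0) -> WindowGrid:
    """Build the window grid and attach a smooth synthetic GC landscape.

    GC varies sinusoidally along each chromosome (period ~30 Mb) with small
    window-level jitter, clipped to [0.30, 0.62] — a caricature of isochore
    structure sufficient to exercise the LOWESS correction.
    """
    grid = build_window_grid(config.layout, config.window_size, config.step)
    grid = mask_windows(grid)  # masks arm-straddling windows; no exclusions in toy
    rng = np.random.default_rng(seed)
    mid = (grid.start + grid.end) / 2
    gc = 0.42 + 0.06 * np.sin(2 * np.pi * mid / 3.0e7) + rng.normal(0, 0.01, grid.n_windows)
    grid.gc_fraction[:] = np.clip(gc, 0.30, 0.62)
    return grid


def _bias(gc: np.ndarray, config: SimulationConfig) -> np.ndarray:
    b1, b2 = config.gc_bias
    x = gc - config.gc_center
    return np.clip(1.0 + b1 * x + b2 * x**2, 0.05, None)


def _draw_counts(mu: np.ndarray, config: SimulationConfig, rng) -> np.ndarray:
    if config.noise == "poisson":
        return rng.poisson(mu)
    r = 1.0 / config.dispersion
    return rng.negative_binomial(r, r / (r + mu))


def _expected_baseline(grid: WindowGrid, config: SimulationConfig) -> np.ndarray:
    return config.depth * _bias(grid.gc_fraction, config)


def simulate_baseline_panel(
    config: SimulationConfig, grid: WindowGrid, seed: int = 0
) -> list[CoverageProfile]:
    """Simulate the panel of healthy diploid controls (purity ignored)."""
    if config.n_baseline < 1:
        raise ValueError("n_baseline must be >= 1")
    rng = np.random.default_rng(seed)
    mu0 = _expected_baseline(grid, config)
    panel = []
    for i in range(config.n_baseline):
        lib = math.exp(rng.normal(0, config.library_sigma))
        counts = _draw_counts(mu0 * lib, config, rng)
        panel.append(
            CoverageProfile(f"normal{i:03d}", counts, int(counts.sum()))
        )
    return panel


def _truth_multiplier(
    grid: WindowGrid, truth: list[TruthSegment], purity: float
) -> np.ndarray:
    ordered = sorted(truth, key=lambda t: (t.chromosome, t.start))
    for s, t in zip(ordered[:-1], ordered[1:]):
        if s.chromosome == t.chromosome and t.start < s.end:
            raise ValueError(
                f"overlapping truth segments on {s.chromosome}: "
                f"{s.start}-{s.end} and {t.start}-{t.end}"
            )
    mult = np.ones(grid.n_windows)
    mid = (grid.start + grid.end) / 2
    for t in truth:
        inside = (grid.chromosome == t.chromosome) & (mid >= t.start) & (mid < t.end)
        mult[inside] = purity * t.copy_ratio + (1 - purity)
    return mult


def simulate_tumor(
    config: SimulationConfig,
    grid: WindowGrid,
    truth: list[TruthSegment],
    seed: int = 0,
    sample_id: str = "tumor",
) -> tuple[CoverageProfile, int]:
    """Simulate a tumor with planted events; returns (profile, expected score).

    Expected per-window coverage is multiplied by
    ``purity * copy_ratio + (1 - purity)`` inside each truth segment.  The
    expected HRD score counts truth segments that are long enough (> 10 Mb)
    and far enough from copy-neutral — computed from the truth geometry
    alone, never from the pipeline.
    """
    rng = np.random.default_rng(seed)
    mu = _expected_baseline(grid, config) * _truth_multiplier(grid, truth, config.purity)
    lib = math.exp(rng.normal(0, config.library_sigma))
    counts = _draw_counts(mu * lib, config, rng)
    expected_score = sum(1 for t in truth if t.counts_toward_lcna())
    profile = CoverageProfile(sample_id, counts, int(counts.sum()))
    return profile, expected_score


def plant_events(
    layout: GenomeLayout,
    k: int,
    event_length: int = 15_000_000,
    copy_ratio: float = 1.5,
    margin: int = 2_000_000,
    seed: int = 0,
) -> list[TruthSegment]:
    """Place k non-overlapping events of fixed length across chromosome arms.

    Events are dealt round-robin over arms and spaced evenly within each arm
    (with a small seeded jitter), keeping a neutral buffer between events and
    away from arm boundaries so segmentation sees clean flanks.
    """
    rng = np.random.default_rng(seed)
    arms = []
    for chrom, length in layout.chromosomes:
        split = layout.arm_boundaries.get(chrom, length)
        arms.append((chrom, "p", 0, split))
        if split < length:
            arms.append((chrom, "q", split, length))
    per_arm = [0] * len(arms)
    for i in range(k):
        per_arm[i % len(arms)] += 1
    truth: list[TruthSegment] = []
    for (chrom, arm, lo, hi), m in zip(arms, per_arm):
        if m == 0:
            continue
        usable = hi - lo - 2 * margin
        gap = usable - m * event_length
        if gap < 0:
            raise ValueError(f"arm {chrom}{arm} cannot hold {m} events of {event_length} bp")
        spacing = gap // (m + 1)
        pos = lo + margin + spacing
        for _ in range(m):
            jitter = int(rng.integers(0, max(1, spacing // 4)))
            start = pos + jitter
            truth.append(TruthSegment(chrom, arm, start, start + event_length, copy_ratio))
            pos = start + event_length + spacing
    return truth


def cohort_ii_event_counts(n: int = 55, seed: int = 0) -> np.ndarray:
    """Event counts emulating a BRCA-mutated calibration cohort.

    Exactly two of the ``n`` samples fall below 10 events (drawn uniformly
    from 2..9); the rest sit at 10 plus a geometric tail (P(extra = 0) =
    0.25), so the cohort has ~96% of scores at or above 10 with the minimum
    of the high group at exactly 10 — the shape that puts the calibrated
    5%-agreement threshold at 10.
    """
    rng = np.random.default_rng(seed)
    low = rng.integers(2, 10, size=2)
    high = 10 + rng.geometric(0.25, size=n - 2) - 1
    counts = np.concatenate([low, high])
    rng.shuffle(counts)
    return counts


def simulate_cohort(
    config: SimulationConfig,
    groups: list[dict],
    seed: int = 0,
    with_profiles: bool = False,
) -> tuple[pd.DataFrame, dict[str, CoverageProfile]]:
    """Simulate an annotated cohort from per-group specifications.

    Each group dict carries ``name``, ``n``, an ``event_counts`` vector or
    callable ``rng -> int``, and optional label fields (``brca_status``,
    ``response_rate`` giving the per-sample probability of pCR,
    ``rcb01_rate``).  Returns a SampleAnnotation-style DataFrame (with the
    ground-truth event count as the expected HRD score) and, when
    ``with_profiles``, the simulated coverage profiles.
    """
    rng = np.random.default_rng(seed)
    grid = make_simulation_grid(config, seed=int(rng.integers(2**31))) if with_profiles else None
    rows = []
    profiles: dict[str, CoverageProfile] = {}
    idx = 0
    for group in groups:
        n = int(group["n"])
        spec = group.get("event_counts")
        if callable(spec):
            ks = [int(spec(rng)) for _ in range(n)]
        elif spec is not None:
            ks = [int(v) for v in spec]
            if len(ks) != n:
                raise ValueError(f"group {group.get('name')}: event_counts length != n")
        else:
            ks = [0] * n
        for k in ks:
            sample_id = f"s{idx:04d}"
            idx += 1
            row = {
                "sample_id": sample_id,
                "group": group.get("name", "group"),
                "true_event_count": k,
                "brca_status": group.get("brca_status", "unknown"),
            }
            for label, rate_key in (("response", "response_rate"), ("rcb_class", "rcb01_rate")):
                rate = group.get(rate_key)
                if rate is not None:
                    hit = rng.random() < rate
                    row[label] = (
                        ("pCR" if hit else "non-pCR")
                        if label == "response"
                        else ("RCB0/1" if hit else "RCB2/3")
                    )
                else:
                    row[label] = "unknown"
            if with_profiles:
                truth = plant_events(config.layout, k, seed=int(rng.integers(2**31)))
                profile, expected = simulate_tumor(
                    config, grid, truth, seed=int(rng.integers(2**31)), sample_id=sample_id
                )
                row["expected_hrd_score"] = expected
                profiles[sample_id] = profile
            rows.append(row)
    columns = [
        "sample_id", "group", "true_event_count", "brca_status", "response", "rcb_class",
    ] + (["expected_hrd_score"] if with_profiles else [])
    annotations = pd.DataFrame(rows, columns=columns)
    return annotations, profiles
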
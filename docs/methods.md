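# Methods

## Model and pipeline

The HRD score treats large-scale copy-number alteration (LCNA) as a genomic
scar of failed homologous recombination.  The quantity scored is the count,
over the whole genome, of copy-altered segments longer than 10 Mb, with
segments bounded within chromosome arms.  The design assumes: (i) ~1×
coverage is Poisson-like at 100-kb window granularity, so relative copy
number is measurable as a ratio of normalized window counts; (ii) GC bias is
a smooth function of window GC content shared within a sample and removable
by LOWESS; (iii) residual position-specific bias (mappability, ploidy of the
reference panel) is absorbed by dividing by the per-window median of a panel
of healthy controls.

Pipeline stages and their contracts:

1. **Window grid.** 0-based half-open windows of `window_size` stepped every
   `step`, trailing remainders dropped so all windows are the same length.
   Windows straddling the arm boundary are assigned the arm of their
   midpoint and masked.  Masking is monotone and masked windows never
   re-enter downstream statistics.
2. **Counting.** A read increments every window containing its leftmost
   aligned position; with the default half-overlapping grid an interior read
   is counted in two windows.  Down-sampling to a target depth is modeled as
   binomial thinning of window counts, which has the same distribution as
   read-level thinning at this granularity.
3. **Library normalization.** Counts are divided by the mean unmasked count,
   so the profile mean is exactly 1 and the result is invariant to
   sequencing depth.  (Any per-sample constant cancels in the CNV ratio, so
   the choice of mean-versus-total scaling is a convention, not a model
   decision.)
4. **GC correction.** The LOWESS trend of normalized value on GC fraction is
   divided out; the corrected profile is rescaled to preserve the
   pre-correction median exactly, keeping copy-neutral at ≈1.  Windows where
   the fitted trend collapses (≤ 0.01) are masked; a degenerate GC spread
   makes the correction an identity with a warning.
5. **CNV ratio.** Sample GC-corrected value divided by the panel median per
   window.  Panel medians below the low-signal floor (0.1) mask the window,
   preventing ratio blow-ups in coverage deserts.
6. **Segmentation.** log2 CNV ratios are first de-overlapped (every
   `window_size/step`-th defined window per arm, guaranteeing disjoint,
   serially-uncorrelated observations), then segmented per arm by circular
   binary segmentation: the arc (i, j] maximizing the two-sample mean-shift
   statistic |Δ|·√(k(n−k)) is accepted as a change-point pair when its
   permutation p-value is below `alpha`, recursing on the pieces.
7. **Merging and re-centering.** Adjacent segments whose levels differ by
   less than `merge_delta` are fused (closest pair first, to a fixpoint).
   The profile is then re-anchored at the modal copy-neutral level,
   estimated as the median of per-segment mean levels.  This step exists
   because normalization pins the *mean* ratio at 1: in strongly aneuploid
   genomes the copy-neutral level drifts off log2 = 0 by the log mean ploidy
   shift, and absolute-level event calling would miscount.  Median-of-
   segments is robust as long as most *segments* are neutral, which holds
   even when altered bases outnumber neutral bases; it fails for genomes
   where most segments are altered to a common level.
8. **Event calling and score.** A segment is copy-altered when
   |log2| ≥ `alt_threshold` and an LCNA event when additionally strictly
   longer than `lcna_min_length`.  The HRD score is the event count; scores
   ≥ `hrd_threshold` classify HRD-high (boundary inclusive).

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `window_size` / `step` | 100 kb / 50 kb | bp | operating point of the method; the mode-frequency sweep selects 100 kb as the most stable size |
| `min_mapq` | 30 | phred | conventional uniqueness filter; configurable |
| `lowess_frac` | 0.3 (3 robustifying iterations) | — | wide enough to be smooth in GC, narrow enough to track the bias curve |
| `low_signal_floor` | 0.1 | ratio | windows whose panel median falls below this are unreliable denominators |
| `alpha` / `n_perm` | 0.01 / 1000 | — | CBS split acceptance; 1000 permutations resolve p = 0.01 with early stopping in both directions |
| `min_width` | 3 | windows | shortest segment CBS may cut |
| `merge_delta` | 0.3 | log2 | shallow-coverage convention; below the one-copy step (0.58 at purity 1) and above segment-level noise |
| `alt_threshold` | 0.2 | log2 | neutral-vs-altered boundary; roughly a one-copy change at purity ≥ 40% |
| `lcna_min_length` | 10 Mb (strict >) | bp | LCNA definition |
| `hrd_threshold` | 10 | events | 5th percentile of calibration-cohort scores (≥95% positive agreement) |
| `lcna_mode` | `altered` | — | see below |
| `recenter` | `median` | — | modal-level re-anchoring (stage 7) |

**LCNA mode.**  Two readings of "a segment larger than 10 Mb is an event"
are implemented.  The default `altered` mode counts copy-altered segments
longer than 10 Mb.  The `breakpoint` mode counts level transitions flanked
by ≥10 Mb segments — the classic large-scale state transition (LST) — since
the score is explicitly LST-like.  The default is the more literal reading;
both are exposed and the choice is echoed in every report.

**Threshold calibration** uses the discrete operational form: the largest
integer t with fraction(scores ≥ t) ≥ target.  This reproduces
"5th-percentile" semantics exactly without interpolation ambiguity and is
verified against a brute-force scan in the tests.

**Association statistics.**  OR = ad/bc on 2×2 tables; 95% CI by the Woolf
log-OR normal approximation with z = 1.959964; Fisher's exact test when any
expected cell is below 5, Pearson chi-squared otherwise (both available
explicitly); zero cells trigger the Haldane–Anscombe 0.5 correction,
flagged in the result.

## Synthetic data

The generator emulates windowed ~1× WGS directly at count granularity:
expected count = depth × bias(gc) × library factor, with depth 600
reads/window by default (~1× with ~150-bp reads on 100-kb windows), a
quadratic GC-bias curve centered at GC 0.45, lognormal library-size factors
(σ = 0.15), Poisson or NB2 negative-binomial noise, and linear purity mixing
(purity·copy_ratio + 1 − purity) inside planted segments.  The toy layout is
2 chromosomes × 120 Mb with arms split at 60 Mb.  The expected HRD score of
a simulated tumor is computed from the truth geometry alone (length > 10 Mb
and |log2 copy_ratio| ≥ 0.2), never from the pipeline, so recovery tests are
genuine round trips.

The calibration-cohort generator emulates a 55-sample *BRCA*-mutated cohort
whose score distribution has exactly two samples below 10 and an atom at 10
(10 + geometric tail), i.e. 53/55 = 96.4% at or above the threshold — the
reported shape of such cohorts.

What the generator does **not** model: mappability structure, replication
timing, subclonality, FFPE artifacts, read-level sequence context, and
focal (<1 Mb) events.  Passing tests therefore demonstrate correctness of
the algorithmic chain under its stated assumptions, not performance on real
FFPE shallow-WGS libraries.

## Numerical and procedural choices

- CBS permutations run in vectorized chunks of 100 with sequential early
  stopping: a split is rejected as soon as exceedances reach ⌈α·n_perm⌉ and
  accepted early (after ≥300 permutations) when the Clopper–Pearson 99%
  upper bound on the exceedance probability falls below α.  Both rules are
  deterministic given the seed; arms are processed in grid order from one
  seeded generator, so a fixed seed reproduces the SegmentSet exactly.
- Change-points hugging a series edge (within `min_width`) are snapped to
  the edge, so no emitted segment is shorter than `min_width`.
- LOWESS uses statsmodels with `delta = 1% of the GC range` (linear
  interpolation between close GC values) for near-linear runtime.
- Merging fuses the closest adjacent pair first and iterates to a fixpoint,
  making the result order-independent and idempotent.
- Degenerate inputs: constant series yield a single segment (permutation
  p = 1); all-NaN arms are skipped; empty profiles, grid mismatches, and
  non-positive ratios reaching the log2 stage are fatal errors by contract.

## Problem sizes used in tests and the acceptance script

End-to-end recovery runs on the toy 2 × 120 Mb layout (4798 stepped windows,
~600 disjoint windows per arm) at depth 100 reads/window with a 50-sample
panel, k ∈ {0, 5, 12} planted 15-Mb events at copy ratio 1.5: 25 replicates
per k in the test suite, 8 per k in the acceptance script (the script's
smaller demo size; values are stable across seeds at both sizes).  CBS
operating characteristics use 200-window series: breakpoint recovery at
SNR 10 and a 100-replicate pure-noise false-split rate at α = 0.01.

## Known limitations

- No allele-specific copy number, LOH or telomeric allelic imbalance; the
  score is purely a total-copy-number scar count.
- No tumor purity or ploidy estimation; low purity shrinks log2 levels
  toward 0 and below `alt_threshold` the score collapses (at the default
  0.2, events at copy ratio 1.5 vanish below ~40% purity).
- Modal re-centering assumes most segments are copy-neutral; near-whole-
  genome duplication at a single level violates this.
- The mask (centromeres, telomeres, repeats) is user-supplied; no blacklist
  ships with the package beyond the synthetic toy layout.
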
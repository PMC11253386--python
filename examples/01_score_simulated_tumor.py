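"""Score a simulated tumor against a simulated panel of normals.

Builds a toy 2 x 120 Mb genome at ~1x-equivalent depth, simulates 50 healthy
controls and one tumor with five planted 15-Mb single-copy gains, then runs
the full pipeline: library/GC normalization, CNV ratio against the baseline
median, arm-wise CBS segmentation, and >10 Mb LCNA counting.
"""

from acornhrd import RunConfig, baseline_from_counts, score_sample
from acornhrd import simulate as sim

cfg = sim.SimulationConfig(depth=100.0, n_baseline=50)
grid = sim.make_simulation_grid(cfg, seed=0)
panel = sim.simulate_baseline_panel(cfg, grid, seed=1)
baseline = baseline_from_counts(panel, grid, RunConfig())

truth = sim.plant_events(cfg.layout, k=5, event_length=15_000_000, copy_ratio=1.5, seed=2)
tumor, expected = sim.simulate_tumor(cfg, grid, truth, seed=3)

result, segments = score_sample(tumor, baseline, grid, RunConfig())

print(f"planted events (ground truth): {expected}")
print(f"recovered HRD score:           {result.hrd_score}  -> status {result.status}")
print(f"segments called: {len(segments.segments)}")
for s in segments.segments:
    if s.is_lcna:
        print(f"  LCNA {s.chromosome}{s.arm} {s.start/1e6:.1f}-{s.end/1e6:.1f} Mb "
              f"log2 {s.mean_log2:+.2f}")
# The HRD score is the count of copy-altered segments longer than 10 Mb;
# scores >= 10 would classify the sample as HRD-high.
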
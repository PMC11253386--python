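import numpy as np
import pytest

from acornhrd import RunConfig, baseline_from_counts, cnv_ratio, gc_correct, normalize_library
from acornhrd import simulate as sim


def quiet_config(**kw):
    """No GC bias, no library variation: isolates the counting noise."""
    defaults = dict(
        layout=sim.toy_layout(1, 40_000_000, 20_000_000),
        depth=100.0,
        gc_bias=(0.0, 0.0),
        library_sigma=0.0,
        n_baseline=50,
    )
    defaults.update(kw)
    return sim.SimulationConfig(**defaults)


class TestBaselinePanel:
    def test_per_window_mean_within_3_se(self):
        cfg = quiet_config()
        grid = sim.make_simulation_grid(cfg, seed=0)
        panel = sim.simulate_baseline_panel(cfg, grid, seed=1)
        stack = np.vstack([p.counts for p in panel])
        grand_se = np.sqrt(100.0 / stack.size)
        assert abs(stack.mean() - 100.0) < 3 * grand_se
        window_se = np.sqrt(100.0 / 50)
        assert (np.abs(stack.mean(axis=0) - 100.0) < 5 * window_se).mean() > 0.99

    def test_seeded_reproducibility(self):
        cfg = quiet_config(n_baseline=3)
        grid = sim.make_simulation_grid(cfg, seed=0)
        a = sim.simulate_baseline_panel(cfg, grid, seed=9)
        b = sim.simulate_baseline_panel(cfg, grid, seed=9)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.counts, pb.counts)

    def test_purity_is_ignored_for_baseline(self):
        grid = sim.make_simulation_grid(quiet_config(), seed=0)
        a = sim.simulate_baseline_panel(quiet_config(n_baseline=2, purity=1.0), grid, seed=4)
        b = sim.simulate_baseline_panel(quiet_config(n_baseline=2, purity=0.3), grid, seed=4)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.counts, pb.counts)


class TestNoiseModels:
    def test_poisson_variance_to_mean_near_one(self):
        cfg = quiet_config(n_baseline=20)
        grid = sim.make_simulation_grid(cfg, seed=0)
        stack = np.vstack([p.counts for p in sim.simulate_baseline_panel(cfg, grid, seed=2)])
        ratio = (stack.var(axis=0, ddof=1) / stack.mean(axis=0)).mean()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_negative_binomial_overdispersion(self):
        disp = 0.02
        cfg = quiet_config(n_baseline=40, noise="nbinom", dispersion=disp)
        grid = sim.make_simulation_grid(cfg, seed=0)
        stack = np.vstack([p.counts for p in sim.simulate_baseline_panel(cfg, grid, seed=3)])
        ratio = (stack.var(axis=0, ddof=1) / stack.mean(axis=0)).mean()
        assert ratio == pytest.approx(1.0 + 100.0 * disp, rel=0.15)

    def test_nbinom_requires_dispersion(self):
        with pytest.raises(ValueError):
            quiet_config(noise="nbinom", dispersion=0.0)


class TestGcBias:
    def test_planted_bias_has_planted_sign_then_vanishes(self):
        cfg = sim.SimulationConfig(
            layout=sim.toy_layout(1, 40_000_000, 20_000_000),
            depth=200.0,
            gc_bias=(1.5, 0.0),
            library_sigma=0.0,
            n_baseline=1,
        )
        grid = sim.make_simulation_grid(cfg, seed=5)
        profile = sim.simulate_baseline_panel(cfg, grid, seed=6)[0]
        ok = grid.unmasked
        before = np.corrcoef(profile.counts[ok], grid.gc_fraction[ok])[0, 1]
        assert before > 0.3
        corrected = gc_correct(normalize_library(profile, grid), grid)
        good = np.isfinite(corrected.values)
        after = np.corrcoef(corrected.values[good], grid.gc_fraction[good])[0, 1]
        assert abs(after) < 0.05


class TestTumor:
    def test_expected_score_is_pure_geometry(self):
        layout = sim.toy_layout()
        events = [
            sim.TruthSegment("chr1", "p", 1_000_000, 9_000_000, 1.5),    # 8 Mb: too short
            sim.TruthSegment("chr1", "q", 61_000_000, 73_000_000, 1.5),  # 12 Mb: counts
            sim.TruthSegment("chr2", "p", 1_000_000, 16_000_000, 1.1),   # near-neutral level
        ]
        expected = sum(t.counts_toward_lcna() for t in events)
        assert expected == 1
        cfg = quiet_config(layout=layout)
        grid = sim.make_simulation_grid(cfg, seed=0)
        _, score = sim.simulate_tumor(cfg, grid, events, seed=1)
        assert score == expected

    def test_overlapping_truth_fatal(self):
        cfg = quiet_config()
        grid = sim.make_simulation_grid(cfg, seed=0)
        events = [
            sim.TruthSegment("chr1", "p", 1_000_000, 12_000_000, 1.5),
            sim.TruthSegment("chr1", "p", 11_000_000, 19_000_000, 0.5),
        ]
        with pytest.raises(ValueError, match="overlap"):
            sim.simulate_tumor(cfg, grid, events, seed=1)

    def test_purity_dilutes_signal(self):
        cfg_pure = quiet_config(purity=1.0)
        cfg_half = quiet_config(purity=0.5)
        grid = sim.make_simulation_grid(cfg_pure, seed=0)
        event = [sim.TruthSegment("chr1", "p", 2_000_000, 14_000_000, 1.5)]
        mid = (grid.start + grid.end) / 2
        inside = (mid >= 2_000_000) & (mid < 14_000_000)
        pure, _ = sim.simulate_tumor(cfg_pure, grid, event, seed=7)
        half, _ = sim.simulate_tumor(cfg_half, grid, event, seed=7)
        lift_pure = pure.counts[inside].mean() / pure.counts[~inside].mean()
        lift_half = half.counts[inside].mean() / half.counts[~inside].mean()
        assert lift_pure == pytest.approx(1.5, abs=0.03)
        assert lift_half == pytest.approx(1.25, abs=0.03)

    def test_plant_events_are_disjoint_and_sized(self):
        layout = sim.toy_layout()
        truth = sim.plant_events(layout, 12, event_length=15_000_000, seed=3)
        assert len(truth) == 12
        assert all(t.length == 15_000_000 for t in truth)
        by_chrom: dict = {}
        for t in sorted(truth, key=lambda t: (t.chromosome, t.start)):
            prev = by_chrom.get(t.chromosome)
            if prev is not None:
                assert t.start >= prev
            by_chrom[t.chromosome] = t.end


class TestCohort:
    def test_cohort_ii_shape(self):
        counts = sim.cohort_ii_event_counts(55, seed=4)
        assert len(counts) == 55
        assert (counts < 10).sum() == 2
        assert counts[counts >= 10].min() == 10

    def test_empty_groups(self):
        ann, profiles = sim.simulate_cohort(quiet_config(), [], seed=0)
        assert ann.empty and not profiles

    def test_annotations_shape_and_labels(self):
        groups = [
            {"name": "mut", "n": 5, "event_counts": [12] * 5, "brca_status": "mutated",
             "response_rate": 1.0},
            {"name": "wt", "n": 4, "event_counts": [0] * 4, "brca_status": "non-mutated",
             "response_rate": 0.0},
        ]
        ann, _ = sim.simulate_cohort(quiet_config(), groups, seed=1)
        assert len(ann) == 9
        assert (ann.loc[ann.group == "mut", "response"] == "pCR").all()
        assert (ann.loc[ann.group == "wt", "response"] == "non-pCR").all()

    def test_null_groups_or_ci_covers_one(self):
        """Two groups with identical response distributions: the OR interval
        should cover 1.0 in most replicates."""
        from acornhrd.stats import ContingencyTable, association

        covered = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            a_hit = rng.random(30) < 0.5
            b_hit = rng.random(30) < 0.5
            table = ContingencyTable(
                int(a_hit.sum()), int((~a_hit).sum()), int(b_hit.sum()), int((~b_hit).sum())
            )
            result = association(table)
            if result.ci_low <= 1.0 <= result.ci_high:
                covered += 1
        assert covered >= 0.9 * n_rep


def test_full_pipeline_recovers_planted_events(tiny_config, tiny_grid, tiny_baseline):
    """Round trip: planted events in, HRD score out (small single-chromosome toy)."""
    from acornhrd import score_sample

    truth = sim.plant_events(tiny_config.layout, 2, event_length=12_000_000, seed=21)
    tumor, expected = sim.simulate_tumor(tiny_config, tiny_grid, truth, seed=22)
    result, _ = score_sample(tumor, tiny_baseline, tiny_grid, RunConfig())
    assert abs(result.hrd_score - expected) <= 1
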
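"""Intensity measurement, background correction, summaries, t-test, interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoquant import quantification as quant
from glycoquant.quantification import (
    BackgroundModel,
    ConditionSummary,
    compare_groups_ttest,
    estimate_background,
    interpolate_timecourse,
    measure_compartments,
    subtract_background,
    summarize_conditions,
)
from glycoquant.segmentation import CompartmentMasks, segment_field


def _toy_masks():
    """One 4x4 cell: 4 nucleus px, 6 pm px, rest cytoplasm."""
    cell = np.zeros((6, 6), dtype=np.int32)
    cell[1:5, 1:5] = 1
    nucleus = np.zeros_like(cell)
    nucleus[2:4, 2:4] = 1
    pm = np.zeros_like(cell, dtype=bool)
    pm[1, 1:5] = True
    pm[4, 1:3] = True
    cyto = (cell > 0) & ~pm & (nucleus == 0)
    return CompartmentMasks(cell, nucleus, pm, cyto)


class TestMeasureCompartments:
    def test_hand_mean(self):
        masks = _toy_masks()
        probe = np.zeros((6, 6))
        probe[2:4, 2:4] = [[1, 2], [3, 4]]
        recs = {r.compartment: r for r in measure_compartments(probe, masks)}
        assert recs["nucleus"].mean_intensity == pytest.approx(2.5)
        assert recs["nucleus"].area == 4

    def test_conservation_identity_per_cell(self, noisy_scene):
        masks = segment_field(noisy_scene.channels)
        probe = noisy_scene.channels["probe"]
        recs = measure_compartments(probe, masks)
        for k in masks.labels():
            by_comp = {r.compartment: r for r in recs if r.cell_id == k}
            parts = sum(by_comp[c].mean_intensity * by_comp[c].area for c in ("pm", "cytoplasm", "nucleus"))
            whole = by_comp["whole_cell"]
            assert parts == pytest.approx(whole.mean_intensity * whole.area, rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_means_match_per_pixel_loop(self, seed):
        rng = np.random.default_rng(seed)
        probe = rng.uniform(0, 100, (12, 12))
        cell = np.zeros((12, 12), dtype=np.int32)
        cell[2:10, 2:10] = 1
        nucleus = np.zeros_like(cell)
        nucleus[4:8, 4:8] = 1
        pm = np.zeros_like(cell, dtype=bool)
        pm[2, 2:10] = pm[9, 2:10] = True
        cyto = (cell > 0) & ~pm & (nucleus == 0)
        masks = CompartmentMasks(cell, nucleus, pm, cyto)
        recs = {r.compartment: r for r in measure_compartments(probe, masks)}
        for comp, mask in (("pm", pm), ("nucleus", nucleus == 1), ("cytoplasm", cyto)):
            total, n = 0.0, 0
            for i in range(12):
                for j in range(12):
                    if mask[i, j]:
                        total += probe[i, j]
                        n += 1
            assert recs[comp].mean_intensity == pytest.approx(total / n, rel=1e-13)

    def test_empty_compartment_skipped_with_warning(self):
        masks = _toy_masks()
        masks.cytoplasm_mask[:] = False
        with pytest.warns(UserWarning, match="cytoplasm"):
            recs = measure_compartments(np.ones((6, 6)), masks)
        assert not any(r.compartment == "cytoplasm" for r in recs)


class TestBackground:
    def test_uniform_untreated_field(self):
        masks = _toy_masks()
        assert estimate_background([(np.full((6, 6), 7.0), masks)]).background == pytest.approx(7.0)

    def test_pooled_mean_over_fields(self):
        masks = _toy_masks()
        model = estimate_background([(np.full((6, 6), 4.0), masks), (np.full((6, 6), 8.0), masks)])
        assert model.background == pytest.approx(6.0)

    def test_no_untreated_fields_warns_and_zeroes(self, caplog):
        with caplog.at_level("WARNING"):
            model = estimate_background([])
        assert model.background == 0.0
        assert "untreated" in caplog.text

    def test_subtract_identity_and_shift(self):
        masks = _toy_masks()
        recs = measure_compartments(np.full((6, 6), 10.0), masks)
        assert subtract_background(recs, BackgroundModel(0.0))[0].mean_intensity == 10.0
        assert subtract_background(recs, BackgroundModel(3.0))[0].mean_intensity == pytest.approx(7.0)

    def test_untreated_scene_background_recovered_and_centered(self, small_spec):
        """On a noisy untreated scene the estimate lands near the configured
        background and corrected per-cell means center at 0 within SE."""
        from glycoquant import simgen

        scene = simgen.generate_scene(small_spec, condition="untreated")
        masks = segment_field(scene.channels)
        model = estimate_background([(scene.channels["probe"], masks)])
        assert model.background == pytest.approx(small_spec.background_level, abs=0.5)
        recs = subtract_background(
            measure_compartments(scene.channels["probe"], masks), model
        )
        whole = [r.mean_intensity for r in recs if r.compartment == "whole_cell"]
        se = np.std(whole, ddof=1) / np.sqrt(len(whole))
        assert abs(np.mean(whole)) <= max(3 * se, 1e-9)


class TestSummaries:
    def test_hand_summary(self):
        masks = _toy_masks()
        recs = []
        for v in (2.0, 4.0, 6.0):
            r = measure_compartments(np.full((6, 6), v), masks)[0]
            recs.append(r)
        (s,) = summarize_conditions(recs, grouping=("compartment",))
        assert (s.n_cells, s.mean, s.sd) == (3, 4.0, pytest.approx(2.0))
        assert s.se == pytest.approx(2.0 / np.sqrt(3))

    def test_single_record_flagged(self):
        masks = _toy_masks()
        recs = measure_compartments(np.full((6, 6), 5.0), masks)[:1]
        (s,) = summarize_conditions(recs, grouping=("compartment",))
        assert s.degenerate and s.sd == 0.0 and s.mean == 5.0

    def test_compartment_ordering_recovered(self, noisy_scene):
        """Nucleus > cytoplasm > membrane band, as configured in the generator."""
        masks = segment_field(noisy_scene.channels)
        recs = measure_compartments(noisy_scene.channels["probe"], masks)
        means = {s.group["compartment"]: s.mean for s in summarize_conditions(recs, grouping=("compartment",))}
        assert means["nucleus"] > means["cytoplasm"] > means["pm"]


class TestTTest:
    def test_identical_groups_symmetric(self):
        res = compare_groups_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "greater")
        assert res.t == 0.0 and res.p_value == pytest.approx(0.5)

    def test_clear_separation(self):
        res = compare_groups_ttest([11.0, 12.0, 13.0], [1.0, 2.0, 3.0], "greater")
        assert res.p_value < 0.001

    def test_zero_pooled_variance_degenerate(self):
        res = compare_groups_ttest([5.0, 5.0], [3.0, 3.0], "greater")
        assert res.degenerate and res.p_value == 0.0
        res = compare_groups_ttest([3.0, 3.0], [5.0, 5.0], "greater")
        assert res.degenerate and res.p_value == 1.0

    def test_type_i_error_calibrated(self):
        """Null rejection rate at alpha=0.05 stays in [0.035, 0.065]."""
        rng = np.random.default_rng(17)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            a, b = rng.normal(size=20), rng.normal(size=20)
            if compare_groups_ttest(a, b, "greater").p_value < 0.05:
                rejections += 1
        assert 0.035 <= rejections / reps <= 0.065


class TestInterpolation:
    def _summary(self, t, mean):
        return ConditionSummary(group={"time_min": t}, n_cells=5, mean=mean, sd=1.0, se=0.5)

    def test_midpoint_and_knot_identity(self):
        curve = interpolate_timecourse([self._summary(0, 0.0), self._summary(10, 10.0)])
        assert curve(5.0) == pytest.approx(5.0)
        assert curve(10.0) == 10.0

    def test_no_extrapolation(self):
        curve = interpolate_timecourse([self._summary(0, 0.0), self._summary(10, 10.0)])
        with pytest.raises(ValueError, match="outside"):
            curve(11.0)

    def test_duplicate_times_averaged(self):
        curve = interpolate_timecourse(
            [self._summary(0, 2.0), self._summary(0, 4.0), self._summary(10, 10.0)]
        )
        assert curve(0.0) == pytest.approx(3.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 100), min_size=2, max_size=6, unique=True))
    def test_curve_monotone_between_knots_for_monotone_means(self, increments):
        times = sorted(increments)
        means = np.cumsum(np.abs(times))  # monotone non-decreasing
        curve = interpolate_timecourse([self._summary(t, m) for t, m in zip(times, means)])
        q = np.linspace(times[0], times[-1], 50)
        vals = curve(q)
        assert (np.diff(vals) >= -1e-9).all()
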
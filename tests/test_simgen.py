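"""Generator correctness: geometry, noise model, ground-truth consistency."""

import math

import numpy as np
import pytest

from glycoquant import simgen
from glycoquant.simgen import (
    FieldSpec,
    GelLaneSpec,
    GelSpec,
    NoiseParams,
    SubcompartmentSpec,
    apply_noise,
    generate_gel,
    generate_time_course,
    render_scene,
    sample_cell_layout,
)


class TestCellLayout:
    def test_zero_cells_gives_empty_geometry(self, small_spec):
        from dataclasses import replace

        geom = sample_cell_layout(replace(small_spec, n_cells=0))
        assert geom.cells == []

    def test_deterministic_for_fixed_seed(self, small_spec):
        a = sample_cell_layout(small_spec)
        b = sample_cell_layout(small_spec)
        assert [c.center for c in a.cells] == [c.center for c in b.cells]
        assert [c.foci for c in a.cells] == [c.foci for c in b.cells]

    def test_nine_cells_pairwise_nonoverlapping_bruteforce(self):
        spec = FieldSpec(n_cells=9, cell_radius_range=(20.0, 30.0), seed=7)
        cells = sample_cell_layout(spec).cells
        assert len(cells) == 9
        for i in range(9):
            for j in range(i + 1, 9):
                ci, cj = cells[i], cells[j]
                d = math.hypot(ci.center[0] - cj.center[0], ci.center[1] - cj.center[1])
                assert d > max(ci.radii) + max(cj.radii)

    def test_nuclei_and_foci_contained(self, small_spec):
        for cell in sample_cell_layout(small_spec).cells:
            cy, cx = cell.center
            ncy, ncx = cell.nucleus_center
            assert math.hypot(ncy - cy, ncx - cx) + max(cell.nucleus_radii) <= min(cell.radii) + 1e-9
            for foci in cell.foci.values():
                for fy, fx, rf in foci:
                    assert math.hypot(fy - ncy, fx - ncx) + rf <= min(cell.nucleus_radii) + 1e-9

    def test_placement_failure_names_achieved_count(self):
        spec = FieldSpec(image_height=64, image_width=64, n_cells=20,
                         cell_radius_range=(20.0, 22.0), nucleus_radius_range=(7.0, 9.0), seed=0)
        with pytest.raises(simgen.PlacementError, match=r"placed only \d+ of 20"):
            sample_cell_layout(spec, max_tries_per_cell=30)


class TestRenderScene:
    def test_mask_containment_pixelwise(self, noisy_scene):
        t = noisy_scene.truth
        nucleus = t.nucleus_labels > 0
        cells = t.cell_labels > 0
        assert np.array_equal(t.nucleus_labels > 0, (t.nucleus_labels > 0) & cells)
        for mask in t.subcompartment_masks.values():
            assert not (mask & ~nucleus).any()
        assert np.array_equal(t.nucleus_labels[nucleus], t.cell_labels[nucleus])

    def test_identity_fold_renders_uniform_nucleus(self, small_spec):
        from dataclasses import replace

        spec = replace(small_spec, enrichment_folds={"DFC": 1.0, "NS": 1.0, "heterochromatin": 1.0}).without_noise()
        scene = render_scene(sample_cell_layout(spec), spec)
        probe = scene.channels["probe"]
        nucleus = scene.truth.nucleus_labels > 0
        assert np.unique(probe[nucleus]).size == 1

    def test_fold_two_doubles_nucleoplasm_signal_exactly(self, small_spec):
        from dataclasses import replace

        spec = replace(small_spec, enrichment_folds={**small_spec.enrichment_folds, "DFC": 2.0}).without_noise()
        scene = render_scene(sample_cell_layout(spec), spec, time_min=360.0)
        probe = scene.channels["probe"] - spec.background_level
        dfc = scene.truth.subcompartment_masks["DFC"]
        nucleoplasm = (scene.truth.nucleus_labels > 0) & ~dfc
        assert np.allclose(probe[dfc], 2.0 * spec.base_levels["nucleoplasm"], atol=0)
        assert np.allclose(probe[nucleoplasm], spec.base_levels["nucleoplasm"], atol=0)

    def test_untreated_probe_is_background_only(self, small_spec):
        spec = small_spec.without_noise()
        scene = render_scene(sample_cell_layout(spec), spec, condition="untreated")
        cells = scene.truth.cell_labels > 0
        integrated = scene.channels["probe"][cells].sum()
        assert integrated == pytest.approx(spec.background_level * cells.sum(), rel=1e-12)

    def test_dapi_confined_to_nuclei_and_membrane_peaks_on_band(self, clean_scene):
        t = clean_scene.truth
        dapi = clean_scene.channels["dapi"]
        assert (dapi[t.nucleus_labels == 0] == 0).all()
        assert (dapi[t.nucleus_labels > 0] > 0).all()
        membrane = clean_scene.channels["membrane"]
        band = membrane > membrane.min()
        # the bright band hugs each cell's boundary: entirely within cells,
        # and every band pixel is within the band width of non-cell pixels
        assert not (band & (t.cell_labels == 0)).any()

    def test_unknown_condition_rejected(self, small_spec):
        geom = sample_cell_layout(small_spec)
        with pytest.raises(ValueError, match="condition"):
            render_scene(geom, small_spec, condition="UVplus")

    def test_scene_determinism_bit_identical(self, small_spec):
        a = render_scene(sample_cell_layout(small_spec), small_spec)
        b = render_scene(sample_cell_layout(small_spec), small_spec)
        for name in a.channels.channels:
            assert np.array_equal(a.channels[name], b.channels[name])


class TestApplyNoise:
    def test_noiseless_limit_is_identity(self, rng):
        raster = rng.uniform(0, 50, (32, 32))
        out = apply_noise(raster, simgen.NO_NOISE, seed=1)
        assert np.array_equal(out, raster)

    def test_same_seed_identical(self, rng):
        raster = rng.uniform(0, 50, (32, 32))
        noise = NoiseParams()
        assert np.array_equal(apply_noise(raster, noise, 5), apply_noise(raster, noise, 5))

    def test_mean_preserved_law_of_large_numbers(self):
        raster = np.full((1000, 1000), 100.0)
        out = apply_noise(raster, NoiseParams(), seed=3)
        assert out.mean() == pytest.approx(100.0, rel=0.01)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            NoiseParams(poisson_scale=-1.0)
        with pytest.raises(ValueError):
            NoiseParams(gaussian_sd=-0.5)
        with pytest.raises(ValueError):
            apply_noise(np.array([[-1.0]]), NoiseParams(), 0)


class TestTimeCourse:
    def test_zero_time_is_background_only(self, small_spec):
        spec = small_spec.without_noise()
        scene = generate_time_course(spec, [0.0, 60.0])[0]
        assert np.allclose(scene.channels["probe"], spec.background_level)

    def test_rate_doubling_doubles_signal(self, small_spec):
        spec = small_spec.without_noise()
        r = 1.0 / 360.0
        s1 = generate_time_course(spec, [120.0], uptake_rate=r)[0]
        s2 = generate_time_course(spec, [120.0], uptake_rate=2 * r)[0]
        sig1 = s1.channels["probe"] - spec.background_level
        sig2 = s2.channels["probe"] - spec.background_level
        assert np.allclose(sig2, 2 * sig1, atol=1e-9)

    def test_true_means_monotone_increasing(self, small_spec):
        scenes = generate_time_course(small_spec.without_noise(), [10, 30, 60, 120, 360])
        means = [s.truth.true_compartment_means["nucleus"] for s in scenes]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_negative_or_unsorted_times_rejected(self, small_spec):
        with pytest.raises(ValueError):
            generate_time_course(small_spec, [-1.0, 10.0])
        with pytest.raises(ValueError):
            generate_time_course(small_spec, [30.0, 10.0])


def _six_lanes(minus=9800.0, plus=20000.0):
    return (
        GelLaneSpec("ladder", 5000.0),
        GelLaneSpec("no_click", 0.0),
        GelLaneSpec("untreated", 0.0),
        GelLaneSpec("vehicle", 0.0),
        GelLaneSpec("minusUV", minus),
        GelLaneSpec("plusUV", plus),
    )


class TestGenerateGel:
    def test_noise_free_lane_profiles_integrate_to_truth(self):
        from glycoquant.geldens import integrate_lane

        gel = generate_gel(GelSpec(lanes=_six_lanes()))
        for (start, stop), truth in zip(gel.lane_columns, gel.true_signals):
            profile = gel.raster[:, start:stop].mean(axis=1)
            assert integrate_lane(profile) == pytest.approx(truth, rel=1e-9, abs=1e-9)

    def test_half_ratio_by_construction(self):
        gel = generate_gel(GelSpec(lanes=_six_lanes(minus=10000.0, plus=20000.0)))
        roles = dict(zip(gel.lane_roles, gel.true_signals))
        assert roles["minusUV"] / roles["plusUV"] == 0.5

    def test_eight_signal_lanes_give_eight_column_maxima(self):
        from scipy.signal import find_peaks

        lanes = tuple(GelLaneSpec("plusUV", 10000.0) for _ in range(8))
        gel = generate_gel(GelSpec(lanes=lanes, seed=1))
        col = gel.raster.sum(axis=0)
        peaks, props = find_peaks(col, plateau_size=1, prominence=0.1 * (col.max() - col.min()))
        assert len(peaks) == 8

    def test_gel_determinism(self):
        spec = GelSpec(lanes=_six_lanes(), noise_sd=30.0, seed=4)
        assert np.array_equal(generate_gel(spec).raster, generate_gel(spec).raster)

    def test_zero_lanes_rejected(self):
        with pytest.raises(ValueError):
            GelSpec(lanes=())


class TestGroundTruthConsistency:
    def test_noise_free_fold_recovered_from_generator_masks(self, small_spec):
        """Ratio measured on the generator's own masks matches the
        configured fold to 1e-12 relative error (background-corrected)."""
        from dataclasses import replace

        spec = replace(
            small_spec,
            subcompartments=(SubcompartmentSpec("DFC"), SubcompartmentSpec("NS", 4, (1.5, 3.0))),
        ).without_noise()
        scene = render_scene(sample_cell_layout(spec), spec)
        probe = scene.channels["probe"] - spec.background_level
        t = scene.truth
        all_sub = np.zeros_like(t.pm_mask)
        for m in t.subcompartment_masks.values():
            all_sub |= m
        for kind, mask in t.subcompartment_masks.items():
            for k in np.unique(t.nucleus_labels)[1:]:
                nmask = t.nucleus_labels == k
                comp = mask & nmask
                rem = nmask & ~all_sub
                fold = probe[comp].mean() / probe[rem].mean()
                assert fold == pytest.approx(t.true_folds[kind], rel=1e-12)
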
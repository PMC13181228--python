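"""Parameter-recovery experiments on synthetic ground truth.

Each function runs the analysis end to end on generator output (never on
the generator's own masks, except where noted) and reports how well the
configured truth is recovered: enrichment-fold bias, null rejection
rates, segmentation IoU, gel ratio error, uptake-rate error, and
byte-level determinism of the pipeline tables.  These back both the test
suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import geldens, quantification as quant, simgen, subnuclear
from .segmentation import SegmentationParams, segment_field, segment_nuclei


def _sub_seed(*parts: int) -> int:
    return int(np.random.SeedSequence([int(p) for p in parts]).generate_state(1)[0] % (2**31))


def region_mean_oracle_max_diff(n_rasters: int = 100, size: int = 24, seed: int = 0) -> float:
    """Max |measured − brute-force| over random rasters and random
    partitions; the oracle is an explicit per-pixel accumulation loop."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_rasters):
        raster = rng.uniform(0, 100, (size, size))
        labels = rng.integers(0, 4, (size, size))
        for k in (1, 2, 3):
            mask = labels == k
            if not mask.any():
                continue
            total, count = 0.0, 0
            for i in range(size):          # brute force, on purpose
                for j in range(size):
                    if labels[i, j] == k:
                        total += raster[i, j]
                        count += 1
            measured = float(raster[mask].mean())
            worst = max(worst, abs(measured - total / count))
    return worst


def estimate_enrichment_folds(
    true_fold: float,
    n_nuclei: int,
    seed: int,
    kind: str = "DFC",
    spec: simgen.FieldSpec | None = None,
) -> list[float]:
    """Per-nucleus enrichment estimates at a configured truth.

    Scenes are generated at the given fold, nuclei segmented from DAPI,
    the subcompartment from the marker channel, background estimated from
    a matched untreated scene, and the fold scored per nucleus until
    ``n_nuclei`` estimates are collected.
    """
    base = spec or simgen.FieldSpec()
    subs = (simgen.SubcompartmentSpec(kind, foci_per_nucleus=3, focus_radius_range=(2.0, 4.0))
            if kind != "heterochromatin" else simgen.SubcompartmentSpec(kind, focus_radius_range=(2.0, 2.0)),)
    folds: list[float] = []
    batch = 0
    background = None
    while len(folds) < n_nuclei:
        s = replace(base, seed=_sub_seed(seed, batch), subcompartments=subs,
                    enrichment_folds={**base.enrichment_folds, kind: true_fold})
        if background is None:
            bg_scene = simgen.generate_scene(s, condition="untreated")
            bg_masks = segment_field(bg_scene.channels)
            background = quant.estimate_background([(bg_scene.channels["probe"], bg_masks)]).background
        scene = simgen.generate_scene(s, condition="plusUV")
        nuclei = segment_nuclei(scene.channels["dapi"])
        masks = subnuclear.segment_subcompartment(scene.channels["marker"], nuclei, kind)
        recs = subnuclear.compute_enrichment(scene.channels["probe"], masks, background=background)
        folds.extend(r.enrichment_fold for r in recs)
        batch += 1
        if batch > 20 * max(1, n_nuclei // 5):
            raise RuntimeError("could not collect enough nuclei")
    return folds[:n_nuclei]


def enrichment_null_rejection_rate(
    n_reps: int = 500,
    n_per_group: int = 50,
    pool_size: int = 600,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Type-I error of the two-sided Mann-Whitney comparison at fold 1.0.

    A pool of fold-1.0 per-nucleus estimates is generated once; each
    replicate tests two disjoint random subsets of the pool, so the null
    of exchangeability holds exactly under the random assignment.
    """
    pool = np.array(estimate_enrichment_folds(1.0, pool_size, seed=_sub_seed(seed, 1)))
    rng = np.random.default_rng(_sub_seed(seed, 2))
    rejections = 0
    for _ in range(n_reps):
        idx = rng.permutation(len(pool))[: 2 * n_per_group]
        a, b = pool[idx[:n_per_group]], pool[idx[n_per_group:]]
        if subnuclear.mann_whitney_u(a, b, "two_sided").p_value < alpha:
            rejections += 1
    return rejections / n_reps


def segmentation_fidelity(seed: int = 0, n_fields: int = 3) -> dict:
    """Noise-free nucleus/cell counts and per-object IoU vs ground truth."""
    nuc_ious, cell_ious = [], []
    counts_ok = True
    for i in range(n_fields):
        spec = simgen.FieldSpec(seed=_sub_seed(seed, 7, i)).without_noise()
        scene = simgen.generate_scene(spec)
        truth = scene.truth
        masks = segment_field(scene.channels, SegmentationParams(exclude_border_cells=False))
        counts_ok &= masks.nucleus_labels.max() == truth.nucleus_labels.max()
        counts_ok &= masks.cell_labels.max() == truth.cell_labels.max()
        for k in masks.labels():
            seg_n = masks.nucleus_labels == k
            tk = int(np.bincount(truth.nucleus_labels[seg_n]).argmax())
            tn, tc = truth.nucleus_labels == tk, truth.cell_labels == tk
            seg_c = masks.cell_labels == k
            nuc_ious.append((seg_n & tn).sum() / (seg_n | tn).sum())
            cell_ious.append((seg_c & tc).sum() / (seg_c | tc).sum())
    return {
        "counts_exact": bool(counts_ok),
        "nucleus_iou_min": float(min(nuc_ious)),
        "nucleus_iou_mean": float(np.mean(nuc_ious)),
        "cell_iou_min": float(min(cell_ious)),
        "cell_iou_mean": float(np.mean(cell_ious)),
        "n_objects": len(nuc_ious),
    }


def _gel_spec(true_ratio: float, plus_uv_signal: float, noise_frac: float, seed: int) -> simgen.GelSpec:
    lanes = (
        simgen.GelLaneSpec("ladder", 5000.0),
        simgen.GelLaneSpec("no_click", 0.0),
        simgen.GelLaneSpec("untreated", 0.0),
        simgen.GelLaneSpec("vehicle", 0.0),
        simgen.GelLaneSpec("minusUV", true_ratio * plus_uv_signal),
        simgen.GelLaneSpec("plusUV", plus_uv_signal),
    )
    peak = plus_uv_signal * simgen._band_kernel(200, simgen.GelSpec(lanes=lanes).band_layout).max()
    return simgen.GelSpec(lanes=lanes, noise_sd=noise_frac * peak, seed=seed)


def gel_recovery(
    true_ratio: float = 0.49,
    n_replicates: int = 4,
    noise_frac: float = 0.02,
    seed: int = 0,
) -> geldens.IncorporationResult:
    """Recover the configured −UV/+UV ratio from rendered gel rasters.

    ``noise_frac`` scales the Gaussian noise SD to that fraction of the
    +UV lane's peak band height (0 gives machine-precision recovery).
    """
    minus, plus = [], []
    for rep in range(n_replicates):
        gel = simgen.generate_gel(_gel_spec(true_ratio, 20000.0, noise_frac, _sub_seed(seed, 11, rep)))
        _, signals, _ = geldens.quantify_gel(gel.raster, gel.lane_roles)
        minus.append(signals["minusUV"][0])
        plus.append(signals["plusUV"][0])
    return geldens.incorporation_ratio(minus, plus, time_h=6.0)


def uptake_recovery(
    times: tuple[float, ...] = (10.0, 30.0, 60.0, 120.0, 360.0),
    cells_per_time: int = 50,
    uptake_rate: float = 1.0 / 360.0,
    seed: int = 0,
) -> dict:
    """Recover the linear uptake rate from a synthetic time course.

    Measured nuclear means (background-corrected, own segmentation) are
    regressed on time; the recovered rate is the measured slope divided by
    the generator's true nuclear brightness per unit of ``rate × t``, so
    the comparison isolates measurement error.
    """
    spec = simgen.FieldSpec(seed=_sub_seed(seed, 23))
    fields_per_time = int(np.ceil(cells_per_time / spec.n_cells))
    scenes = simgen.generate_time_course(spec, list(times), uptake_rate, fields_per_time=fields_per_time)

    xs, ys, truth_slope_num = [], [], []
    for scene in scenes:
        masks = segment_field(scene.channels)
        recs = quant.measure_compartments(scene.channels["probe"], masks, time_min=scene.time_min)
        nuclear = [r.mean_intensity - scene.truth.background_level for r in recs if r.compartment == "nucleus"]
        xs.extend([scene.time_min] * len(nuclear))
        ys.extend(nuclear)
        # true nuclear brightness per minute for this geometry
        truth_slope_num.append((scene.truth.true_compartment_means["nucleus"] - scene.truth.background_level)
                               / scene.time_min if scene.time_min > 0 else np.nan)
    measured_slope = float(np.polyfit(xs, ys, 1)[0])
    true_slope = float(np.nanmean(truth_slope_num))
    recovered_rate = uptake_rate * measured_slope / true_slope
    return {
        "true_rate": uptake_rate,
        "recovered_rate": recovered_rate,
        "relative_error": abs(recovered_rate - uptake_rate) / uptake_rate,
        "n_cells_per_time": cells_per_time,
    }


def pipeline_determinism(config: dict, seed: int, workdir) -> bool:
    """Run the pipeline twice with the same config + seed; compare the
    bytes of every CSV table."""
    from pathlib import Path

    from .pipeline import run_pipeline

    workdir = Path(workdir)
    outs = []
    for name in ("run_a", "run_b"):
        bundle = run_pipeline(config, seed=seed, outdir=workdir / name)
        outs.append(sorted(p for p in (workdir / name).glob("*.csv")))
    if [p.name for p in outs[0]] != [p.name for p in outs[1]]:
        return False
    return all(a.read_bytes() == b.read_bytes() for a, b in zip(outs[0], outs[1]))
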
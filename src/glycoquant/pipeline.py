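"""End-to-end synthetic pipeline: simulate → segment → quantify → enrich → gel.

Runs the full analysis on generator output, persisting every intermediate
(scene TIFFs, label masks, tidy CSVs, scalar JSON reports) plus a
provenance block (config hash, seed, package version).  Output bytes are
deterministic for a fixed config + seed: no timestamps are written.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, geldens, io, quantification as quant, simgen, subnuclear
from .segmentation import SegmentationParams, segment_field
from .subnuclear import SubnuclearParams

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "field": {},  # FieldSpec overrides
        "times": [10.0, 30.0, 60.0, 120.0, 360.0],
        "conditions": ["plusUV", "minusUV", "untreated"],
        "uptake_rate": 1.0 / 360.0,
        "fields_per_time": 1,
    },
    "segmentation": {},  # SegmentationParams overrides
    "subnuclear": {"kinds": ["DFC"], "min_compartment_area": 4},
    "gel": {"enabled": True, "true_ratio": 0.49, "plus_uv_signal": 20000.0, "replicates": 4, "noise_frac": 0.02},
}


@dataclass
class ResultBundle:
    outdir: Path
    records: pd.DataFrame
    summaries: pd.DataFrame
    enrichment_records: pd.DataFrame
    enrichment_summaries: pd.DataFrame
    gel_lanes: pd.DataFrame
    reports: dict
    provenance: dict


def _merge(base: dict, override: dict | None) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def _field_spec(cfg: dict, seed: int) -> simgen.FieldSpec:
    overrides = dict(cfg["simulate"]["field"])
    subs = overrides.pop("subcompartments", None)
    if subs is not None:
        overrides["subcompartments"] = tuple(simgen.SubcompartmentSpec(**s) for s in subs)
    if "noise" in overrides:
        overrides["noise"] = simgen.NoiseParams(**overrides["noise"])
    return simgen.FieldSpec(seed=seed, **overrides)


def run_pipeline(config: dict | None = None, seed: int | None = None, outdir: str | Path = "results") -> ResultBundle:
    """Execute all stages on synthetic data and persist the results.

    Any stage failure aborts with a stage-named diagnostic; outputs written
    before the failure are retained.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": io.config_hash(cfg), "seed": cfg["seed"], "package_version": __version__}
    io.write_json(outdir / "provenance.json", provenance)
    io.save_config(outdir / "config.yaml", cfg)

    master = np.random.SeedSequence(int(cfg["seed"]))
    stage_seeds = {name: int(s.generate_state(1)[0] % (2**31)) for name, s in
                   zip(("simulate", "gel"), master.spawn(2))}
    sim = cfg["simulate"]
    seg_params = SegmentationParams(**cfg["segmentation"])
    sub_params = SubnuclearParams(min_compartment_area=cfg["subnuclear"]["min_compartment_area"])

    # -- simulate + segment + measure -------------------------------------
    stage = "simulate/segment/quantify"
    try:
        all_records: list[quant.IntensityRecord] = []
        untreated_pairs = []
        enrich_inputs: dict[str, list] = {}  # condition -> [(scene, masks)]
        for ci, condition in enumerate(sim["conditions"]):
            for ti, t in enumerate(sim["times"]):
                for fi in range(sim["fields_per_time"]):
                    sub_seed = int(np.random.SeedSequence(
                        [stage_seeds["simulate"], ci, ti, fi]).generate_state(1)[0] % (2**31))
                    spec = _field_spec(cfg, sub_seed)
                    scene = simgen.generate_scene(spec, time_min=t, condition=condition,
                                                  uptake_rate=sim["uptake_rate"])
                    fid = f"{condition}_t{t:g}_f{fi}"
                    io.write_stack(outdir / f"scene_{fid}.tif", scene.channels,
                                   ["dapi", "membrane", "marker", "probe"])
                    masks = segment_field(scene.channels, seg_params)
                    io.write_labels(outdir / f"cells_{fid}.tif", masks.cell_labels)
                    io.write_labels(outdir / f"nuclei_{fid}.tif", masks.nucleus_labels)
                    all_records.extend(
                        quant.measure_compartments(scene.channels["probe"], masks, field_id=fid,
                                                   time_min=t, uv_condition=condition)
                    )
                    if condition == "untreated":
                        untreated_pairs.append((scene.channels["probe"], masks))
                    if t == max(sim["times"]):
                        enrich_inputs.setdefault(condition, []).append((scene, masks))

        background = quant.estimate_background(untreated_pairs)
        corrected = quant.subtract_background(all_records, background)
        summaries = quant.summarize_conditions(corrected, grouping=("uv_condition", "time_min", "compartment"))
        records_df = quant.records_to_frame(corrected)
        summaries_df = quant.summaries_to_frame(summaries)
        records_df.to_csv(outdir / "intensity_records.csv", index=False)
        summaries_df.to_csv(outdir / "condition_summaries.csv", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # -- subnuclear enrichment --------------------------------------------
    stage = "enrich"
    try:
        enr_records, enr_summaries, utests = [], [], {}
        for kind in cfg["subnuclear"]["kinds"]:
            per_condition: dict[str, list[float]] = {}
            for condition, pairs in enrich_inputs.items():
                if condition == "untreated":
                    continue
                recs = []
                for scene, masks in pairs:
                    if scene.marker_kind != kind:
                        raise KeyError(f"scene marker channel is {scene.marker_kind!r}, not {kind!r}; "
                                       "configure simulate.field.subcompartments accordingly")
                    smasks = subnuclear.segment_subcompartment(
                        scene.channels["marker"], masks.nucleus_labels, kind, sub_params)
                    recs.extend(subnuclear.compute_enrichment(
                        scene.channels["probe"], smasks, background=background.background,
                        uv_condition=condition))
                if recs:
                    enr_records.extend(recs)
                    enr_summaries.append(subnuclear.summarize_enrichment(recs))
                    per_condition[condition] = [r.enrichment_fold for r in recs]
            if {"plusUV", "minusUV"} <= set(per_condition):
                res = subnuclear.mann_whitney_u(per_condition["plusUV"], per_condition["minusUV"], "two_sided")
                utests[kind] = {"U": res.U, "p_value": res.p_value, "method": res.method,
                                "comparison": "plusUV_vs_minusUV_folds"}
        enr_records_df = pd.DataFrame([r.__dict__ for r in enr_records])
        enr_summaries_df = pd.DataFrame([s.__dict__ for s in enr_summaries])
        enr_records_df.to_csv(outdir / "enrichment_records.csv", index=False)
        enr_summaries_df.to_csv(outdir / "enrichment_summaries.csv", index=False)
        io.write_json(outdir / "enrichment_tests.json", utests)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # -- gel densitometry ---------------------------------------------------
    stage = "gel"
    reports: dict = {"background": background.background, "utests": utests}
    gel_rows = []
    try:
        if cfg["gel"]["enabled"]:
            g = cfg["gel"]
            minus_sig, plus_sig = [], []
            for rep in range(int(g["replicates"])):
                plus = float(g["plus_uv_signal"])
                lanes = (
                    simgen.GelLaneSpec("ladder", 5000.0),
                    simgen.GelLaneSpec("no_click", 0.0),
                    simgen.GelLaneSpec("untreated", 0.0),
                    simgen.GelLaneSpec("vehicle", 0.0),
                    simgen.GelLaneSpec("minusUV", float(g["true_ratio"]) * plus),
                    simgen.GelLaneSpec("plusUV", plus),
                )
                peak = plus * simgen._band_kernel(200, simgen.GelSpec(lanes=lanes).band_layout).max()
                gel_spec = simgen.GelSpec(lanes=lanes, noise_sd=float(g["noise_frac"]) * peak,
                                          seed=int(np.random.SeedSequence(
                                              [stage_seeds["gel"], rep]).generate_state(1)[0] % (2**31)))
                gel = simgen.generate_gel(gel_spec)
                profiles, signals, _ = geldens.quantify_gel(gel.raster, gel.lane_roles)
                for lane, truth in zip(profiles, gel.true_signals):
                    gel_rows.append({"replicate": rep, "lane": lane.lane_id, "role": lane.role,
                                     "signal": geldens.integrate_lane(lane), "true_signal": truth})
                minus_sig.append(signals["minusUV"][0])
                plus_sig.append(signals["plusUV"][0])
            result = geldens.incorporation_ratio(minus_sig, plus_sig)
            reports["incorporation"] = {"ratio": result.ratio, "percent": result.percent,
                                        "n_replicates": result.n_replicates, "se": result.se}
        gel_df = pd.DataFrame(gel_rows)
        gel_df.to_csv(outdir / "gel_lanes.csv", index=False)
        io.write_json(outdir / "reports.json", reports)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    return ResultBundle(
        outdir=outdir,
        records=records_df,
        summaries=summaries_df,
        enrichment_records=enr_records_df,
        enrichment_summaries=enr_summaries_df,
        gel_lanes=gel_df,
        reports=reports,
        provenance=provenance,
    )
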
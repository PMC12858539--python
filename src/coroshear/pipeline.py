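"""End-to-end orchestration: generate -> fields -> indices -> segments -> cohort -> fit.

A single YAML-serializable :class:`RunConfig` holds every constant of the
study conditions (blood density, hyperemia factor, sub-segment length, the
±5 ΔDS% thresholds live in ``segstats``, the CT-FFR offset, ...).  A run is
deterministic given its seed, and the manifest lists every artifact with a
SHA-256 content hash so two runs can be compared by hash equality.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import synthgen, vtkio
from .errors import PipelineStageError, ValidationError
from .geometry import (
    REFERENCE_ID,
    assign_vertices_to_segments,
    define_segments,
    stenosis_metrics,
)
from .hemofields import HemoConfig, apply_hyperemia, solve_reduced_order
from .indices import compute_ctffr, compute_index_maps
from .inference import fit_logistic, roc_analysis
from .segstats import aggregate_segment, build_cohort_table, normalize_to_reference
from .synthgen import CohortSpec, StenosisSpec

log = logging.getLogger("coroshear")

__all__ = ["RunConfig", "run_pipeline", "default_config"]


@dataclass
class RunConfig:
    """Configuration of one synthetic end-to-end run."""

    seed: int = 0
    outdir: str = "coroshear_run"
    # vessel stage
    vessel: dict = field(
        default_factory=lambda: {
            "base_radius": 2.0e-3,
            "vessel_length": 60.0e-3,
            "stenosis_center": 30.0e-3,
            "stenosis_width": 4.0e-3,
            "severity": 0.5,
            "axial_resolution": 120,
            "circumferential_resolution": 32,
        }
    )
    waveform: dict = field(
        default_factory=lambda: {
            "period": 0.8,
            "mean_flow": 1.0e-6,
            "pulsatility_amplitude": 0.5,
            "samples_per_cycle": 48,
        }
    )
    hemo: dict = field(default_factory=dict)  # HemoConfig overrides
    swirl_rate: float = 20.0
    segments: dict = field(
        default_factory=lambda: {"sub_length_mm": 3.0, "epsilon": 0.05}
    )
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    models: dict = field(
        default_factory=lambda: {
            "progression": ["N.Min.TAWSS", "N.Max.Helicity"],
            "regression": ["N.Ave.GON", "N.Ave.Vorticity"],
        }
    )
    roc_bootstrap: int = 2000
    write_fields: bool = False

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def default_config() -> RunConfig:
    return RunConfig()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: RunConfig, until_stage: str | None = None) -> dict:
    """Run all stages and return the manifest (also written to disk).

    Stages in order: ``generate``, ``flow``, ``indices``, ``segments``,
    ``cohort``, ``fit``, ``roc``.  ``until_stage`` stops after the named
    stage (inclusive).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    info: dict = {"seed": config.seed, "stages": []}
    stage_order = ["generate", "flow", "indices", "segments", "cohort", "fit", "roc"]
    if until_stage is not None and until_stage not in stage_order:
        raise ValidationError(f"unknown stage: {until_stage}")
    stop_at = stage_order.index(until_stage) if until_stage else len(stage_order) - 1

    def record(stage, t0):
        info["stages"].append({"stage": stage, "elapsed_s": round(time.time() - t0, 3)})

    # -- generate ----------------------------------------------------------
    t0 = time.time()
    try:
        vconf = dict(config.vessel)
        res = (
            vconf.pop("axial_resolution", 120),
            vconf.pop("circumferential_resolution", 32),
        )
        spec = StenosisSpec(**vconf)
        geom = synthgen.make_stenotic_vessel(spec, *res)
        vtkio.write_polydata(
            outdir / "vessel.vtk", geom.vertices, geom.triangles,
            {"s": geom.vertex_s, "angle": geom.vertex_angle},
        )
        written.append(outdir / "vessel.vtk")
    except Exception as exc:
        raise PipelineStageError("generate", str(exc)) from exc
    record("generate", t0)
    if stop_at < 1:
        return _finish(outdir, written, info)

    # -- flow --------------------------------------------------------------
    t0 = time.time()
    try:
        waveform = synthgen.make_flow_waveform(**config.waveform)
        cfg = HemoConfig(**config.hemo)
        wall, vol = solve_reduced_order(geom, waveform, cfg)
        hyper = apply_hyperemia(waveform, cfg.hyperemia_factor)
        wall_hyper, _ = solve_reduced_order(geom, hyper, cfg)
        if config.swirl_rate:
            vol = synthgen.make_volume_field_series(
                geom, waveform, swirl_rate=config.swirl_rate
            )
        if config.write_fields:
            mpath = vtkio.write_field_series(wall, vol, outdir / "fields")
            written.append(mpath)
            written.extend(sorted((outdir / "fields").glob("*.vtk")))
            written.append(outdir / "fields" / "vertex_s.txt")
    except Exception as exc:
        raise PipelineStageError("flow", str(exc)) from exc
    record("flow", t0)
    if stop_at < 2:
        return _finish(outdir, written, info)

    # -- indices -----------------------------------------------------------
    t0 = time.time()
    try:
        metrics = stenosis_metrics(
            geom, proximal_reference_s=0.0, epsilon=config.segments.get("epsilon", 0.05)
        )
        maps = compute_index_maps(
            wall,
            vol,
            geom,
            hyperemic_wall=wall_hyper,
            lesion_distal_s=metrics["lesion_extent"][1],
            cfg=cfg,
        )
        vtkio.write_index_maps(outdir / "index_maps.vtk", geom, maps)
        written.append(outdir / "index_maps.vtk")
        with open(outdir / "stenosis_metrics.json", "w") as fh:
            json.dump(
                {**metrics, "ctffr": maps.ctffr, "flagged": maps.flagged_counts},
                fh, indent=2, default=_json_default,
            )
        written.append(outdir / "stenosis_metrics.json")
        log.info("flagged index values: %s", maps.flagged_counts)
    except Exception as exc:
        raise PipelineStageError("indices", str(exc)) from exc
    record("indices", t0)
    if stop_at < 3:
        return _finish(outdir, written, info)

    # -- segments ----------------------------------------------------------
    t0 = time.time()
    try:
        summaries_payload: list = []
        if metrics["no_narrowing"]:
            log.info("no narrowing found: zero lesion segments")
            info["n_lesion_segments"] = 0
        else:
            segdef = define_segments(
                geom,
                metrics["lesion_extent"],
                sub_length=config.segments.get("sub_length_mm", 3.0) * 1e-3,
            )
            assign_s = assign_vertices_to_segments(geom.vertex_s, segdef)
            assign_v = assign_vertices_to_segments(vol.param_s, segdef)
            vol_w = np.maximum(vol.param_r, 1e-12)  # cylindrical volume element
            summaries = aggregate_segment(
                maps, assign_s, segdef,
                surface_weights=geom.vertex_areas(),
                volume_assignment=assign_v,
                volume_weights=vol_w,
            )
            ref = next(s for s in summaries if s.segment_id == REFERENCE_ID)
            for s in summaries:
                if s.segment_id == REFERENCE_ID or s.empty:
                    continue
                norm = normalize_to_reference(s, ref)
                summaries_payload.append(
                    {"segment_id": s.segment_id, "normalized": norm.values,
                     "flagged": norm.flagged}
                )
            (outdir / "segments.json").write_text(segdef.to_json())
            written.append(outdir / "segments.json")
            info["n_lesion_segments"] = segdef.n_segments
        with open(outdir / "segment_summaries.json", "w") as fh:
            json.dump(summaries_payload, fh, indent=2, default=_json_default)
        written.append(outdir / "segment_summaries.json")
    except Exception as exc:
        raise PipelineStageError("segments", str(exc)) from exc
    record("segments", t0)
    if stop_at < 4:
        return _finish(outdir, written, info)

    # -- cohort ------------------------------------------------------------
    t0 = time.time()
    try:
        cspec = CohortSpec(**{"seed": config.seed, **config.cohort})
        cohort = synthgen.simulate_cohort(cspec)
        synthgen.write_cohort(
            cohort, outdir / "cohort.csv", outdir / "cohort_provenance.json"
        )
        written += [outdir / "cohort.csv", outdir / "cohort_provenance.json"]
        info["n_cohort_rows"] = len(cohort)
    except Exception as exc:
        raise PipelineStageError("cohort", str(exc)) from exc
    record("cohort", t0)
    if stop_at < 5:
        return _finish(outdir, written, info)

    # -- fit ---------------------------------------------------------------
    t0 = time.time()
    fits = {}
    try:
        for contrast, covs in config.models.items():
            res = fit_logistic(cohort, contrast, covs)
            fits[contrast] = res
            res.table.to_csv(outdir / f"logistic_{contrast}.csv")
            written.append(outdir / f"logistic_{contrast}.csv")
    except Exception as exc:
        raise PipelineStageError("fit", str(exc)) from exc
    record("fit", t0)
    if stop_at < 6:
        return _finish(outdir, written, info)

    # -- roc ---------------------------------------------------------------
    t0 = time.time()
    try:
        roc_payload = {}
        for contrast, res in fits.items():
            scores = res.predicted_probabilities(cohort)
            labels = (cohort["label"] == contrast).astype(int).to_numpy()
            roc = roc_analysis(
                scores, labels, n_bootstrap=config.roc_bootstrap,
                seed=config.seed + 1,
            )
            roc_payload[contrast] = {
                "auc": roc.auc,
                "auc_ci": roc.auc_ci,
                "threshold": roc.threshold,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "ppv": roc.ppv,
                "npv": roc.npv,
                "accuracy": roc.accuracy,
                "confusion": roc.confusion,
            }
        with open(outdir / "roc.json", "w") as fh:
            json.dump(roc_payload, fh, indent=2, default=_json_default)
        written.append(outdir / "roc.json")
    except Exception as exc:
        raise PipelineStageError("roc", str(exc)) from exc
    record("roc", t0)

    return _finish(outdir, written, info)


def _finish(outdir: Path, written: list[Path], info: dict) -> dict:
    manifest = {
        "seed": info["seed"],
        "files": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(written))
        },
        **{k: v for k, v in info.items() if k not in ("seed", "stages")},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(info["stages"], fh, indent=2)
    return manifest
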
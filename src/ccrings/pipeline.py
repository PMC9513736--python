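"""Per-eye and cohort orchestration: file I/O, QC artifacts, reports.

A run is driven by a YAML manifest listing, per eye, the T1/T2 angiogram and
structural images plus the three masks (MNV, dark halo, vessels). Each eye is
processed as validate margins -> compensate -> build rings on T1 -> transfer
to T2 -> Phansalkar threshold -> per-ring FD metrics; eyes that fail
validation are skipped with a logged reason rather than aborting the cohort
(mirroring study-level exclusion). Outputs are tidy CSVs, a JSON statistics
bundle with the run manifest embedded, and per-eye QC overlays.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binarize import PhansalkarParams, phansalkar_threshold
from .compensation import compensate_angiogram
from .images import EnFaceImage, GeometryError, read_image, read_mask, write_image, write_mask
from .metrics import RingMetrics, ring_fd_metrics
from .phantom import CohortSpec, EyeRecord, PhantomSpec, generate_paired_cohort
from .rings import (
    LesionMaskSet,
    build_analysis_masks,
    build_rings,
    transfer_rings,
    validate_scan_margins,
)
from .stats import cohort_summary

__all__ = ["RunParameters", "RunConfig", "run_eye", "run_cohort", "write_phantom_cohort", "load_config"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunParameters:
    """Analysis parameters shared by every eye of a run."""

    pixel_pitch_um: float = 6.0
    ring_width_um: float = 200.0
    n_rings: int = 5
    min_margin_um: float = 1000.0
    phansalkar: PhansalkarParams = field(default_factory=PhansalkarParams)
    connectivity: int = 8
    min_fd_area_um2: float = 0.0
    min_ring_area_px: int = 100
    compensation: bool = True
    ground_truth_mask_mode: bool = False

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunParameters":
        d = dict(d)
        if "phansalkar" in d:
            d["phansalkar"] = PhansalkarParams(**d["phansalkar"])
        return cls(**d)


@dataclass(frozen=True)
class VisitPaths:
    angiogram: Path
    structural: Path
    truth_deficit: Path | None = None


@dataclass(frozen=True)
class EyePaths:
    eye_id: str
    t1: VisitPaths
    t2: VisitPaths
    mnv_mask: Path
    halo_mask: Path
    vessel_mask: Path


@dataclass(frozen=True)
class RunConfig:
    eyes: tuple[EyePaths, ...]
    parameters: RunParameters
    output_dir: Path
    seed: int = 0

    def validate(self) -> None:
        for eye in self.eyes:
            paths = [
                eye.t1.angiogram, eye.t1.structural,
                eye.t2.angiogram, eye.t2.structural,
                eye.mnv_mask, eye.halo_mask, eye.vessel_mask,
            ]
            if self.parameters.ground_truth_mask_mode:
                paths += [eye.t1.truth_deficit, eye.t2.truth_deficit]
            for p in paths:
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"eye {eye.eye_id}: missing input {p}")


def _visit_paths(base: Path, d: dict[str, Any]) -> VisitPaths:
    truth = d.get("truth_deficit")
    return VisitPaths(
        angiogram=base / d["angiogram"],
        structural=base / d["structural"],
        truth_deficit=base / truth if truth else None,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run manifest (paths relative to the file)."""
    path = Path(path)
    base = path.parent
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    params = RunParameters.from_dict(raw.get("parameters", {}))
    eyes = tuple(
        EyePaths(
            eye_id=str(e["id"]),
            t1=_visit_paths(base, e["t1"]),
            t2=_visit_paths(base, e["t2"]),
            mnv_mask=base / e["mnv_mask"],
            halo_mask=base / e["halo_mask"],
            vessel_mask=base / e["vessel_mask"],
        )
        for e in raw["eyes"]
    )
    out_dir = raw.get("output_dir", "ccrings_out")
    out_path = Path(out_dir)
    if not out_path.is_absolute():
        out_path = base / out_path
    cfg = RunConfig(eyes=eyes, parameters=params, output_dir=out_path, seed=int(raw.get("seed", 0)))
    cfg.validate()
    return cfg


def _visit_deficit(
    paths: VisitPaths,
    masks: LesionMaskSet,
    params: RunParameters,
):
    """Load one visit and return (deficit raster/map, angiogram image)."""
    angio = read_image(paths.angiogram, params.pixel_pitch_um, "angiogram")
    if params.ground_truth_mask_mode:
        if paths.truth_deficit is None:
            raise FileNotFoundError("ground-truth-mask mode requires truth_deficit paths")
        return read_mask(paths.truth_deficit), angio
    struct = read_image(paths.structural, params.pixel_pitch_um, "structural")
    work = compensate_angiogram(angio, struct) if params.compensation else angio
    return phansalkar_threshold(work, params.phansalkar), work


def run_eye(eye: EyePaths, params: RunParameters, output_dir: Path | None = None) -> dict[str, Any]:
    """Process one eye end to end; returns per-visit metrics and QC paths.

    Raises on margin violations or geometry errors; ``run_cohort`` catches
    these and skips the eye.
    """
    masks = LesionMaskSet(
        read_mask(eye.mnv_mask), read_mask(eye.halo_mask), read_mask(eye.vessel_mask)
    )
    report = validate_scan_margins(masks.mnv_mask, params.pixel_pitch_um, params.min_margin_um)
    if not report.passed:
        raise GeometryError(
            f"eye {eye.eye_id}: MNV margin {report.min_margin_um:.0f} um "
            f"< required {report.required_um:.0f} um"
        )
    rings = build_rings(masks, params.pixel_pitch_um, params.ring_width_um, params.n_rings)
    analysis = build_analysis_masks(rings, masks, params.min_ring_area_px)

    deficit_t1, work_t1 = _visit_deficit(eye.t1, masks, params)
    work_t2_img = read_image(eye.t2.angiogram, params.pixel_pitch_um, "angiogram")
    transfer_rings(rings, work_t2_img)  # grid check: fixed ROI transfer to T2
    deficit_t2, work_t2 = _visit_deficit(eye.t2, masks, params)

    kwargs = dict(min_fd_area_um2=params.min_fd_area_um2, connectivity=params.connectivity)
    metrics_t1 = ring_fd_metrics(deficit_t1, analysis, masks, **kwargs)
    metrics_t2 = ring_fd_metrics(deficit_t2, analysis, masks, **kwargs)

    artifacts: dict[str, str] = {}
    if output_dir is not None:
        eye_dir = Path(output_dir) / eye.eye_id
        eye_dir.mkdir(parents=True, exist_ok=True)
        for visit, deficit in (("t1", deficit_t1), ("t2", deficit_t2)):
            dmask = deficit if isinstance(deficit, np.ndarray) else deficit.deficit
            p = eye_dir / f"deficit_{visit}.tif"
            write_mask(p, dmask)
            artifacts[f"deficit_{visit}"] = str(p)
        overlay = eye_dir / "rings_overlay.png"
        _write_ring_overlay(overlay, work_t1, rings.label_map)
        artifacts["rings_overlay"] = str(overlay)
    return {
        "eye_id": eye.eye_id,
        "t1": metrics_t1,
        "t2": metrics_t2,
        "margin_um": report.min_margin_um,
        "artifacts": artifacts,
    }


def _write_ring_overlay(path: Path, image, label_map: np.ndarray) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pixels = image.pixels if isinstance(image, EnFaceImage) else np.asarray(image)
    fig, ax = plt.subplots(figsize=(5, 5), dpi=110)
    ax.imshow(pixels, cmap="gray", interpolation="nearest")
    masked = np.ma.masked_equal(label_map, 0)
    ax.imshow(masked, cmap="tab10", alpha=0.35, interpolation="nearest",
              vmin=1, vmax=max(int(label_map.max()), 1))
    ax.set_axis_off()
    fig.tight_layout(pad=0)
    fig.savefig(path)
    plt.close(fig)


def _metrics_rows(eye_id: str, visit: str, metrics: RingMetrics) -> list[dict[str, Any]]:
    rows = []
    for r in metrics.rings:
        rows.append(
            {
                "eye_id": eye_id,
                "visit": visit,
                "ring": f"R{r.ring}",
                "fd_percent": r.fd_percent,
                "fd_avg_area_um2": r.fd_avg_area_um2,
                "fd_count": r.fd_count,
                "denominator_px": r.denominator_px,
                "flagged": r.flagged,
            }
        )
    return rows


def run_cohort(config: RunConfig, write_qc: bool = True) -> dict[str, Any]:
    """Process every eye of a run and aggregate the cohort statistics.

    Per-eye failures are skipped with a logged reason; fewer than two usable
    eyes is a cohort-level error. Writes per-eye metric CSVs, lesion-area
    CSV, the per-metric comparison tables, and a JSON bundle embedding the
    run manifest (parameters, seed, package version).
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_eye: dict[str, dict[str, Any]] = {}
    skipped: dict[str, str] = {}
    for eye in config.eyes:
        try:
            per_eye[eye.eye_id] = run_eye(eye, config.parameters, out_dir if write_qc else None)
        except (GeometryError, ValueError, FileNotFoundError) as exc:
            log.warning("skipping eye %s: %s", eye.eye_id, exc)
            skipped[eye.eye_id] = str(exc)
    if len(per_eye) < 2:
        raise RuntimeError(
            f"cohort needs >= 2 usable eyes, got {len(per_eye)} "
            f"(skipped: {list(skipped) or 'none'})"
        )

    metric_rows: list[dict[str, Any]] = []
    area_rows: list[dict[str, Any]] = []
    for eye_id, rec in sorted(per_eye.items()):
        for visit in ("t1", "t2"):
            m: RingMetrics = rec[visit]
            metric_rows.extend(_metrics_rows(eye_id, visit.upper(), m))
            area_rows.append(
                {
                    "eye_id": eye_id,
                    "visit": visit.upper(),
                    "mnv_area_mm2": m.mnv_area_mm2,
                    "dh_area_mm2": m.dh_area_mm2,
                }
            )
    metrics_df = pd.DataFrame(metric_rows)
    areas_df = pd.DataFrame(area_rows)
    metrics_df.to_csv(out_dir / "ring_metrics.csv", index=False)
    areas_df.to_csv(out_dir / "lesion_areas.csv", index=False)

    tables = cohort_summary({k: {"t1": v["t1"], "t2": v["t2"]} for k, v in per_eye.items()})
    for name, df in tables.items():
        df.to_csv(out_dir / f"summary_{name}.csv")
    _write_markdown_report(out_dir / "report.md", tables, len(per_eye), skipped)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": _params_dict(config.parameters),
        "n_eyes_used": len(per_eye),
        "skipped": skipped,
    }
    stats_json = {
        "manifest": manifest,
        "tables": {name: json.loads(df.to_json(orient="index")) for name, df in tables.items()},
    }
    with open(out_dir / "statistics.json", "w") as fh:
        json.dump(stats_json, fh, indent=2, sort_keys=True)
    return {"tables": tables, "per_eye": per_eye, "skipped": skipped, "output_dir": out_dir}


def _params_dict(params: RunParameters) -> dict[str, Any]:
    d = dataclasses.asdict(params)
    return d


_TABLE_TITLES = {
    "fd_percent": "CC FD% per ring (T1 vs T2)",
    "fd_avg_area_um2": "CC FD average area per ring, um^2 (T1 vs T2)",
    "fd_count": "CC FD number per ring (T1 vs T2)",
    "lesion_areas": "Lesion areas (T1 vs T2)",
}


def _write_markdown_report(path: Path, tables: dict[str, pd.DataFrame], n_eyes: int, skipped: dict[str, str]) -> None:
    lines = [f"# Cohort report ({n_eyes} eyes)", ""]
    if skipped:
        lines += ["Skipped eyes: " + ", ".join(f"{k} ({v})" for k, v in skipped.items()), ""]
    for name, df in tables.items():
        lines += [f"## {_TABLE_TITLES.get(name, name)}", "", df.round(4).to_markdown(), ""]
    path.write_text("\n".join(lines))


# --------------------------------------------------------------------------
# phantom cohort serialization


def write_phantom_cohort(
    cohort: CohortSpec, out_dir: str | Path, write_truth: bool = True
) -> Path:
    """Generate a paired phantom cohort and write it as a runnable dataset.

    Per eye: T1/T2 angiogram + structural TIFFs, shared mask TIFFs, a truth
    sidecar JSON, and truth deficit masks; plus a top-level ``manifest.yaml``
    consumable by :func:`load_config` and a ``cohort_spec.yaml`` record.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = generate_paired_cohort(cohort)
    eyes_manifest = []
    for rec in records:
        eye_dir = out_dir / rec.eye_id
        eye_dir.mkdir(exist_ok=True)
        truth1, truth2 = rec.t1[2], rec.t2[2]
        for visit, (angio, struct, truth) in (("t1", rec.t1), ("t2", rec.t2)):
            write_image(eye_dir / f"angio_{visit}.tif", angio)
            write_image(eye_dir / f"struct_{visit}.tif", struct)
            write_mask(eye_dir / f"truth_deficit_{visit}.tif", truth.deficit_mask)
        write_mask(eye_dir / "mnv_mask.tif", truth1.mnv_mask)
        write_mask(eye_dir / "halo_mask.tif", truth1.halo_mask)
        write_mask(eye_dir / "vessel_mask.tif", truth1.vessel_mask)
        sidecar = {
            "eye_id": rec.eye_id,
            "designed_delta_points": list(rec.designed_delta_points),
            "realized_delta_points": list(rec.realized_delta_points),
            "t1_ring_truth_fractions": list(truth1.ring_truth_fractions),
            "t2_ring_truth_fractions": list(truth2.ring_truth_fractions),
            "t1_component_count_per_ring": list(truth1.component_count_per_ring),
            "t2_component_count_per_ring": list(truth2.component_count_per_ring),
        }
        if write_truth:
            with open(eye_dir / "truth.json", "w") as fh:
                json.dump(sidecar, fh, indent=2)
        eyes_manifest.append(
            {
                "id": rec.eye_id,
                "t1": {
                    "angiogram": f"{rec.eye_id}/angio_t1.tif",
                    "structural": f"{rec.eye_id}/struct_t1.tif",
                    "truth_deficit": f"{rec.eye_id}/truth_deficit_t1.tif",
                },
                "t2": {
                    "angiogram": f"{rec.eye_id}/angio_t2.tif",
                    "structural": f"{rec.eye_id}/struct_t2.tif",
                    "truth_deficit": f"{rec.eye_id}/truth_deficit_t2.tif",
                },
                "mnv_mask": f"{rec.eye_id}/mnv_mask.tif",
                "halo_mask": f"{rec.eye_id}/halo_mask.tif",
                "vessel_mask": f"{rec.eye_id}/vessel_mask.tif",
            }
        )
    spec = cohort.t1_spec
    manifest = {
        "seed": cohort.seed,
        "output_dir": "results",
        "parameters": {
            "pixel_pitch_um": spec.pixel_pitch_um,
            "ring_width_um": spec.ring_width_um,
            "n_rings": spec.n_rings,
            "min_margin_um": spec.min_margin_um,
        },
        "eyes": eyes_manifest,
    }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    with open(out_dir / "cohort_spec.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "n_eyes": cohort.n_eyes,
                "fd_percent_delta_per_ring": list(cohort.fd_percent_delta_per_ring),
                "split_factor": cohort.split_factor,
                "between_eye_sd": cohort.between_eye_sd,
                "seed": cohort.seed,
                "t1_spec": {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in dataclasses.asdict(spec).items()},
            },
            fh,
            sort_keys=False,
        )
    return out_dir / "manifest.yaml"
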
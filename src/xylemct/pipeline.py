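"""End-to-end orchestration: simulate -> segment -> anatomy -> PLC -> fit.

The pipeline is fully deterministic given its configuration: every
stochastic stage draws from seeds derived from the single top-level
``seed`` via ``numpy.random.SeedSequence``, and the summary JSON is
serialised with sorted keys so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anatomy import compute_anatomy
from .errors import ValidationError, XylemCTError
from .hydraulics import FluidProperties, plc_theoretical
from .io import (thresholds_table, write_conduit_map, write_curve_points,
                 write_curves_json, write_image, write_ground_truth_frame)
from .segmentation import SegmentationSettings, match_scan_pair, segment_air_conduits
from .synthetic import (OrganSimConfig, generate_cross_section,
                        generate_final_scan, organ_preset)
from .vulnerability import compare_curves, fit_curve

log = logging.getLogger("xylemct")

_ORGAN_KEYS = {"label", "preset", "n_plants", "psi_min", "psi_max",
               "noise_sd", "image_size_px", "pixel_size_um"}
_TOP_KEYS = {"seed", "out_dir", "n_boot", "log_level", "organs",
             "segmentation", "fluid", "compare", "match_tol_um", "image_format"}
_SEG_KEYS = {"method", "threshold", "min_area_um2", "min_circularity",
             "connectivity"}
_FLUID_KEYS = {"density_kg_m3", "viscosity_pa_s", "temperature_c"}


@dataclass
class OrganRun:
    """One simulated dehydration experiment for one organ."""

    label: str
    preset: str
    n_plants: int = 10
    psi_min: float = -5.0
    psi_max: float = -0.1
    noise_sd: float = 0.0
    image_size_px: tuple[int, int] = (500, 500)
    pixel_size_um: float = 2.0

    def build_config(self, seed: int) -> OrganSimConfig:
        return organ_preset(
            self.preset,
            image_size_px=tuple(self.image_size_px),
            pixel_size_um=self.pixel_size_um,
            noise_sd=self.noise_sd,
            seed=seed,
        )


@dataclass
class PipelineConfig:
    """Validated top-level configuration (see ``configs/demo.yaml``)."""

    seed: int
    organs: list[OrganRun]
    out_dir: str = "xylemct_out"
    n_boot: int = 300
    segmentation: SegmentationSettings = field(default_factory=SegmentationSettings)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    compare: list[tuple[str, str, str]] = field(default_factory=list)
    match_tol_um: float = 5.0
    image_format: str = "tif"
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValidationError("config must set an explicit top-level seed")
        if "organs" not in raw or not raw["organs"]:
            raise ValidationError("config must list at least one organ")
        organs = []
        for entry in raw["organs"]:
            bad = set(entry) - _ORGAN_KEYS
            if bad:
                raise ValidationError(
                    f"organ {entry.get('label', '?')}: unknown keys {sorted(bad)}")
            if "preset" not in entry:
                raise ValidationError("each organ entry needs a preset name")
            entry = dict(entry)
            entry.setdefault("label", entry["preset"])
            organs.append(OrganRun(**entry))
        seg_raw = raw.get("segmentation", {})
        bad = set(seg_raw) - _SEG_KEYS
        if bad:
            raise ValidationError(f"unknown segmentation keys: {sorted(bad)}")
        fluid_raw = raw.get("fluid", {})
        bad = set(fluid_raw) - _FLUID_KEYS
        if bad:
            raise ValidationError(f"unknown fluid keys: {sorted(bad)}")
        compare = [tuple(c) for c in raw.get("compare", [])]
        for c in compare:
            if len(c) != 3 or c[2] not in ("psi12", "psi50", "psi88"):
                raise ValidationError(
                    f"compare entries must be [organ_a, organ_b, psi12|psi50|psi88]: {c}")
        return cls(
            seed=int(raw["seed"]),
            organs=organs,
            out_dir=str(raw.get("out_dir", "xylemct_out")),
            n_boot=int(raw.get("n_boot", 300)),
            segmentation=SegmentationSettings(**seg_raw),
            fluid=FluidProperties(**fluid_raw),
            compare=compare,
            match_tol_um=float(raw.get("match_tol_um", 5.0)),
            image_format=str(raw.get("image_format", "tif")),
            log_level=str(raw.get("log_level", "INFO")),
        )


def _stage(name: str, item: str):
    """Context wrapper that prefixes stage/input information onto errors."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, XylemCTError):
                raise type(exc)(f"[stage {name}, input {item}] {exc}") from exc
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full simulated experiment and write all artifacts.

    Per organ and plant: simulate an initial and a final (fully embolised)
    cross-section, segment both, match the scans, and compute theoretical
    PLC; then fit the vulnerability curve with bootstrap thresholds and
    evaluate the configured comparisons. Returns the summary dict that is
    also written to ``summary.json``.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "conduits").mkdir(exist_ok=True)
    (out / "images").mkdir(exist_ok=True)
    logging.basicConfig(level=config.log_level)

    root_seq = np.random.SeedSequence(config.seed)
    organ_seqs = root_seq.spawn(len(config.organs))

    curves = {}
    all_points = []
    anatomy_rows = []
    for organ_idx, organ in enumerate(config.organs):
        plant_seqs = organ_seqs[organ_idx].spawn(organ.n_plants)
        psis = np.linspace(organ.psi_min, organ.psi_max, organ.n_plants)
        sim_config = organ.build_config(seed=config.seed)
        region_mask = sim_config.xylem_region.mask(
            sim_config.image_size_px, sim_config.pixel_size_um)
        rows = []
        for i, (psi, seq) in enumerate(zip(psis, plant_seqs)):
            sample_id = f"{organ.label}_{i:02d}"
            with _stage("simulate", sample_id):
                image, truth = generate_cross_section(sim_config, float(psi), seed=seq)
                final_image = generate_final_scan(truth, sim_config, seed=seq)
            with _stage("segment", sample_id):
                initial_map = segment_air_conduits(
                    image, sim_config.pixel_size_um, config.segmentation,
                    region_mask=region_mask,
                    xylem_area_mm2=truth.xylem_area_mm2,
                    image_id=f"{sample_id}_initial")
                final_map = segment_air_conduits(
                    final_image, sim_config.pixel_size_um, config.segmentation,
                    region_mask=region_mask,
                    xylem_area_mm2=truth.xylem_area_mm2,
                    image_id=f"{sample_id}_final")
            with _stage("plc", sample_id):
                pair = match_scan_pair(initial_map, final_map,
                                       tol_um=config.match_tol_um, psi_mpa=float(psi))
                plc = plc_theoretical(pair, config.fluid)
            log.info("%s: psi=%.2f MPa, %d/%d conduits embolised, PLC_t=%.1f%% "
                     "(threshold applied %.3f)",
                     sample_id, psi, len(pair.embolised_ids), len(final_map),
                     plc, initial_map.settings.get("threshold_applied", float("nan")))
            write_image(out / "images" / f"{sample_id}_initial.{config.image_format}",
                        image)
            write_image(out / "images" / f"{sample_id}_final.{config.image_format}",
                        final_image)
            write_ground_truth_frame(out / "conduits" / f"{sample_id}_truth.csv",
                                     truth.to_frame())
            write_conduit_map(out / "conduits" / f"{sample_id}_initial.csv", initial_map)
            write_conduit_map(out / "conduits" / f"{sample_id}_final.csv", final_map)
            rows.append({"sample_id": sample_id, "organ": organ.label,
                         "method": "microct", "psi_mpa": float(psi),
                         "plc_pct": plc})
            stats = compute_anatomy(final_map)
            anatomy_rows.append({"sample_id": sample_id, "organ": organ.label,
                                 "mean_d_um": stats.mean_d_um,
                                 "d_h_um": stats.d_h_um,
                                 "vd_per_mm2": stats.vd_per_mm2,
                                 "n_conduits": stats.n_conduits})
        points = pd.DataFrame(rows)
        all_points.append(points)
        with _stage("fit", organ.label):
            curves[organ.label] = fit_curve(
                points, organ.label, "microct", n_boot=config.n_boot,
                seed=config.seed * 1000 + organ_idx)

    write_curve_points(out / "curve_points.csv", pd.concat(all_points))
    pd.DataFrame(anatomy_rows).to_csv(out / "anatomy.csv", index=False)
    write_curves_json(out / "curves.json", list(curves.values()))
    thresholds_table(list(curves.values())).to_csv(out / "thresholds.csv", index=False)

    comparisons = []
    for organ_a, organ_b, threshold in config.compare:
        with _stage("compare", f"{organ_a} vs {organ_b}"):
            for name in (organ_a, organ_b):
                if name not in curves:
                    raise ValidationError(f"compare references unknown organ {name!r}")
            comparisons.append(dataclasses.asdict(
                compare_curves(curves[organ_a], curves[organ_b], threshold)
            ) | {"organ_a": organ_a, "organ_b": organ_b})

    summary = {
        "version": __version__,
        "seed": config.seed,
        "n_boot": config.n_boot,
        "segmentation": dataclasses.asdict(config.segmentation),
        "fluid": dataclasses.asdict(config.fluid),
        "organs": {label: {
            "fit": dataclasses.asdict(c.fit) if c.fit else None,
            "thresholds": (
                dataclasses.asdict(c.thresholds) | {
                    "ci": {k: list(v) for k, v in c.thresholds.ci.items()}}
                if c.thresholds else None),
            "n_points": int(len(c.points)),
        } for label, c in curves.items()},
        "comparisons": comparisons,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (out / "run.log").write_text(
        f"xylemct {__version__}\nnumpy {np.__version__}\npandas {pd.__version__}\n"
        f"seed {config.seed}\n")
    return summary
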
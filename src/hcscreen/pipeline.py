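"""End-to-end orchestration: simulate -> (render/segment/measure) -> QC ->
hit calling -> cascade report, with reproducible seeds and manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .hitcall import (
    CLASSES,
    calls_to_frame,
    cascade_report,
    classify_compounds,
    stages_from_calls,
    well_zscores,
)
from .imaging import (
    SegmentationParams,
    field_background,
    measure_cells,
    segment_field,
    summaries_to_frame,
    summarize_well,
)
from .screenqc import QcThresholds, gate_plates, qc_from_well_table
from .synthgen import (
    ROLE_COMPOUND,
    ROLE_NEGATIVE,
    ROLE_POSITIVE,
    CompoundEffect,
    GenotypePreset,
    make_layout,
    preset_pair,
    render_field,
    simulate_well_table,
)

PLATE_CAPACITY = {96: 96, 384: 384}


@dataclass
class RunConfig:
    """Configuration for a simulated screen run.

    All thresholds default to the screening constants: activity at 3 SD,
    toxicity at 2 SD, robust Z' >= 0.3, SSMD >= 3, CV <= 10%, driver
    correlation 0.75.
    """

    out_dir: str = "runs/demo"
    mode: str = "tabular"  # "tabular" or "images"
    preset_stage: str = "fibroblast_primary"
    plate_format: int = 384
    n_controls_per_role: int = 16
    n_compounds: int = 1000
    screen_dose_um: float = 10.0
    active_fraction: float = 0.02
    toxic_fraction: float = 0.03
    artifact_fraction: float = 0.005
    seed: int = 0
    active_sd: float = 3.0
    toxic_sd: float = 2.0
    z_prime_min: float = 0.3
    ssmd_min: float = 3.0
    cv_max: float = 10.0
    driver_r: float = 0.75
    min_cells: int = 20
    # images mode only
    n_cells_per_field: int = 24
    image_shape: tuple[int, int] = (384, 384)

    def __post_init__(self) -> None:
        if self.mode not in ("tabular", "images"):
            raise ConfigurationError("mode must be 'tabular' or 'images'")
        for name in ("active_sd", "toxic_sd", "ssmd_min", "cv_max", "driver_r"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_shape"] = list(d["image_shape"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "image_shape" in d:
            d["image_shape"] = tuple(d["image_shape"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def config_hash(config: RunConfig) -> str:
    payload = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def plan_effects(config: RunConfig) -> dict[str, CompoundEffect]:
    """Deterministically plant compound classes per the configured fractions."""
    rng = np.random.default_rng(config.seed + 1)
    effects = {}
    for i in range(config.n_compounds):
        cid = f"CPD{i + 1:06d}"
        u = rng.random()
        if u < config.active_fraction:
            effects[cid] = CompoundEffect(cid, efficacy=1.0, ec50=0.5, hill=1.5)
        elif u < config.active_fraction + config.toxic_fraction:
            effects[cid] = CompoundEffect(cid, efficacy=0.0, tox_ec50=config.screen_dose_um / 2)
        elif u < config.active_fraction + config.toxic_fraction + config.artifact_fraction:
            effects[cid] = CompoundEffect(cid, efficacy=0.0, autofluorescent=True)
        else:
            effects[cid] = CompoundEffect(cid, efficacy=0.0)
    return effects


def _plate_layouts(config: RunConfig):
    """Chunk compounds into as many plates as needed."""
    per_plate = PLATE_CAPACITY[config.plate_format] - 2 * config.n_controls_per_role
    if per_plate <= 0:
        raise ConfigurationError("controls fill the whole plate")
    cids = [f"CPD{i + 1:06d}" for i in range(config.n_compounds)]
    for start in range(0, len(cids), per_plate):
        chunk = cids[start : start + per_plate]
        yield make_layout(
            config.plate_format,
            config.n_controls_per_role,
            [(cid, config.screen_dose_um) for cid in chunk],
        )


def _simulate_tabular(
    config: RunConfig,
    presets: dict[str, GenotypePreset],
    effects: dict[str, CompoundEffect],
) -> pd.DataFrame:
    frames = []
    for p, layout in enumerate(_plate_layouts(config)):
        df = simulate_well_table(
            layout, presets, effects, n_plates=1, seed=config.seed + 100 + p
        )
        df["plate"] = f"P{p + 1:03d}"
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _simulate_images(
    config: RunConfig,
    presets: dict[str, GenotypePreset],
    effects: dict[str, CompoundEffect],
) -> pd.DataFrame:
    """Rendered-image path: one field per well, segmented and measured."""
    seg_params = SegmentationParams()
    rng = np.random.default_rng(config.seed + 7)
    summaries = []
    for p, layout in enumerate(_plate_layouts(config)):
        plate_id = f"P{p + 1:03d}"
        for i, rec in enumerate(layout.wells.itertuples(index=False)):
            if rec.role == ROLE_COMPOUND:
                preset, effect, dose = presets[ROLE_NEGATIVE], effects[rec.compound_id], rec.dose_um
            else:
                preset, effect, dose = presets[rec.role], None, None
            # Poisson well-to-well variation in plated cells, clipped so
            # placement stays feasible at the configured field size
            n_cells = int(
                np.clip(rng.poisson(config.n_cells_per_field), 2, int(1.5 * config.n_cells_per_field))
            )
            fld, _ = render_field(
                preset,
                effect,
                dose,
                n_cells=n_cells,
                image_shape=config.image_shape,
                seed=config.seed + 10_000 * (p + 1) + i,
                well=rec.well,
            )
            seg = segment_field(fld, seg_params)
            cells = measure_cells(fld, seg, compute_features=True)
            summaries.append(
                summarize_well(
                    cells,
                    well=rec.well,
                    role=rec.role,
                    compound_id=rec.compound_id,
                    dose_um=dose,
                    background=field_background(fld, seg),
                    min_cells=config.min_cells,
                    plate=plate_id,
                )
            )
    return summaries_to_frame(summaries)


def run_screen_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> QC -> hit-calling and write all stage outputs.

    Returns a dict with the run directory, per-stage artifacts and the
    cascade report.  Rerunning with an identical config reproduces the
    tabular outputs bit for bit.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    timings: dict[str, float] = {}

    disease, control = preset_pair(config.preset_stage)
    presets = {ROLE_NEGATIVE: disease, ROLE_POSITIVE: control}
    effects = plan_effects(config)

    t0 = time.perf_counter()
    if config.mode == "tabular":
        wells = _simulate_tabular(config, presets, effects)
    else:
        wells = _simulate_images(config, presets, effects)
    timings["simulate_s"] = time.perf_counter() - t0
    wells.to_csv(out / "wells.csv", index=False)

    t0 = time.perf_counter()
    thresholds = QcThresholds(config.z_prime_min, config.ssmd_min, config.cv_max)
    qc = qc_from_well_table(wells, thresholds)
    passed, qc_summary = gate_plates(qc, thresholds)
    timings["qc_s"] = time.perf_counter() - t0
    pd.DataFrame([vars(q) for q in qc]).to_csv(out / "qc.csv", index=False)
    passing_plates = {q.plate for q in passed}
    kept = wells[wells["plate"].isin(passing_plates)]

    t0 = time.perf_counter()
    z = well_zscores(kept)
    calls = classify_compounds(z, active_sd=config.active_sd, toxic_sd=config.toxic_sd)
    stage = stages_from_calls(calls, stage_name="primary")
    cascade = cascade_report([stage])
    timings["hits_s"] = time.perf_counter() - t0
    calls_to_frame(calls).to_csv(out / "calls.csv", index=False)

    cascade_payload = [dataclasses.asdict(r) for r in cascade]
    (out / "cascade.json").write_text(json.dumps(cascade_payload, indent=2))
    manifest = {
        "config": config.to_dict(),
        "config_hash": chash,
        "seed": config.seed,
        "version": __version__,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "n_plates": int(wells["plate"].nunique()),
        "qc": qc_summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    truth = wells[wells["role"] == ROLE_COMPOUND][["compound_id", "planted_class"]] if "planted_class" in wells else None
    return {
        "out_dir": str(out),
        "config_hash": chash,
        "wells": wells,
        "qc": qc,
        "qc_summary": qc_summary,
        "calls": calls,
        "cascade": cascade_payload,
        "class_counts": {c: sum(1 for k in calls if k.classification == c) for c in CLASSES},
        "truth": truth,
    }
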
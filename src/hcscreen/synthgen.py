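"""Synthetic screen generation: plate layouts, tabular well-level screens,
and rendered multichannel fields with ground truth.

Printed control summary statistics from the assay stages are used as
calibration targets.  The printed per-well SDs pool within-plate and
between-plate variability, so each preset decomposes the pooled SD into a
within-plate component ``well_sd = pooled/3`` and a between-plate component
``plate_sd = pooled * sqrt(1 - 1/9)``; pooled statistics then match print
while individual plates remain tight enough to pass the QC gates.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field as dc_field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse

from .errors import CapacityError, ConfigurationError, PlacementError
from .imaging import CHANNEL_NAMES, FieldImage

ROLE_NEGATIVE = "negative_control"
ROLE_POSITIVE = "positive_control"
ROLE_COMPOUND = "compound"

PLATE_FORMATS = {96: (8, 12), 384: (16, 24)}

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# presets and compound effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypePreset:
    """Generative parameters for one genotype/cell-model condition."""

    name: str
    true_ratio: float
    cell_sd: float
    well_sd: float
    plate_sd: float
    mean_cells_per_well: float

    def __post_init__(self) -> None:
        if self.true_ratio <= 0:
            raise ConfigurationError("true_ratio must be positive")
        if min(self.cell_sd, self.well_sd, self.plate_sd) < 0:
            raise ConfigurationError("SDs must be nonnegative")
        if self.mean_cells_per_well <= 0:
            raise ConfigurationError("mean_cells_per_well must be positive")

    @property
    def pooled_well_sd(self) -> float:
        """SD of per-well means pooled across plates."""
        return math.hypot(self.well_sd, self.plate_sd)


def decompose_pooled_sd(pooled_sd: float) -> tuple[float, float]:
    """Split a pooled per-well SD into (well_sd, plate_sd) defaults."""
    well_sd = pooled_sd / 3.0
    plate_sd = pooled_sd * math.sqrt(1.0 - 1.0 / 9.0)
    return well_sd, plate_sd


def _preset(name: str, ratio: float, pooled_sd: float, cells: float) -> GenotypePreset:
    well_sd, plate_sd = decompose_pooled_sd(pooled_sd)
    return GenotypePreset(
        name=name,
        true_ratio=ratio,
        cell_sd=0.15 * ratio,
        well_sd=well_sd,
        plate_sd=plate_sd,
        mean_cells_per_well=cells,
    )


#: Calibrated (disease, control) preset pairs per assay stage.  The disease
#: genotype is always the higher-ratio condition; the primary-screen pair is
#: stored in that orientation as well (see package notes on label direction).
PRESET_PAIRS: dict[str, tuple[GenotypePreset, GenotypePreset]] = {
    "fibroblast_primary": (
        _preset("fibroblast_primary_disease", 1.34, 0.05, 400),
        _preset("fibroblast_primary_control", 1.10, 0.02, 400),
    ),
    "fibroblast_secondary": (
        _preset("fibroblast_secondary_disease", 1.40, 0.07, 400),
        _preset("fibroblast_secondary_control", 1.12, 0.02, 400),
    ),
    "neuroblastoma_cargo": (
        _preset("neuroblastoma_cargo_disease", 1.80, 0.06, 300),
        _preset("neuroblastoma_cargo_control", 1.17, 0.03, 300),
    ),
    "neuroblastoma_alt_cargo": (
        _preset("neuroblastoma_alt_cargo_disease", 1.80, 0.10, 300),
        _preset("neuroblastoma_alt_cargo_control", 1.36, 0.07, 300),
    ),
    "neuron": (
        _preset("neuron_disease", 4.31, 0.40, 150),
        _preset("neuron_control", 1.56, 0.12, 150),
    ),
}


def preset_pair(stage: str) -> tuple[GenotypePreset, GenotypePreset]:
    """(disease, control) presets for a named assay stage."""
    try:
        return PRESET_PAIRS[stage]
    except KeyError as exc:
        raise ConfigurationError(f"unknown preset stage {stage!r}") from exc


@dataclass(frozen=True)
class CompoundEffect:
    """Generative dose-response behaviour of one compound."""

    compound_id: str
    efficacy: float = 0.0  # fraction of (disease - control) gap removed at saturation
    ec50: float = 1.0  # uM
    hill: float = 1.5
    tox_ec50: float | None = None  # uM, dose halving expected cell count
    autofluorescent: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficacy <= 1.0:
            raise ConfigurationError("efficacy must be in [0, 1]")
        if self.ec50 <= 0:
            raise ConfigurationError("ec50 must be positive")
        if self.hill == 0:
            raise ConfigurationError("hill must be nonzero")
        if self.tox_ec50 is not None and self.tox_ec50 <= 0:
            raise ConfigurationError("tox_ec50 must be positive")


def effective_ratio(
    preset: GenotypePreset, effect: CompoundEffect | None = None, dose: float | None = None
) -> float:
    """Expected cargo ratio at ``dose``: the 4PL-shaped fraction of the
    disease-to-1 gap removed, or ``true_ratio`` without compound."""
    if effect is None or dose is None or dose == 0:
        return preset.true_ratio
    h = abs(effect.hill)
    frac = dose**h / (dose**h + effect.ec50**h)
    return preset.true_ratio - effect.efficacy * (preset.true_ratio - 1.0) * frac


def survival_fraction(effect: CompoundEffect | None, dose: float | None) -> float:
    """Expected surviving cell fraction: exponential with half-kill at tox_ec50."""
    if effect is None or effect.tox_ec50 is None or not dose:
        return 1.0
    return math.exp(-LN2 * (dose / effect.tox_ec50) ** abs(effect.hill))


def planted_class(
    preset: GenotypePreset, effect: CompoundEffect | None, dose: float | None
) -> str:
    """Ground-truth classification of a compound well at a dose.

    active: expected ratio reduction of at least 3 within-plate well SDs;
    toxic: expected cell-count reduction of at least 2 Poisson SDs;
    artifact overrides both (the generator plants a ratio bias there).
    """
    if effect is None:
        return "inactive"
    if effect.autofluorescent:
        return "artifact"
    reduction = preset.true_ratio - effective_ratio(preset, effect, dose)
    active = reduction >= 3.0 * preset.well_sd
    kill = preset.mean_cells_per_well * (1.0 - survival_fraction(effect, dose))
    toxic = kill >= 2.0 * math.sqrt(preset.mean_cells_per_well)
    if active and toxic:
        return "active_toxic"
    if active:
        return "active"
    if toxic:
        return "toxic"
    return "inactive"


# ---------------------------------------------------------------------------
# layouts
# ---------------------------------------------------------------------------

def titration_doses(low: float = 0.04, high: float = 40.0, n: int = 11) -> list[float]:
    """Halving dose ladder anchored at ``high``, rounded half-up to 2 decimals.

    Defaults reproduce the 11-point 0.04-40 uM ladder:
    0.04, 0.08, 0.16, 0.31, 0.63, 1.25, 2.5, 5, 10, 20, 40.
    """
    if low <= 0 or high <= low or n < 2:
        raise ConfigurationError("need 0 < low < high and n >= 2")
    raw = [high / 2 ** (n - 1 - i) for i in range(n)]
    if raw[0] < low / 2:
        raise ConfigurationError("halving ladder from high undershoots low")
    return [float(Decimal(str(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)) for x in raw]


def well_name(row: int, col: int) -> str:
    return f"{string.ascii_uppercase[row]}{col + 1:02d}"


@dataclass
class PlateLayout:
    """Deterministic well-to-role/compound assignment for one plate format."""

    format: int
    wells: pd.DataFrame  # columns: well, row, col, role, compound_id, dose_um

    def __post_init__(self) -> None:
        if self.format not in PLATE_FORMATS:
            raise ConfigurationError(f"unsupported plate format {self.format}")

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    def role_wells(self, role: str) -> pd.DataFrame:
        return self.wells[self.wells["role"] == role]


def make_layout(
    format: int,
    n_control_wells_per_role: int,
    compound_assignments: list[tuple[str, float]],
) -> PlateLayout:
    """Build a plate layout with edge-column controls and row-major compounds.

    Controls fill the outermost columns (1, last, 2, second-to-last, ...)
    top to bottom, alternating negative/positive well by well.  Compound
    wells are assigned row-major over the remaining positions.
    """
    if format not in PLATE_FORMATS:
        raise ConfigurationError(f"unsupported plate format {format}")
    n_rows, n_cols = PLATE_FORMATS[format]
    capacity = n_rows * n_cols
    n_ctrl = 2 * n_control_wells_per_role
    if n_ctrl + len(compound_assignments) > capacity:
        raise CapacityError(
            f"{n_ctrl} control + {len(compound_assignments)} compound wells "
            f"exceed {format}-well capacity"
        )
    for cid, dose in compound_assignments:
        if dose is not None and dose <= 0:
            raise ConfigurationError(f"nonpositive dose for {cid!r}")

    col_order: list[int] = []
    lo, hi = 0, n_cols - 1
    while lo <= hi:
        col_order.append(lo)
        if hi != lo:
            col_order.append(hi)
        lo += 1
        hi -= 1
    control_positions = [(r, c) for c in col_order for r in range(n_rows)]
    if n_ctrl > len(control_positions):
        raise CapacityError("too many control wells for plate")

    rows = []
    used: set[tuple[int, int]] = set()
    for i in range(n_ctrl):
        r, c = control_positions[i]
        role = ROLE_NEGATIVE if i % 2 == 0 else ROLE_POSITIVE
        rows.append((well_name(r, c), r, c, role, None, None))
        used.add((r, c))
    free = [(r, c) for r in range(n_rows) for c in range(n_cols) if (r, c) not in used]
    for (cid, dose), (r, c) in zip(compound_assignments, free):
        rows.append((well_name(r, c), r, c, ROLE_COMPOUND, cid, dose))
    wells = pd.DataFrame(
        rows, columns=["well", "row", "col", "role", "compound_id", "dose_um"]
    ).sort_values(["row", "col"], ignore_index=True)
    return PlateLayout(format=format, wells=wells)


def titration_assignments(
    compound_ids: list[str], doses: list[float]
) -> list[tuple[str, float]]:
    """Expand compounds x doses into layout assignments (compound-major)."""
    return [(cid, d) for cid in compound_ids for d in doses]


# ---------------------------------------------------------------------------
# tabular fast path
# ---------------------------------------------------------------------------

def simulate_well_table(
    layout: PlateLayout,
    presets: dict[str, GenotypePreset],
    effects: dict[str, CompoundEffect],
    n_plates: int = 1,
    seed: int = 0,
    background_mean: float = 50.0,
    background_sd: float = 2.0,
    af_gain: float = 0.05,
) -> pd.DataFrame:
    """Simulate per-well measurements for ``n_plates`` copies of a layout.

    Compound wells use the negative-control (disease) genotype.  Per plate a
    shared standard-normal offset scales with each preset's ``plate_sd``;
    ratios are Normal(r_eff + offset, well_sd); cell counts are Poisson with
    exponential dose-dependent survival; autofluorescent compounds receive a
    dose-scaled additive cargo offset that inflates the background and biases
    the ratio toward 1.
    """
    for role in (ROLE_NEGATIVE, ROLE_POSITIVE):
        if role not in presets:
            raise ConfigurationError(f"missing preset for role {role!r}")
    cids = set(layout.wells.loc[layout.wells["role"] == ROLE_COMPOUND, "compound_id"])
    missing = sorted(c for c in cids if c not in effects)
    if missing:
        raise ConfigurationError(f"missing CompoundEffect for: {missing[:5]}")

    rng = np.random.default_rng(seed)
    records = []
    for p in range(n_plates):
        plate_id = f"P{p + 1:03d}"
        plate_u = rng.standard_normal()
        for rec in layout.wells.itertuples(index=False):
            if rec.role == ROLE_COMPOUND:
                preset = presets[ROLE_NEGATIVE]
                effect = effects[rec.compound_id]
                dose = rec.dose_um
            else:
                preset = presets[rec.role]
                effect, dose = None, None
            r_eff = effective_ratio(preset, effect, dose)
            bg_mu = background_mean
            if effect is not None and effect.autofluorescent and dose:
                a = af_gain * dose
                r_eff = (r_eff + a) / (1.0 + a)
                bg_mu = background_mean * (1.0 + a)
            ratio = rng.normal(r_eff + plate_u * preset.plate_sd, preset.well_sd)
            count = int(
                rng.poisson(preset.mean_cells_per_well * survival_fraction(effect, dose))
            )
            bg = rng.normal(bg_mu, background_sd)
            records.append(
                {
                    "plate": plate_id,
                    "well": rec.well,
                    "row": rec.row,
                    "col": rec.col,
                    "role": rec.role,
                    "compound_id": rec.compound_id,
                    "dose_um": dose,
                    "mean_ratio": ratio,
                    "cell_count": count,
                    "background_intensity": bg,
                    "true_ratio": r_eff,
                    "planted_class": planted_class(preset, effect, dose),
                }
            )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# rendered fields
# ---------------------------------------------------------------------------

@dataclass
class RenderParams:
    """Geometry, intensity and noise settings for field rendering."""

    cell_axis_range: tuple[float, float] = (16.0, 26.0)
    nucleus_scale: float = 0.45
    tgn_scale_range: tuple[float, float] = (0.45, 0.75)  # of nucleus axes
    margin: int = 4
    max_retries: int = 300
    background: float = 3.0
    nucleus_intensity: float = 120.0
    body_intensity: float = 60.0
    tgn_intensity: float = 150.0
    cargo_base: float = 80.0
    blur_sigma: float = 0.6
    read_noise_sd: float = 2.0
    min_cell_ratio: float = 0.05


@dataclass
class GroundTruth:
    """Planted truth accompanying a rendered field."""

    cells: pd.DataFrame  # cell_id, centroid_row/col, planted_ratio, areas
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    tgn_labels: np.ndarray
    well: dict = dc_field(default_factory=dict)


def render_field(
    preset: GenotypePreset,
    effect: CompoundEffect | None = None,
    dose: float | None = None,
    n_cells: int = 20,
    image_shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    params: RenderParams | None = None,
    well: str = "",
    field_index: int = 0,
) -> tuple[FieldImage, GroundTruth]:
    """Render one multichannel field of non-overlapping elliptical cells.

    Each cell carries an interior nucleus ellipse and a perinuclear TGN blob
    covering roughly 5-15% of the cell area.  The cargo channel is flat at
    ``cargo_base`` in the cytoplasm and ``r_i * cargo_base`` in the TGN,
    with per-cell ratio ``r_i ~ Normal(r_eff, cell_sd)``; Poisson shot noise
    plus Gaussian read noise is added on top of a light blur.
    """
    if params is None:
        params = RenderParams()
    h, w = image_shape
    if h < 64 or w < 64:
        raise ConfigurationError("image_shape must be at least 64x64")
    if n_cells < 0:
        raise ConfigurationError("n_cells must be nonnegative")
    rng = np.random.default_rng(seed)
    r_eff = effective_ratio(preset, effect, dose)

    nuc_ch = np.zeros(image_shape)
    body_ch = np.zeros(image_shape)
    tgn_ch = np.zeros(image_shape)
    cargo_ch = np.zeros(image_shape)
    nucleus_labels = np.zeros(image_shape, dtype=np.int32)
    cell_labels = np.zeros(image_shape, dtype=np.int32)
    tgn_labels = np.zeros(image_shape, dtype=np.int32)
    occupied = np.zeros(image_shape, dtype=bool)

    rows = []
    for cid in range(1, n_cells + 1):
        placed = False
        for _ in range(params.max_retries):
            a = rng.uniform(*params.cell_axis_range)
            b = rng.uniform(*params.cell_axis_range)
            theta = rng.uniform(0, math.pi)
            amax = max(a, b) + params.margin
            if 2 * amax >= min(h, w):
                continue
            r0 = rng.uniform(amax, h - amax)
            c0 = rng.uniform(amax, w - amax)
            rr, cc = draw_ellipse(r0, c0, a, b, shape=image_shape, rotation=theta)
            if occupied[rr, cc].any():
                continue
            # reserve a margin so neighbouring cells stay separable
            rm, cm = draw_ellipse(
                r0, c0, a + params.margin, b + params.margin,
                shape=image_shape, rotation=theta,
            )
            occupied[rm, cm] = True
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {cid} of {n_cells} after "
                f"{params.max_retries} retries"
            )

        cell_labels[rr, cc] = cid
        body_ch[rr, cc] = params.body_intensity

        na, nb = a * params.nucleus_scale, b * params.nucleus_scale
        nrr, ncc = draw_ellipse(r0, c0, na, nb, shape=image_shape, rotation=theta)
        nucleus_labels[nrr, ncc] = cid
        nuc_ch[nrr, ncc] = params.nucleus_intensity

        # perinuclear TGN blob: small ellipse centred just outside the nucleus
        phi = rng.uniform(0, 2 * math.pi)
        off = 1.25 * max(na, nb)
        tr0 = r0 + off * math.sin(phi)
        tc0 = c0 + off * math.cos(phi)
        ts = rng.uniform(*params.tgn_scale_range)
        trr, tcc = draw_ellipse(
            tr0, tc0, max(2.0, na * ts), max(2.0, nb * ts),
            shape=image_shape, rotation=theta,
        )
        tmask = np.zeros(image_shape, dtype=bool)
        tmask[trr, tcc] = True
        tmask &= (cell_labels == cid) & (nucleus_labels != cid)
        if not tmask.any():  # fall back to a blob at the nucleus edge
            trr, tcc = draw_ellipse(
                r0 + na, c0, max(2.0, na * 0.5), max(2.0, nb * 0.5), shape=image_shape
            )
            tmask[trr, tcc] = True
            tmask &= (cell_labels == cid) & (nucleus_labels != cid)
        tgn_labels[tmask] = cid
        tgn_ch[tmask] = params.tgn_intensity

        ratio_i = max(rng.normal(r_eff, preset.cell_sd), params.min_cell_ratio)
        cmask = cell_labels == cid
        cargo_ch[cmask & ~tmask] = params.cargo_base
        cargo_ch[tmask] = ratio_i * params.cargo_base

        rows.append(
            {
                "cell_id": cid,
                "centroid_row": r0,
                "centroid_col": c0,
                "planted_ratio": ratio_i,
                "cell_area": int(cmask.sum()),
                "nucleus_area": int((nucleus_labels == cid).sum()),
                "tgn_area": int(tmask.sum()),
            }
        )

    channels = np.stack([nuc_ch, body_ch, tgn_ch, cargo_ch]) + params.background
    if params.blur_sigma > 0:
        for i in range(4):
            channels[i] = gaussian_filter(channels[i], params.blur_sigma)
    channels = rng.poisson(channels).astype(float)
    channels += rng.normal(0.0, params.read_noise_sd, size=channels.shape)
    channels = np.clip(channels, 0.0, None)

    field = FieldImage(
        channels=channels, channel_names=CHANNEL_NAMES, well=well, field_index=field_index
    )
    cells_df = pd.DataFrame(
        rows,
        columns=[
            "cell_id", "centroid_row", "centroid_col", "planted_ratio",
            "cell_area", "nucleus_area", "tgn_area",
        ],
    )
    truth = GroundTruth(
        cells=cells_df,
        nucleus_labels=nucleus_labels,
        cell_labels=cell_labels,
        tgn_labels=tgn_labels,
        well={
            "well": well,
            "true_ratio": r_eff,
            "true_cell_count": n_cells,
            "planted_class": planted_class(preset, effect, dose),
        },
    )
    return field, truth


# ---------------------------------------------------------------------------
# dose series
# ---------------------------------------------------------------------------

def simulate_dose_series(
    effect: CompoundEffect,
    preset: GenotypePreset,
    doses: list[float],
    n_replicates: int = 2,
    seed: int = 0,
    noise_sd: float | None = None,
):
    """Replicate ratio measurements around the generative dose-response curve.

    Returns a :class:`hcscreen.doseresp.DoseSeries` whose ``true_ec50``
    retains the planted value.  ``noise_sd`` defaults to the preset's
    within-plate well SD.
    """
    from .doseresp import DoseSeries  # local import to avoid cycle

    doses = list(doses)
    if any(d <= 0 for d in doses):
        raise ConfigurationError("doses must be positive")
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    if noise_sd is None:
        noise_sd = preset.well_sd
    rng = np.random.default_rng(seed)
    mu = np.array([effective_ratio(preset, effect, d) for d in doses])
    responses = mu[:, None] + rng.normal(0.0, noise_sd, size=(len(doses), n_replicates))
    toxic = np.array(
        [
            preset.mean_cells_per_well * (1 - survival_fraction(effect, d))
            >= 2.0 * math.sqrt(preset.mean_cells_per_well)
            for d in doses
        ]
    )
    return DoseSeries(
        compound_id=effect.compound_id,
        doses=np.asarray(doses, dtype=float),
        responses=responses,
        toxic=toxic,
        backgrounds=None,
        true_ec50=effect.ec50 if effect.efficacy > 0 else None,
    )
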
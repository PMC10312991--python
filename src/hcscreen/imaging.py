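"""Field segmentation and per-cell cargo-ratio / morphology measurement.

A field carries four co-registered channels (nucleus marker, cell-body
marker, TGN marker, cargo marker).  Cells are kept only when a nucleus lies
inside a cell-body-positive region; the TGN mask is the thresholded TGN
channel intersected with each cell; the cargo ratio is the mean cargo
intensity over TGN pixels divided by the mean over the remaining cell-body
pixels.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import perimeter_crofton, regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .errors import EmptyMaskError
from .features import FEATURE_MANIFEST, MANIFEST_VERSION, compute_cell_features

CHANNEL_NAMES = ("nucleus", "cell_body", "tgn", "cargo")


@dataclass
class FieldImage:
    """One imaging field: four registered 2-D intensity channels."""

    channels: np.ndarray  # (4, H, W), nonnegative
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    pixel_size_um: float = 0.65
    well: str = ""
    field_index: int = 0

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3 or self.channels.shape[0] != 4:
            raise ValueError("channels must be a (4, H, W) stack")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("channel intensities must be finite")
        if self.channels.min() < 0:
            raise ValueError("channel intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        return self.channels[self.channel_names.index(name)]


@dataclass
class SegmentationParams:
    smooth_sigma: float = 1.5
    tgn_smooth_sigma: float = 0.5
    min_nucleus_area: int = 40
    min_cell_area: int = 120
    nucleus_peak_min_distance: int = 8
    drop_border_cells: bool = True


@dataclass
class SegmentationResult:
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    tgn_labels: np.ndarray  # nonzero only inside cells; value = owning cell label
    params: dict = dc_field(default_factory=dict)
    blank_warning: bool = False

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.cell_labels)
        return ids[ids > 0]


TgnShape = namedtuple(
    "TgnShape",
    ["area", "perimeter", "length", "width", "elongation", "compactness", "roughness"],
)


def tgn_shape(mask: np.ndarray) -> TgnShape:
    """Shape descriptors of a (possibly multi-part) binary region.

    length/width are the major/minor axes of the moment-based best-fit
    ellipse over all pixels; ``elongation = width/length``;
    ``compactness = perimeter^2 / (4*pi*area)``; ``roughness`` is the
    reciprocal shape factor ``4*pi*area / perimeter^2``, so
    ``roughness * compactness == 1`` exactly.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot compute shape of an empty mask")
    area = float(mask.sum())
    perim = float(perimeter_crofton(mask, directions=4))
    props = regionprops(mask.astype(np.uint8))[0]
    length = float(props.axis_major_length)
    width = float(props.axis_minor_length)
    elongation = width / length if length > 0 else 1.0
    elongation = min(max(elongation, 1e-9), 1.0)
    compactness = perim**2 / (4.0 * math.pi * area) if perim > 0 else float("nan")
    roughness = 1.0 / compactness if compactness else float("nan")
    return TgnShape(area, perim, length, width, elongation, compactness, roughness)


def _empty_segmentation(shape: tuple[int, int], params: SegmentationParams) -> SegmentationResult:
    z = np.zeros(shape, dtype=np.int32)
    return SegmentationResult(z, z.copy(), z.copy(), params=vars(params).copy(), blank_warning=True)


def segment_field(field: FieldImage, params: SegmentationParams | None = None) -> SegmentationResult:
    """Segment nuclei, cell bodies and TGN regions of one field.

    Nuclei: smoothed nucleus channel, Otsu threshold, hole filling, small
    object removal, distance-transform watershed split.  Cells: Otsu on the
    cell-body channel, nucleus-seeded watershed; cells without an interior
    nucleus and (by default) cells touching the image border are dropped.
    TGN: Otsu on the TGN channel intersected with each retained cell.

    A blank nucleus or cell-body channel yields an empty result with
    ``blank_warning`` set instead of raising.
    """
    if params is None:
        params = SegmentationParams()
    nuc_ch = field.channel("nucleus")
    body_ch = field.channel("cell_body")
    tgn_ch = field.channel("tgn")
    if nuc_ch.max() <= 0 or body_ch.max() <= 0:
        return _empty_segmentation(field.shape, params)

    # nuclei
    nuc_s = gaussian(nuc_ch, sigma=params.smooth_sigma, preserve_range=True)
    try:
        nuc_mask = nuc_s > threshold_otsu(nuc_s)
    except ValueError:  # constant image
        return _empty_segmentation(field.shape, params)
    nuc_mask = ndi.binary_fill_holes(nuc_mask)
    nuc_mask = remove_small_objects(nuc_mask, max_size=params.min_nucleus_area - 1)
    if not nuc_mask.any():
        return _empty_segmentation(field.shape, params)
    dist = ndi.distance_transform_edt(nuc_mask)
    peaks = peak_local_max(
        dist, labels=nuc_mask, min_distance=params.nucleus_peak_min_distance,
        exclude_border=False,
    )
    markers = np.zeros(field.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers, _ = ndi.label(nuc_mask)
    nucleus_labels = watershed(-dist, markers, mask=nuc_mask).astype(np.int32)

    # cell bodies, seeded by nuclei
    body_s = gaussian(body_ch, sigma=params.smooth_sigma, preserve_range=True)
    try:
        body_mask = body_s > threshold_otsu(body_s)
    except ValueError:
        return _empty_segmentation(field.shape, params)
    body_mask = ndi.binary_fill_holes(body_mask | (nucleus_labels > 0))
    cell_labels = watershed(-body_s, nucleus_labels, mask=body_mask).astype(np.int32)

    # drop cells lacking an interior nucleus (watershed seeds guarantee one,
    # but nuclei outside any body region produce single-nucleus "cells"
    # smaller than min_cell_area or pure-nucleus blobs with no body signal)
    keep: set[int] = set()
    for p in regionprops(cell_labels):
        cell_mask = cell_labels == p.label
        if cell_mask.sum() < params.min_cell_area:
            continue
        nuc_in = nucleus_labels[cell_mask]
        if not (nuc_in > 0).any():
            continue
        # require body-positive signal beyond the nucleus itself
        body_only = cell_mask & (nucleus_labels == 0)
        if not body_only.any() or not body_mask[body_only].any():
            continue
        keep.add(p.label)
    if params.drop_border_cells:
        border = np.zeros(field.shape, dtype=bool)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        touching = set(np.unique(cell_labels[border])) - {0}
        keep -= touching
    drop = ~np.isin(cell_labels, sorted(keep))
    cell_labels = cell_labels.copy()
    cell_labels[drop] = 0

    # TGN mask inside retained cells
    tgn_s = gaussian(tgn_ch, sigma=params.tgn_smooth_sigma, preserve_range=True)
    try:
        tgn_mask = tgn_s > threshold_otsu(tgn_s)
    except ValueError:
        tgn_mask = np.zeros(field.shape, dtype=bool)
    tgn_labels = np.where(tgn_mask, cell_labels, 0).astype(np.int32)

    return SegmentationResult(
        nucleus_labels, cell_labels, tgn_labels, params=vars(params).copy(),
        blank_warning=False,
    )


@dataclass
class CellRecord:
    """Measurements for one segmented cell."""

    cell_id: int
    cargo_mean_in_tgn: float
    cargo_mean_outside_tgn: float
    cargo_ratio: float
    tgn_area: float
    tgn_perimeter: float
    tgn_length: float
    tgn_width: float
    tgn_elongation: float
    tgn_compactness: float
    tgn_roughness: float
    feature_vector: np.ndarray | None
    valid: bool
    centroid: tuple[float, float] = (float("nan"), float("nan"))
    manifest_version: str = MANIFEST_VERSION


def compartment_means(
    cargo: np.ndarray, tgn_mask: np.ndarray, cyto_mask: np.ndarray
) -> tuple[float, float]:
    """Mean cargo intensity over TGN pixels and over cytoplasm pixels."""
    cargo = np.asarray(cargo, dtype=float)
    if not tgn_mask.any() or not cyto_mask.any():
        raise EmptyMaskError("empty compartment")
    return float(cargo[tgn_mask].mean()), float(cargo[cyto_mask].mean())


def measure_cells(
    field: FieldImage,
    seg: SegmentationResult,
    compute_features: bool = True,
) -> list[CellRecord]:
    """Per-cell compartment means, cargo ratio, TGN shape and features.

    Cells with an empty TGN mask or empty cytoplasm mask are returned
    flagged invalid (``valid=False``) and carry NaN measurements.
    """
    cargo = field.channel("cargo")
    records: list[CellRecord] = []
    for cid in seg.cell_ids:
        cell_mask = seg.cell_labels == cid
        tgn_mask = seg.tgn_labels == cid
        cyto_mask = cell_mask & ~tgn_mask
        nucleus_mask = (seg.nucleus_labels > 0) & cell_mask
        centroid = tuple(np.mean(np.nonzero(cell_mask), axis=1))
        if not tgn_mask.any() or not cyto_mask.any() or not nucleus_mask.any():
            records.append(
                CellRecord(
                    int(cid), *(float("nan"),) * 10, feature_vector=None,
                    valid=False, centroid=centroid,
                )
            )
            continue
        mean_in, mean_out = compartment_means(cargo, tgn_mask, cyto_mask)
        ratio = mean_in / mean_out if mean_out > 0 else float("nan")
        shape = tgn_shape(tgn_mask)
        fv = (
            compute_cell_features(field.channels, cell_mask, nucleus_mask, tgn_mask)
            if compute_features
            else None
        )
        records.append(
            CellRecord(
                cell_id=int(cid),
                cargo_mean_in_tgn=mean_in,
                cargo_mean_outside_tgn=mean_out,
                cargo_ratio=ratio,
                tgn_area=shape.area,
                tgn_perimeter=shape.perimeter,
                tgn_length=shape.length,
                tgn_width=shape.width,
                tgn_elongation=shape.elongation,
                tgn_compactness=shape.compactness,
                tgn_roughness=shape.roughness,
                feature_vector=fv,
                valid=math.isfinite(ratio),
                centroid=centroid,
            )
        )
    return records


def field_background(field: FieldImage, seg: SegmentationResult) -> float:
    """Mean cargo intensity outside all cells (NaN when cells fill the field)."""
    outside = seg.cell_labels == 0
    if not outside.any():
        return float("nan")
    return float(field.channel("cargo")[outside].mean())


@dataclass
class WellSummary:
    """Per-well aggregate of valid cell records."""

    well: str
    role: str = "compound"
    compound_id: str | None = None
    dose_um: float | None = None
    mean_ratio: float = float("nan")
    cell_count: int = 0
    mean_features: np.ndarray | None = None
    background_intensity: float = float("nan")
    excluded: bool = False
    plate: str = ""


def summarize_well(
    cells: Sequence[CellRecord],
    well: str = "",
    role: str = "compound",
    compound_id: str | None = None,
    dose_um: float | None = None,
    background: float = float("nan"),
    min_cells: int = 20,
    plate: str = "",
) -> WellSummary:
    """Unweighted mean of valid per-cell ratios plus cell count.

    Wells with fewer than ``min_cells`` valid cells are flagged excluded;
    their mean_ratio is still reported when at least one valid cell exists.
    """
    valid = [c for c in cells if c.valid]
    count = len(valid)
    mean_ratio = float(np.mean([c.cargo_ratio for c in valid])) if valid else float("nan")
    feats = [c.feature_vector for c in valid if c.feature_vector is not None]
    mean_features = np.mean(np.stack(feats), axis=0) if feats else None
    return WellSummary(
        well=well,
        role=role,
        compound_id=compound_id,
        dose_um=dose_um,
        mean_ratio=mean_ratio,
        cell_count=count,
        mean_features=mean_features,
        background_intensity=background,
        excluded=count < min_cells,
        plate=plate,
    )


def summaries_to_frame(summaries: Sequence[WellSummary]) -> pd.DataFrame:
    """Tabulate well summaries; feature means become ``feat_*`` columns."""
    rows = []
    for s in summaries:
        row = {
            "plate": s.plate,
            "well": s.well,
            "role": s.role,
            "compound_id": s.compound_id,
            "dose_um": s.dose_um,
            "mean_ratio": s.mean_ratio,
            "cell_count": s.cell_count,
            "background_intensity": s.background_intensity,
            "excluded": s.excluded,
        }
        if s.mean_features is not None:
            row.update({f"feat_{n}": v for n, v in zip(FEATURE_MANIFEST, s.mean_features)})
        rows.append(row)
    return pd.DataFrame(rows)
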
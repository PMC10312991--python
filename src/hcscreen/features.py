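"""Versioned per-cell feature manifest and its computation.

The manifest pins exactly 85 named measurements per cell, spread over five
categories: nucleus, cytoskeleton (cell-body channel), global cell
morphology, TGN, and cargo/vesicles.  Downstream profiling refuses matrices
whose columns do not match this manifest verbatim (see
:class:`hcscreen.errors.ManifestVersionError`).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import perimeter_crofton, regionprops

MANIFEST_VERSION = "1"

_NUCLEUS = (
    "nucleus_area",
    "nucleus_perimeter",
    "nucleus_major_axis_length",
    "nucleus_minor_axis_length",
    "nucleus_eccentricity",
    "nucleus_solidity",
    "nucleus_extent",
    "nucleus_compactness",
    "nucleus_equivalent_diameter",
    "nucleus_intensity_mean",
    "nucleus_intensity_sd",
    "nucleus_intensity_q25",
    "nucleus_intensity_median",
    "nucleus_intensity_q75",
    "nucleus_intensity_max",
    "nucleus_intensity_integrated",
)

_CYTOSKELETON = (
    "cytoskeleton_intensity_mean",
    "cytoskeleton_intensity_sd",
    "cytoskeleton_intensity_min",
    "cytoskeleton_intensity_q25",
    "cytoskeleton_intensity_median",
    "cytoskeleton_intensity_q75",
    "cytoskeleton_intensity_max",
    "cytoskeleton_intensity_integrated",
    "cytoskeleton_intensity_mean_nucleus",
    "cytoskeleton_intensity_mean_cytoplasm",
    "cytoskeleton_nucleus_to_cell_intensity_ratio",
    "cytoskeleton_intensity_cv",
)

_CELL = (
    "cell_area",
    "cell_perimeter",
    "cell_major_axis_length",
    "cell_minor_axis_length",
    "cell_eccentricity",
    "cell_solidity",
    "cell_extent",
    "cell_compactness",
    "cell_roughness",
    "cell_equivalent_diameter",
    "cell_elongation",
    "cell_convex_area",
    "cell_orientation",
    "nucleus_to_cell_area_fraction",
)

_TGN = (
    "tgn_area",
    "tgn_perimeter",
    "tgn_length",
    "tgn_width",
    "tgn_elongation",
    "tgn_compactness",
    "tgn_roughness",
    "tgn_component_count",
    "tgn_area_fraction_of_cell",
    "tgn_equivalent_diameter",
    "tgn_solidity",
    "tgn_eccentricity",
    "tgn_distance_to_nucleus",
    "tgn_intensity_mean",
    "tgn_intensity_sd",
    "tgn_intensity_q25",
    "tgn_intensity_median",
    "tgn_intensity_q75",
    "tgn_intensity_max",
    "tgn_intensity_integrated",
    "tgn_intensity_cv",
    "tgn_to_cytoplasm_intensity_ratio",
)

_CARGO = (
    "cargo_mean_in_tgn",
    "cargo_mean_outside_tgn",
    "cargo_ratio",
    "cargo_sd_in_tgn",
    "cargo_sd_outside_tgn",
    "cargo_median_in_tgn",
    "cargo_median_outside_tgn",
    "cargo_max_in_tgn",
    "cargo_max_outside_tgn",
    "cargo_integrated_in_tgn",
    "cargo_integrated_outside_tgn",
    "cargo_integrated_cell",
    "cargo_mean_cell",
    "cargo_cv_cell",
    "cargo_spot_count",
    "cargo_spot_density",
    "cargo_spot_total_area",
    "cargo_spot_mean_area",
    "cargo_spot_intensity_mean",
    "cargo_spot_intensity_max",
    "cargo_spot_intensity_sd",
)

FEATURE_CATEGORIES: dict[str, tuple[str, ...]] = {
    "nucleus": _NUCLEUS,
    "cytoskeleton": _CYTOSKELETON,
    "cell": _CELL,
    "tgn": _TGN,
    "cargo": _CARGO,
}

#: Ordered names of the 85 per-cell measurements, manifest version 1.
FEATURE_MANIFEST: tuple[str, ...] = _NUCLEUS + _CYTOSKELETON + _CELL + _TGN + _CARGO

assert len(FEATURE_MANIFEST) == 85
assert len(set(FEATURE_MANIFEST)) == 85


def _region(mask: np.ndarray):
    """Single regionprops entry over all True pixels of ``mask``.

    Multi-part regions are measured on the union (one shared label), so axis
    lengths come from the pooled second moments and area/perimeter are sums.
    """
    return regionprops(mask.astype(np.uint8))[0]


def _intensity_stats(values: np.ndarray) -> dict[str, float]:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return {k: float("nan") for k in ("mean", "sd", "min", "q25", "median", "q75", "max", "sum")}
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=0)),
        "min": float(v.min()),
        "q25": float(np.percentile(v, 25)),
        "median": float(np.percentile(v, 50)),
        "q75": float(np.percentile(v, 75)),
        "max": float(v.max()),
        "sum": float(v.sum()),
    }


def _shape_block(mask: np.ndarray, prefix: str) -> dict[str, float]:
    r = _region(mask)
    area = float(mask.sum())
    perim = float(perimeter_crofton(mask, directions=4))
    compact = perim**2 / (4.0 * math.pi * area) if area > 0 else float("nan")
    return {
        f"{prefix}_area": area,
        f"{prefix}_perimeter": perim,
        f"{prefix}_major_axis_length": float(r.axis_major_length),
        f"{prefix}_minor_axis_length": float(r.axis_minor_length),
        f"{prefix}_eccentricity": float(r.eccentricity),
        f"{prefix}_solidity": float(r.solidity),
        f"{prefix}_extent": float(r.extent),
        f"{prefix}_compactness": compact,
        f"{prefix}_equivalent_diameter": float(r.equivalent_diameter_area),
    }


def compute_cell_features(
    channels: np.ndarray,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    tgn_mask: np.ndarray,
) -> np.ndarray:
    """Compute the 85-feature vector for one cell.

    Parameters
    ----------
    channels:
        ``(4, H, W)`` stack ordered nucleus, cell-body, TGN, cargo.
    cell_mask, nucleus_mask, tgn_mask:
        Boolean masks of the cell, its nucleus, and its TGN region.
        ``tgn_mask`` must be a subset of ``cell_mask``.

    Returns
    -------
    numpy.ndarray
        Values aligned with :data:`FEATURE_MANIFEST`.
    """
    nuc_ch, body_ch, tgn_ch, cargo_ch = (np.asarray(c, dtype=float) for c in channels)
    cyto_mask = cell_mask & ~tgn_mask
    out: dict[str, float] = {}

    # --- nucleus ---
    blk = _shape_block(nucleus_mask, "nucleus")
    out.update(blk)
    s = _intensity_stats(nuc_ch[nucleus_mask])
    out["nucleus_intensity_mean"] = s["mean"]
    out["nucleus_intensity_sd"] = s["sd"]
    out["nucleus_intensity_q25"] = s["q25"]
    out["nucleus_intensity_median"] = s["median"]
    out["nucleus_intensity_q75"] = s["q75"]
    out["nucleus_intensity_max"] = s["max"]
    out["nucleus_intensity_integrated"] = s["sum"]

    # --- cytoskeleton (cell-body channel) ---
    s = _intensity_stats(body_ch[cell_mask])
    out["cytoskeleton_intensity_mean"] = s["mean"]
    out["cytoskeleton_intensity_sd"] = s["sd"]
    out["cytoskeleton_intensity_min"] = s["min"]
    out["cytoskeleton_intensity_q25"] = s["q25"]
    out["cytoskeleton_intensity_median"] = s["median"]
    out["cytoskeleton_intensity_q75"] = s["q75"]
    out["cytoskeleton_intensity_max"] = s["max"]
    out["cytoskeleton_intensity_integrated"] = s["sum"]
    mean_nuc = float(body_ch[nucleus_mask].mean()) if nucleus_mask.any() else float("nan")
    not_nuc = cell_mask & ~nucleus_mask
    mean_cyt = float(body_ch[not_nuc].mean()) if not_nuc.any() else float("nan")
    out["cytoskeleton_intensity_mean_nucleus"] = mean_nuc
    out["cytoskeleton_intensity_mean_cytoplasm"] = mean_cyt
    out["cytoskeleton_nucleus_to_cell_intensity_ratio"] = (
        mean_nuc / s["mean"] if s["mean"] else float("nan")
    )
    out["cytoskeleton_intensity_cv"] = s["sd"] / s["mean"] if s["mean"] else float("nan")

    # --- cell morphology ---
    blk = _shape_block(cell_mask, "cell")
    out.update(blk)
    out["cell_roughness"] = 1.0 / blk["cell_compactness"] if blk["cell_compactness"] else float("nan")
    major = blk["cell_major_axis_length"]
    out["cell_elongation"] = blk["cell_minor_axis_length"] / major if major > 0 else 1.0
    cell_region = _region(cell_mask)
    out["cell_convex_area"] = float(cell_region.area_convex)
    out["cell_orientation"] = float(cell_region.orientation)
    out["nucleus_to_cell_area_fraction"] = out["nucleus_area"] / out["cell_area"]

    # --- TGN ---
    blk = _shape_block(tgn_mask, "tgn")
    out["tgn_area"] = blk["tgn_area"]
    out["tgn_perimeter"] = blk["tgn_perimeter"]
    out["tgn_length"] = blk["tgn_major_axis_length"]
    out["tgn_width"] = blk["tgn_minor_axis_length"]
    out["tgn_elongation"] = (
        blk["tgn_minor_axis_length"] / blk["tgn_major_axis_length"]
        if blk["tgn_major_axis_length"] > 0
        else 1.0
    )
    out["tgn_compactness"] = blk["tgn_compactness"]
    out["tgn_roughness"] = 1.0 / blk["tgn_compactness"] if blk["tgn_compactness"] else float("nan")
    n_comp = int(ndi.label(tgn_mask)[1])
    out["tgn_component_count"] = float(n_comp)
    out["tgn_area_fraction_of_cell"] = out["tgn_area"] / out["cell_area"]
    out["tgn_equivalent_diameter"] = blk["tgn_equivalent_diameter"]
    out["tgn_solidity"] = blk["tgn_solidity"]
    out["tgn_eccentricity"] = blk["tgn_eccentricity"]
    tgn_c = np.array(_region(tgn_mask).centroid)
    nuc_c = np.array(_region(nucleus_mask).centroid)
    out["tgn_distance_to_nucleus"] = float(np.linalg.norm(tgn_c - nuc_c))
    s = _intensity_stats(tgn_ch[tgn_mask])
    out["tgn_intensity_mean"] = s["mean"]
    out["tgn_intensity_sd"] = s["sd"]
    out["tgn_intensity_q25"] = s["q25"]
    out["tgn_intensity_median"] = s["median"]
    out["tgn_intensity_q75"] = s["q75"]
    out["tgn_intensity_max"] = s["max"]
    out["tgn_intensity_integrated"] = s["sum"]
    out["tgn_intensity_cv"] = s["sd"] / s["mean"] if s["mean"] else float("nan")
    tgn_cyto_mean = float(tgn_ch[cyto_mask].mean()) if cyto_mask.any() else float("nan")
    out["tgn_to_cytoplasm_intensity_ratio"] = (
        s["mean"] / tgn_cyto_mean if tgn_cyto_mean else float("nan")
    )

    # --- cargo / vesicles ---
    in_vals = cargo_ch[tgn_mask]
    out_vals = cargo_ch[cyto_mask]
    si = _intensity_stats(in_vals)
    so = _intensity_stats(out_vals)
    out["cargo_mean_in_tgn"] = si["mean"]
    out["cargo_mean_outside_tgn"] = so["mean"]
    out["cargo_ratio"] = si["mean"] / so["mean"] if so["mean"] else float("nan")
    out["cargo_sd_in_tgn"] = si["sd"]
    out["cargo_sd_outside_tgn"] = so["sd"]
    out["cargo_median_in_tgn"] = si["median"]
    out["cargo_median_outside_tgn"] = so["median"]
    out["cargo_max_in_tgn"] = si["max"]
    out["cargo_max_outside_tgn"] = so["max"]
    out["cargo_integrated_in_tgn"] = si["sum"]
    out["cargo_integrated_outside_tgn"] = so["sum"]
    sc = _intensity_stats(cargo_ch[cell_mask])
    out["cargo_integrated_cell"] = sc["sum"]
    out["cargo_mean_cell"] = sc["mean"]
    out["cargo_cv_cell"] = sc["sd"] / sc["mean"] if sc["mean"] else float("nan")

    # vesicle-like spots: bright cargo puncta in the cytoplasm (outside TGN)
    if out_vals.size:
        thresh = so["mean"] + 2.0 * so["sd"]
        spot_mask = cyto_mask & (cargo_ch > thresh)
        labels, n_spots = ndi.label(spot_mask)
        out["cargo_spot_count"] = float(n_spots)
        out["cargo_spot_density"] = n_spots / out["cell_area"]
        out["cargo_spot_total_area"] = float(spot_mask.sum())
        out["cargo_spot_mean_area"] = (
            float(spot_mask.sum()) / n_spots if n_spots else 0.0
        )
        if n_spots:
            sp = _intensity_stats(cargo_ch[spot_mask])
            out["cargo_spot_intensity_mean"] = sp["mean"]
            out["cargo_spot_intensity_max"] = sp["max"]
            out["cargo_spot_intensity_sd"] = sp["sd"]
        else:
            out["cargo_spot_intensity_mean"] = 0.0
            out["cargo_spot_intensity_max"] = 0.0
            out["cargo_spot_intensity_sd"] = 0.0
    else:
        for k in (
            "cargo_spot_count",
            "cargo_spot_density",
            "cargo_spot_total_area",
            "cargo_spot_mean_area",
            "cargo_spot_intensity_mean",
            "cargo_spot_intensity_max",
            "cargo_spot_intensity_sd",
        ):
            out[k] = float("nan")

    return np.array([out[name] for name in FEATURE_MANIFEST], dtype=float)
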
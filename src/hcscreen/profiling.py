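"""Multiparametric morphological profiling: standardized feature matrices,
PCA, PC-feature correlations, driver selection and condition profiles."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import ManifestVersionError
from .features import FEATURE_MANIFEST, MANIFEST_VERSION


@dataclass
class ProfileMatrix:
    """Standardized rows-by-features matrix with condition labels."""

    data: np.ndarray  # rows x kept features, standardized
    feature_names: list[str]
    labels: pd.DataFrame  # row-aligned condition labels
    means: np.ndarray  # per kept feature, pre-standardization
    sds: np.ndarray
    dropped: list[str] = dc_field(default_factory=list)
    manifest_version: str = MANIFEST_VERSION


def build_profile_matrix(
    table: pd.DataFrame,
    label_cols: list[str] | None = None,
    feature_prefix: str = "",
    manifest_version: str = MANIFEST_VERSION,
) -> ProfileMatrix:
    """Assemble and standardize the 85-feature matrix from a tidy table.

    ``table`` must contain one column per manifest feature (optionally
    prefixed, e.g. ``feat_``); remaining columns named in ``label_cols``
    become row labels.  Zero-variance columns are dropped and recorded.
    Rows with any missing feature value are dropped.
    """
    if manifest_version != MANIFEST_VERSION:
        raise ManifestVersionError(
            f"records carry manifest {manifest_version!r}, build expects {MANIFEST_VERSION!r}"
        )
    cols = [feature_prefix + n for n in FEATURE_MANIFEST]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ManifestVersionError(f"missing manifest features: {missing[:5]}")
    sub = table[cols].astype(float)
    ok = sub.notna().all(axis=1)
    sub = sub[ok]
    labels = (
        table.loc[ok, label_cols].reset_index(drop=True)
        if label_cols
        else pd.DataFrame(index=range(int(ok.sum())))
    )
    x = sub.to_numpy()
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=0)
    keep = sds > 0
    dropped = [n for n, k in zip(FEATURE_MANIFEST, keep) if not k]
    x = (x[:, keep] - means[keep]) / sds[keep]
    return ProfileMatrix(
        data=x,
        feature_names=[n for n, k in zip(FEATURE_MANIFEST, keep) if k],
        labels=labels,
        means=means[keep],
        sds=sds[keep],
        dropped=dropped,
    )


@dataclass
class PCAResult:
    loadings: np.ndarray  # features x components, orthonormal columns
    scores: np.ndarray  # rows x components
    variance_explained: np.ndarray  # fractions, nonincreasing


def run_pca(matrix: ProfileMatrix, k: int) -> PCAResult:
    """PCA of the standardized matrix by SVD.

    Sign convention: each component is oriented so its largest-|loading|
    feature has a positive loading.  ``k`` beyond the matrix rank is
    truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = matrix.data
    if x.shape[0] < k:
        raise ValueError("need at least k rows")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if len(s) else 0
    if k > rank:
        warnings.warn(f"k={k} exceeds matrix rank {rank}; truncating", stacklevel=2)
        k = rank
    loadings = vt[:k].T
    scores = u[:, :k] * s[:k]
    total_var = float((s**2).sum())
    var_frac = (s[:k] ** 2) / total_var
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(loadings=loadings, scores=scores, variance_explained=var_frac)


def pc_feature_correlation(
    matrix: ProfileMatrix,
    scores: np.ndarray,
    component: int = 0,
    threshold: float = 0.75,
    use_abs: bool = False,
) -> tuple[pd.Series, list[str]]:
    """Pearson r of each feature with one PC, plus selected driver features.

    Drivers have signed ``r > threshold`` by default; pass ``use_abs=True``
    for a symmetric |r| cut.
    """
    pc = np.asarray(scores)[:, component]
    x = matrix.data
    if x.shape[0] != len(pc):
        raise ValueError("scores not row-aligned with matrix")
    pc_c = pc - pc.mean()
    x_c = x - x.mean(axis=0)
    denom = np.sqrt((x_c**2).sum(axis=0) * (pc_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x_c * pc_c[:, None]).sum(axis=0) / denom
    rs = pd.Series(r, index=matrix.feature_names, name=f"r_pc{component + 1}")
    sel = np.abs(rs) > threshold if use_abs else rs > threshold
    return rs, list(rs.index[sel])


def condition_profiles(
    matrix: ProfileMatrix,
    condition_col: str,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Per-condition median standardized value of each (selected) feature.

    Returns a tidy table (condition, feature, median_z) suitable for
    heatmap rendering.
    """
    if condition_col not in matrix.labels.columns:
        raise ValueError(f"no label column {condition_col!r}")
    feats = features if features is not None else matrix.feature_names
    idx = [matrix.feature_names.index(f) for f in feats]
    df = pd.DataFrame(matrix.data[:, idx], columns=feats)
    df[condition_col] = matrix.labels[condition_col].to_numpy()
    tidy = (
        df.groupby(condition_col)
        .median()
        .reset_index()
        .melt(id_vars=condition_col, var_name="feature", value_name="median_z")
    )
    return tidy
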
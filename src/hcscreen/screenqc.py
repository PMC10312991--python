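"""Plate-level quality control and control-separation statistics.

Gates follow the screening thresholds: robust Z' >= 0.3, SSMD >= 3 and an
inter-assay CV <= 10%, each computed from the positive- and
negative-control wells of the same plate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .errors import DegenerateSeparationError, HcsError

MAD_SCALE = 1.4826  # normal-consistency factor for the MAD


@dataclass
class QcThresholds:
    z_prime_min: float = 0.3
    ssmd_min: float = 3.0
    cv_max: float = 10.0


@dataclass
class PlateQC:
    plate: str
    z_prime_robust: float
    ssmd: float
    cv_percent: float
    n_pos: int
    n_neg: int
    passed: bool


@dataclass
class SeparationReport:
    u_statistic: float
    p_value: float
    mean_pos: float
    mean_neg: float
    sd_pos: float
    sd_neg: float
    n_pos: int
    n_neg: int
    auc: float | None = None
    split_meta: dict = dc_field(default_factory=dict)
    replicate_corr_mean: float | None = None
    replicate_corr_sd: float | None = None


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def robust_z_prime(pos: Sequence[float], neg: Sequence[float]) -> float:
    """Robust Z'-factor: medians and normal-scaled MADs replace mean/SD.

    ``1 - 3 * (1.4826*MAD_pos + 1.4826*MAD_neg) / |median_pos - median_neg|``
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise DegenerateSeparationError("need >= 2 wells per control group")
    delta = abs(np.median(pos) - np.median(neg))
    if delta == 0:
        raise DegenerateSeparationError("equal control medians")
    return 1.0 - 3.0 * MAD_SCALE * (_mad(pos) + _mad(neg)) / delta


def ssmd(pos: Sequence[float], neg: Sequence[float]) -> float:
    """Strictly standardized mean difference, sample-SD form."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise DegenerateSeparationError("need >= 2 wells per control group")
    return ssmd_from_stats(
        pos.mean(), pos.std(ddof=1), neg.mean(), neg.std(ddof=1)
    )


def ssmd_from_stats(mean_pos: float, sd_pos: float, mean_neg: float, sd_neg: float) -> float:
    """SSMD from group summary statistics: (m1 - m2) / sqrt(s1^2 + s2^2)."""
    denom = math.sqrt(sd_pos**2 + sd_neg**2)
    if denom == 0:
        if mean_pos == mean_neg:
            raise DegenerateSeparationError("zero variance and equal means")
        return math.inf if mean_pos > mean_neg else -math.inf
    return (mean_pos - mean_neg) / denom


def inter_assay_cv(per_plate_means: Sequence[float]) -> float:
    """Percent CV of per-plate control means across plates."""
    x = np.asarray(per_plate_means, dtype=float)
    if len(x) < 2:
        raise DegenerateSeparationError("need >= 2 plates for inter-assay CV")
    mean = x.mean()
    if mean == 0:
        raise DegenerateSeparationError("zero mean; CV undefined")
    return 100.0 * x.std(ddof=1) / abs(mean)


def plate_qc(
    plate: str,
    pos: Sequence[float],
    neg: Sequence[float],
    cv_percent: float = 0.0,
    thresholds: QcThresholds | None = None,
) -> PlateQC:
    """Compute one plate's QC record; the CV is screen-level and passed in."""
    if thresholds is None:
        thresholds = QcThresholds()
    zp = robust_z_prime(pos, neg)
    sm = abs(ssmd(pos, neg))
    passed = (
        zp >= thresholds.z_prime_min
        and sm >= thresholds.ssmd_min
        and cv_percent <= thresholds.cv_max
    )
    return PlateQC(
        plate=plate,
        z_prime_robust=zp,
        ssmd=sm,
        cv_percent=cv_percent,
        n_pos=len(pos),
        n_neg=len(neg),
        passed=passed,
    )


def qc_from_well_table(
    wells: pd.DataFrame,
    thresholds: QcThresholds | None = None,
    value_col: str = "mean_ratio",
) -> list[PlateQC]:
    """Per-plate QC from a long well table (plate, role, value columns).

    The inter-assay CV is computed over the per-plate negative-control means
    and shared by every plate record (screens with a single plate get 0).
    """
    if thresholds is None:
        thresholds = QcThresholds()
    neg_means = wells[wells["role"] == "negative_control"].groupby("plate")[value_col].mean()
    cv = inter_assay_cv(neg_means.to_numpy()) if len(neg_means) >= 2 else 0.0
    out = []
    for plate, grp in wells.groupby("plate"):
        pos = grp.loc[grp["role"] == "positive_control", value_col].to_numpy()
        neg = grp.loc[grp["role"] == "negative_control", value_col].to_numpy()
        out.append(plate_qc(str(plate), pos, neg, cv_percent=cv, thresholds=thresholds))
    return out


def gate_plates(
    qc: Iterable[PlateQC], thresholds: QcThresholds | None = None
) -> tuple[list[PlateQC], dict]:
    """Split plates into passing/failing and report counts.

    Re-evaluates the gate against ``thresholds`` so a QC list computed with
    one set of thresholds can be re-gated with another.
    """
    if thresholds is None:
        thresholds = QcThresholds()
    passed, failed = [], []
    for q in qc:
        ok = (
            q.z_prime_robust >= thresholds.z_prime_min
            and abs(q.ssmd) >= thresholds.ssmd_min
            and q.cv_percent <= thresholds.cv_max
        )
        (passed if ok else failed).append(q)
    report = {
        "n_plates": len(passed) + len(failed),
        "n_passed": len(passed),
        "n_failed": len(failed),
        "failed_plates": [q.plate for q in failed],
        "thresholds": vars(thresholds).copy(),
    }
    return passed, report


def replicate_correlation(
    plates: Sequence[pd.DataFrame],
    n_resamples: int = 100,
    seed: int = 0,
    value_col: str = "mean_ratio",
    well_col: str = "well",
) -> tuple[float, float]:
    """Random-split replicate correlation over well positions.

    Each resample splits the plates into two halves, averages well-position-
    matched values within each half, and computes Pearson r across wells;
    the mean and SD over resamples are returned.
    """
    plates = list(plates)
    if len(plates) < 2:
        raise DegenerateSeparationError("need >= 2 plates")
    if len(plates) % 2 != 0:
        raise DegenerateSeparationError("need an even number of plates to split")
    common = set(plates[0][well_col])
    for p in plates[1:]:
        common &= set(p[well_col])
    if not common:
        raise DegenerateSeparationError("plates share no well positions")
    wells_sorted = sorted(common)
    mat = np.column_stack(
        [
            p.set_index(well_col)[value_col].reindex(wells_sorted).to_numpy()
            for p in plates
        ]
    )  # wells x plates
    rng = np.random.default_rng(seed)
    half = len(plates) // 2
    rs = []
    for _ in range(n_resamples):
        order = rng.permutation(len(plates))
        a = mat[:, order[:half]].mean(axis=1)
        b = mat[:, order[half:]].mean(axis=1)
        rs.append(stats.pearsonr(a, b).statistic)
    rs = np.asarray(rs)
    return float(rs.mean()), float(rs.std(ddof=1))


def _u_statistic(pos: np.ndarray, neg: np.ndarray) -> float:
    """U counting (pos > neg) pairs, ties counted half, via average ranks."""
    pooled = np.concatenate([pos, neg])
    ranks = stats.rankdata(pooled)
    r_pos = ranks[: len(pos)].sum()
    return float(r_pos - len(pos) * (len(pos) + 1) / 2.0)


def mann_whitney(
    pos: Sequence[float], neg: Sequence[float], exact_max_n: int = 8
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test oriented as (pos > neg) pair counts.

    Exact enumeration over all group assignments when both groups have at
    most ``exact_max_n`` observations (handles ties); otherwise the
    tie-corrected normal approximation.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    n1, n2 = len(pos), len(neg)
    if n1 == 0 or n2 == 0:
        raise DegenerateSeparationError("empty group")
    u = _u_statistic(pos, neg)
    mu = n1 * n2 / 2.0
    if n1 <= exact_max_n and n2 <= exact_max_n:
        pooled = np.concatenate([pos, neg])
        idx = range(n1 + n2)
        count = 0
        total = 0
        d_obs = abs(u - mu)
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - mu) >= d_obs - 1e-12:
                count += 1
        return u, count / total
    # tie-corrected normal approximation
    pooled = np.concatenate([pos, neg])
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return u, 1.0
    z = (u - mu) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return u, min(p, 1.0)


def control_separation(neg: Sequence[float], pos: Sequence[float]) -> SeparationReport:
    """Mann-Whitney separation report between control groups."""
    neg = np.asarray(neg, dtype=float)
    pos = np.asarray(pos, dtype=float)
    if len(neg) < 3 or len(pos) < 3:
        raise DegenerateSeparationError("need >= 3 wells per group")
    u, p = mann_whitney(pos, neg)
    return SeparationReport(
        u_statistic=u,
        p_value=p,
        mean_pos=float(pos.mean()),
        mean_neg=float(neg.mean()),
        sd_pos=float(pos.std(ddof=1)),
        sd_neg=float(neg.std(ddof=1)),
        n_pos=len(pos),
        n_neg=len(neg),
    )


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney U of positive-class scores over n1*n2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    s1, s0 = scores[labels], scores[~labels]
    if len(s1) == 0 or len(s0) == 0:
        raise DegenerateSeparationError("need both classes")
    return _u_statistic(s1, s0) / (len(s1) * len(s0))


def separation_auc(
    values: Sequence[float],
    labels: Sequence[int],
    train_frac: float = 0.7,
    seed: int = 0,
    max_attempts: int = 10,
) -> tuple[float, dict]:
    """Train/test AUC of a logistic model of genotype label on cargo ratio.

    The data are split 70/30 (configurable); a single-predictor logistic
    regression is fit on the training split and the test-split AUC is the
    rank statistic of its scores.  Splits with a single class are retried
    with the next seed, up to ``max_attempts``.
    """
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    labels = np.asarray(labels).astype(int)
    n = len(values)
    if n != len(labels):
        raise HcsError("values and labels must align")
    n_train = int(round(train_frac * n))
    for attempt in range(max_attempts):
        rng = np.random.default_rng(seed + attempt)
        order = rng.permutation(n)
        tr, te = order[:n_train], order[n_train:]
        if len(set(labels[tr])) < 2 or len(set(labels[te])) < 2:
            continue
        model = LogisticRegression()
        model.fit(values[tr], labels[tr])
        scores = model.predict_proba(values[te])[:, 1]
        auc = rank_auc(scores, labels[te])
        meta = {
            "train_frac": train_frac,
            "seed": seed + attempt,
            "n_train": len(tr),
            "n_test": len(te),
        }
        return auc, meta
    raise DegenerateSeparationError("could not obtain two-class splits")
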
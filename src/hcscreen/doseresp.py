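"""Four-parameter logistic dose-response fitting, the secondary-screen
activity criterion, artifact flagging and EC50 summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import ConfigurationError, EmptySummaryError


@dataclass
class DoseSeries:
    """Replicate measurements of one compound over an increasing dose ladder."""

    compound_id: str
    doses: np.ndarray  # strictly increasing, uM
    responses: np.ndarray  # (n_doses, n_replicates)
    toxic: np.ndarray | None = None  # per-dose toxicity flag
    backgrounds: np.ndarray | None = None  # per-dose cargo background
    true_ec50: float | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if self.responses.shape[0] != len(self.doses):
            raise ConfigurationError("responses must have one row per dose")
        if np.any(np.diff(self.doses) <= 0):
            raise ConfigurationError("doses must be strictly increasing")
        if np.any(self.doses <= 0):
            raise ConfigurationError("doses must be positive")
        if self.toxic is None:
            self.toxic = np.zeros(len(self.doses), dtype=bool)
        else:
            self.toxic = np.asarray(self.toxic, dtype=bool)


@dataclass
class FourPLFit:
    top: float
    bottom: float
    ec50: float
    hill: float
    rss: float
    converged: bool
    message: str = ""


def four_pl(dose: np.ndarray, top: float, bottom: float, ec50: float, hill: float) -> np.ndarray:
    """y = bottom + (top - bottom) / (1 + (dose/ec50)^hill).

    ``top`` is the low-dose asymptote when hill > 0.
    """
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ec50) ** hill)


def _model_log10(logx: np.ndarray, top: float, bottom: float, log_ec50: float, hill: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logx - log_ec50)))


def fit_4pl(series: DoseSeries, flat_tol: float = 1e-3) -> FourPLFit:
    """Least-squares 4PL fit over log10 dose.

    Initialization uses the data extremes (low-dose mean as top, high-dose
    mean as bottom) and the dose nearest the half-range crossing for EC50.
    EC50 is bounded to [min_dose/10, max_dose*10].  Non-convergence and flat
    series return ``converged=False`` with NaN EC50 rather than raising.
    """
    if len(series.doses) < 4:
        raise ConfigurationError("need >= 4 distinct doses")
    logx = np.repeat(np.log10(series.doses), series.responses.shape[1])
    y = series.responses.ravel()
    mean_per_dose = series.responses.mean(axis=1)

    span = y.max() - y.min()
    if span < flat_tol:
        return FourPLFit(
            top=float(y.mean()), bottom=float(y.mean()), ec50=float("nan"),
            hill=float("nan"), rss=float(((y - y.mean()) ** 2).sum()),
            converged=False, message="flat series",
        )

    top0 = float(mean_per_dose[:2].mean())
    bot0 = float(mean_per_dose[-2:].mean())
    half = 0.5 * (top0 + bot0)
    ec50_0 = float(series.doses[np.argmin(np.abs(mean_per_dose - half))])
    hill0 = 1.0 if top0 >= bot0 else -1.0
    lo_ec, hi_ec = math.log10(series.doses.min() / 10.0), math.log10(series.doses.max() * 10.0)
    p0 = [top0, bot0, np.clip(math.log10(ec50_0), lo_ec, hi_ec), hill0]
    lo = [y.min() - 2 * span, y.min() - 2 * span, lo_ec, -10.0]
    hi = [y.max() + 2 * span, y.max() + 2 * span, hi_ec, 10.0]
    try:
        popt, _ = optimize.curve_fit(
            _model_log10, logx, y, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning, ValueError) as exc:
        return FourPLFit(
            top=float("nan"), bottom=float("nan"), ec50=float("nan"),
            hill=float("nan"), rss=float("nan"), converged=False, message=str(exc),
        )
    top, bottom, log_ec50, hill = (float(v) for v in popt)
    resid = y - _model_log10(logx, *popt)
    rss = float((resid**2).sum())
    if abs(top - bottom) < flat_tol:
        return FourPLFit(
            top=top, bottom=bottom, ec50=float("nan"), hill=hill, rss=rss,
            converged=False, message="no dose effect (|top-bottom| < tol)",
        )
    return FourPLFit(
        top=top, bottom=bottom, ec50=10.0**log_ec50, hill=hill, rss=rss, converged=True
    )


def call_secondary_active(
    series: DoseSeries, z_threshold: float = -3.0, min_doses: int = 2
) -> tuple[bool, list[float]]:
    """Secondary-screen activity: both replicates at or below the threshold
    at ``min_doses`` or more non-toxic concentrations.

    ``series.responses`` must hold z-scores with exactly 2 replicates.
    Returns the verdict and the supporting (qualifying, non-toxic) doses.
    """
    if series.responses.shape[1] != 2:
        raise ConfigurationError("secondary criterion requires exactly 2 replicates")
    both_below = np.all(series.responses <= z_threshold, axis=1)
    qualifying = both_below & ~series.toxic
    supporting = [float(d) for d, q in zip(series.doses, qualifying) if q]
    return len(supporting) >= min_doses, supporting


def flag_artifact(
    backgrounds: np.ndarray,
    doses: np.ndarray,
    vehicle_backgrounds: np.ndarray,
    z_threshold: float = 3.0,
    min_doses: int = 2,
    spearman_min: float = 0.9,
) -> bool:
    """Autofluorescence/artifact proxy flag for one compound.

    Flag when the cargo-channel background exceeds the vehicle distribution
    by more than ``z_threshold`` SDs at ``min_doses`` or more doses, or when
    background rises monotonically with dose (Spearman rho > 0.9).
    """
    backgrounds = np.asarray(backgrounds, dtype=float)
    doses = np.asarray(doses, dtype=float)
    vehicle = np.asarray(vehicle_backgrounds, dtype=float)
    mu, sd = vehicle.mean(), vehicle.std(ddof=1)
    if sd > 0:
        z = (backgrounds - mu) / sd
        if int((z > z_threshold).sum()) >= min_doses:
            return True
    if len(doses) >= 3 and np.std(backgrounds) > 0:
        rho = stats.spearmanr(doses, backgrounds).statistic
        if rho > spearman_min:
            return True
    return False


def flag_artifact_wells(
    series_list: list[DoseSeries],
    vehicle_backgrounds: np.ndarray,
    **kwargs,
) -> dict[str, bool]:
    """Artifact flag per compound (series lacking backgrounds are unflagged)."""
    flags = {}
    for s in series_list:
        if s.backgrounds is None:
            flags[s.compound_id] = False
        else:
            flags[s.compound_id] = flag_artifact(
                s.backgrounds, s.doses, vehicle_backgrounds, **kwargs
            )
    return flags


def ec50_summary(fits: list[FourPLFit]) -> dict:
    """Median and linear-interpolation IQR over converged EC50s."""
    conv = [f.ec50 for f in fits if f.converged and math.isfinite(f.ec50)]
    if not conv:
        raise EmptySummaryError("no converged fits")
    arr = np.asarray(conv, dtype=float)
    q25, q50, q75 = np.percentile(arr, [25, 50, 75])
    return {
        "median_um": float(q50),
        "iqr_um": float(q75 - q25),
        "n_converged": len(conv),
        "n_failed": len(fits) - len(conv),
        "ec50s_um": sorted(float(v) for v in arr),
    }
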
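"""Z-score hit calling against same-plate negative controls and cascade
bookkeeping across screen stages.

Activity means the cargo ratio dropped by at least ``active_sd`` (default 3)
negative-control SDs; toxicity means the cell count dropped by at least
``toxic_sd`` (default 2) SDs.  Both boundaries are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CascadeConsistencyError, DegenerateControlsError

CLASSES = ("inactive", "active", "toxic", "active_toxic", "excluded_unquantifiable")


@dataclass
class CompoundCall:
    compound_id: str
    z_ratio: float
    z_count: float
    classification: str
    plate: str = ""
    well: str = ""


def well_zscores(wells: pd.DataFrame) -> pd.DataFrame:
    """Per-compound z-scores of ratio and cell count vs same-plate negatives.

    Expects a long table with columns plate, well, role, compound_id,
    mean_ratio, cell_count.  Returns one row per compound well with z_ratio
    and z_count columns appended.
    """
    out = []
    for plate, grp in wells.groupby("plate"):
        neg = grp[grp["role"] == "negative_control"]
        if len(neg) < 2:
            raise DegenerateControlsError(f"plate {plate}: need >= 2 negative controls")
        mu_r, sd_r = neg["mean_ratio"].mean(), neg["mean_ratio"].std(ddof=1)
        mu_c, sd_c = neg["cell_count"].mean(), neg["cell_count"].std(ddof=1)
        if sd_r == 0 or sd_c == 0:
            raise DegenerateControlsError(f"plate {plate}: degenerate negative controls")
        cpd = grp[grp["role"] == "compound"].copy()
        cpd["z_ratio"] = (cpd["mean_ratio"] - mu_r) / sd_r
        cpd["z_count"] = (cpd["cell_count"] - mu_c) / sd_c
        out.append(cpd)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame()


def classify(z_ratio: float, z_count: float, active_sd: float = 3.0, toxic_sd: float = 2.0) -> str:
    active = z_ratio <= -active_sd
    toxic = z_count <= -toxic_sd
    if active and toxic:
        return "active_toxic"
    if active:
        return "active"
    if toxic:
        return "toxic"
    return "inactive"


def classify_compounds(
    zscores: pd.DataFrame,
    exclusions: set[str] | None = None,
    active_sd: float = 3.0,
    toxic_sd: float = 2.0,
) -> list[CompoundCall]:
    """Classify compound wells; pre-excluded ids become excluded_unquantifiable."""
    exclusions = exclusions or set()
    calls = []
    for rec in zscores.itertuples(index=False):
        if rec.compound_id in exclusions:
            cls = "excluded_unquantifiable"
        else:
            cls = classify(rec.z_ratio, rec.z_count, active_sd, toxic_sd)
        calls.append(
            CompoundCall(
                compound_id=rec.compound_id,
                z_ratio=float(rec.z_ratio),
                z_count=float(rec.z_count),
                classification=cls,
                plate=getattr(rec, "plate", ""),
                well=getattr(rec, "well", ""),
            )
        )
    return calls


def calls_to_frame(calls: Sequence[CompoundCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls])


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (matching printed screen percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class Stage:
    """One triage stage: its input size, outcome counts and survivors.

    ``denominator`` defaults to ``n_input`` and is the base for percentages;
    ``survivors`` is the count carried into the next stage.
    """

    name: str
    n_input: int
    counts: Mapping[str, int]
    survivors: int
    denominator: int | None = None


@dataclass
class CascadeReport:
    stage: str
    n_input: int
    denominator: int
    counts: dict[str, int] = dc_field(default_factory=dict)
    percentages: dict[str, float] = dc_field(default_factory=dict)
    survivors: int = 0


def cascade_report(stages: Sequence[Stage]) -> list[CascadeReport]:
    """Per-stage counts and one-decimal percentages; survivors must chain.

    Percentages are always re-derived from the raw counts against each
    stage's denominator and rounded half-up to one decimal.
    """
    reports = []
    prev_survivors: int | None = None
    for st in stages:
        if prev_survivors is not None and st.n_input != prev_survivors:
            raise CascadeConsistencyError(
                f"stage {st.name!r} input {st.n_input} != previous survivors {prev_survivors}"
            )
        if st.survivors > st.n_input:
            raise CascadeConsistencyError(
                f"stage {st.name!r} survivors {st.survivors} exceed input {st.n_input}"
            )
        denom = st.denominator if st.denominator is not None else st.n_input
        if denom <= 0:
            raise CascadeConsistencyError(f"stage {st.name!r} has nonpositive denominator")
        pct = {k: round_half_up(100.0 * v / denom, 1) for k, v in st.counts.items()}
        reports.append(
            CascadeReport(
                stage=st.name,
                n_input=st.n_input,
                denominator=denom,
                counts=dict(st.counts),
                percentages=pct,
                survivors=st.survivors,
            )
        )
        prev_survivors = st.survivors
    return reports


def stages_from_calls(
    calls: Iterable[CompoundCall], stage_name: str = "primary"
) -> Stage:
    """Summarize a call list into a Stage (survivors = active compounds)."""
    counts = {c: 0 for c in CLASSES}
    n = 0
    for call in calls:
        counts[call.classification] += 1
        n += 1
    survivors = counts["active"] + counts["active_toxic"]
    return Stage(name=stage_name, n_input=n, counts=counts, survivors=survivors)
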
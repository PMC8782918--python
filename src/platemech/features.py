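"""Event records, the isoperimetric deformation metric, and gating.

Deformation is one minus circularity, 1 − 2√(πA)/P, computed from the
projected area A and perimeter P of each cell: zero for a circle and
approaching one for elongated shapes.  Gating reproduces the acquisition
conventions of platelet deformability cytometry: a hard fluorescence gate
on the platelet identity channel (CD61), a convex-hull area-ratio filter
against rough contours and aggregates, a projected-size window, and a stop
criterion (first N gated events or a wall-clock limit, whichever comes
first).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import imaging
from .synthetic import CHANNELS

logger = logging.getLogger(__name__)

__all__ = [
    "GateConfig",
    "GateAudit",
    "EVENT_COLUMNS",
    "deformation",
    "events_from_analytic",
    "events_from_contours",
    "flag_gates",
    "apply_gates",
    "acquisition_stop",
]

#: Canonical event-table columns and their units.
EVENT_COLUMNS: Mapping[str, str] = {
    "donor_id": "",
    "condition_label": "",
    "area_um2": "um^2",
    "perimeter_um": "um",
    "deformation": "dimensionless",
    "area_ratio": "dimensionless",
    "fluor_CD61": "AU",
    "fluor_CD62P": "AU",
    "fluor_PAC1": "AU",
    "timestamp_s": "s",
}

_GATE_NAMES = ("cd61", "area_ratio", "size")
_GATE_FIELD = {"cd61": "fluor_CD61", "area_ratio": "area_ratio", "size": "area_um2"}


@dataclass(frozen=True)
class GateConfig:
    """Gating thresholds and the acquisition stop criterion.

    Defaults follow standard platelet RT-FDC practice: CD61-PE hard gate
    150–33000 AU, convex-hull area ratio ≤ 1.1, projected size 0–10 µm²,
    and acquisition stopped at 5000 gated events or 600 s.
    """

    cd61_range: tuple[float, float] = (150.0, 33000.0)
    area_ratio_max: float = 1.1
    size_range: tuple[float, float] = (0.0, 10.0)
    max_events: int = 5000
    max_time_s: float = 600.0
    positivity_cutoff: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.cd61_range[0] >= self.cd61_range[1]:
            raise ValueError("cd61_range must be a non-empty interval")
        if self.size_range[0] >= self.size_range[1]:
            raise ValueError("size_range must be a non-empty interval")
        if self.area_ratio_max < 1.0:
            raise ValueError("area_ratio_max must be >= 1")
        if self.max_events < 1:
            raise ValueError("max_events must be >= 1")
        if self.max_time_s <= 0:
            raise ValueError("max_time_s must be positive")


@dataclass(frozen=True)
class GateAudit:
    """Book-keeping of one gating pass.

    ``by_gate`` counts events violating each gate (an event failing several
    gates appears under each of them); ``n_rejected`` counts unique
    rejected events, so n_input = n_kept + n_rejected always holds.
    """

    n_input: int
    n_kept: int
    n_rejected: int
    by_gate: Mapping[str, int] = field(default_factory=dict)


def deformation(area, perimeter):
    """Isoperimetric deformation 1 − 2√(π·area)/perimeter.

    Accepts scalars or arrays (µm² and µm, or any consistent units).  The
    isoperimetric inequality guarantees a non-negative result for true
    closed curves; raster contours smoothed below the bound are clamped to
    zero and the clamp count is logged.
    """
    A = np.asarray(area, dtype=float)
    P = np.asarray(perimeter, dtype=float)
    if not np.all(np.isfinite(A)) or np.any(A <= 0):
        raise ValueError("area must be finite and positive")
    if not np.all(np.isfinite(P)) or np.any(P <= 0):
        raise ValueError("perimeter must be finite and positive")
    d = 1.0 - 2.0 * np.sqrt(np.pi * A) / P
    n_clamped = int(np.count_nonzero(d < 0))
    if n_clamped:
        logger.info("deformation: clamped %d negative value(s) to 0", n_clamped)
        d = np.maximum(d, 0.0)
    return float(d) if (np.isscalar(area) and np.isscalar(perimeter)) else d


def events_from_analytic(events: pd.DataFrame, donor_id: str = "",
                         condition_label: str | None = None) -> pd.DataFrame:
    """Turn an analytic ground-truth event table into event records.

    Deformation is recomputed from (area, perimeter) rather than copied, so
    the record invariant deformation = 1 − 2√(πA)/P holds by construction.
    Analytic ellipses are convex, hence area_ratio = 1.
    """
    if len(events) == 0:
        raise ValueError("empty event table")
    out = pd.DataFrame({
        "donor_id": events["donor_id"] if "donor_id" in events else donor_id,
        "condition_label": (events["condition_label"] if "condition_label" in events
                            else (condition_label or "")),
        "area_um2": np.asarray(events["true_area_um2"], float),
        "perimeter_um": np.asarray(events["true_perimeter_um"], float),
        "area_ratio": 1.0,
        "timestamp_s": np.asarray(events["timestamp_s"], float),
    })
    out["deformation"] = deformation(out["area_um2"].to_numpy(),
                                     out["perimeter_um"].to_numpy())
    for ch in CHANNELS:
        out[f"fluor_{ch}"] = np.asarray(events[f"fluor_{ch}"], float)
    return out[list(EVENT_COLUMNS)]


def events_from_contours(contours: Sequence[imaging.Contour], pixel_size_um: float,
                         donor_id: str = "", condition_label: str = "",
                         timestamps: Sequence[float] | None = None) -> pd.DataFrame:
    """Measure a list of contours into event records (no fluorescence)."""
    rows = []
    for i, c in enumerate(contours):
        if c.pixel_size_um != 1.0:
            pixel_size = c.pixel_size_um
        else:
            pixel_size = pixel_size_um
        scaled = imaging.Contour(c.vertices, pixel_size_um=pixel_size, frame_id=c.frame_id)
        area = imaging.contour_area(scaled)
        perim = imaging.contour_perimeter(scaled)
        rows.append({
            "donor_id": donor_id,
            "condition_label": condition_label,
            "area_um2": area,
            "perimeter_um": perim,
            "deformation": deformation(area, perim),
            "area_ratio": imaging.area_ratio(scaled),
            "fluor_CD61": np.nan,
            "fluor_CD62P": np.nan,
            "fluor_PAC1": np.nan,
            "timestamp_s": float(timestamps[i]) if timestamps is not None else float(i),
        })
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


def _require(events: pd.DataFrame, fields: Sequence[str]):
    for name in fields:
        if name not in events.columns:
            raise ValueError(f"event table is missing required field {name!r}")


def flag_gates(events: pd.DataFrame, gate: GateConfig | None = None) -> pd.DataFrame:
    """Return a copy of the event table with per-gate boolean pass flags.

    Events are retained with flags (not dropped) so gate audits and
    re-gating are possible without re-processing.
    """
    if gate is None:
        gate = GateConfig()
    _require(events, [_GATE_FIELD[g] for g in _GATE_NAMES])
    out = events.copy()
    cd61 = out["fluor_CD61"].to_numpy(float)
    out["gate_cd61"] = (cd61 >= gate.cd61_range[0]) & (cd61 <= gate.cd61_range[1])
    out["gate_area_ratio"] = out["area_ratio"].to_numpy(float) <= gate.area_ratio_max
    size = out["area_um2"].to_numpy(float)
    out["gate_size"] = (size >= gate.size_range[0]) & (size <= gate.size_range[1])
    out["gates_passed"] = out["gate_cd61"] & out["gate_area_ratio"] & out["gate_size"]
    return out


def apply_gates(events: pd.DataFrame, gate: GateConfig | None = None):
    """Apply all hard gates; returns ``(kept, audit)``.

    An event is kept iff it passes the CD61 range AND the area-ratio
    maximum AND the size window.  Gating is order-independent and
    idempotent; ``audit.n_kept + audit.n_rejected == audit.n_input``.
    """
    flagged = flag_gates(events, gate)
    kept = flagged[flagged["gates_passed"]].drop(
        columns=["gate_cd61", "gate_area_ratio", "gate_size", "gates_passed"])
    by_gate = {g: int((~flagged[f"gate_{g}"]).sum()) for g in _GATE_NAMES}
    audit = GateAudit(
        n_input=len(flagged),
        n_kept=len(kept),
        n_rejected=int((~flagged["gates_passed"]).sum()),
        by_gate=by_gate,
    )
    return kept.reset_index(drop=True), audit


def acquisition_stop(events: pd.DataFrame, gate: GateConfig | None = None) -> pd.DataFrame:
    """Truncate a time-ordered gated stream at the acquisition stop.

    Keeps events up to the earlier of the ``max_events``-th event or the
    ``max_time_s`` wall-clock limit.  Timestamps must be non-decreasing.
    """
    if gate is None:
        gate = GateConfig()
    _require(events, ["timestamp_s"])
    t = events["timestamp_s"].to_numpy(float)
    if len(t) and np.any(np.diff(t) < 0):
        raise ValueError("timestamps must be non-decreasing")
    within_time = events[t <= gate.max_time_s]
    return within_time.head(gate.max_events).reset_index(drop=True)
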
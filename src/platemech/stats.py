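"""Condition-level summary statistics for gated platelet event tables.

Per-sample medians (deformation, size), geometric-mean fluorescence
(gMean), percent-positive fractions, stimulation fold changes, KDE event
densities for scatter colouring, and tidy multi-donor tables for external
statistical testing (mixed models, Tukey, Kruskal-Wallis and friends are
deliberately *not* implemented here — the tables are the interface).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import CHANNELS

__all__ = [
    "SampleSummary",
    "FoldChange",
    "MECHANICS_METRICS",
    "summarize_sample",
    "percent_positive",
    "positivity_cutoff",
    "fold_change",
    "kde_density",
    "condition_panel_table",
    "condition_means",
]

#: Metrics where stimulation *lowers* the value, so the conventional fold
#: change is unstim/stim ("decrease by a factor"); fluorescence metrics use
#: stim/unstim ("increase by a factor").
MECHANICS_METRICS = frozenset({"deformation", "median_deformation",
                               "area_um2", "median_area_um2", "size"})


@dataclass(frozen=True)
class SampleSummary:
    donor_id: str
    condition_label: str
    n_events: int
    median_deformation: float
    median_area_um2: float
    gmean_fluor: Mapping[str, float] = field(default_factory=dict)
    pct_positive: Mapping[str, float] = field(default_factory=dict)
    n_nonpositive: Mapping[str, int] = field(default_factory=dict)

    def metric(self, name: str) -> float:
        """Look up a metric by tidy-table name (e.g. 'gmean_CD62P')."""
        if name in ("median_deformation", "deformation"):
            return self.median_deformation
        if name in ("median_area_um2", "area_um2", "size"):
            return self.median_area_um2
        if name.startswith("gmean_"):
            return self.gmean_fluor[name[len("gmean_"):]]
        if name.startswith("pct_positive_"):
            return self.pct_positive[name[len("pct_positive_"):]]
        raise KeyError(f"unknown metric {name!r}")


@dataclass(frozen=True)
class FoldChange:
    donor_id: str
    condition_label: str
    metric: str
    ratio: float


def _gmean(values: np.ndarray) -> tuple[float, int]:
    """Geometric mean over strictly positive values; returns the count of
    excluded non-positive (or non-finite) values alongside."""
    finite = values[np.isfinite(values)]
    positive = finite[finite > 0]
    n_excluded = len(values) - len(positive)
    if len(positive) == 0:
        return float("nan"), n_excluded
    return float(np.exp(np.mean(np.log(positive)))), n_excluded


def summarize_sample(events: pd.DataFrame,
                     cutoffs: Mapping[str, float] | None = None) -> SampleSummary:
    """Summarise one gated sample: medians, per-channel gMean and, when
    positivity cutoffs are supplied, percent-positive fractions.

    Medians use the midpoint convention for even counts (numpy default);
    gMean = exp(mean(ln intensity)) over strictly positive intensities,
    with excluded non-positive values counted in ``n_nonpositive``.
    """
    if len(events) == 0:
        raise ValueError("cannot summarise a sample with zero events")
    donor = str(events["donor_id"].iloc[0]) if "donor_id" in events else ""
    condition = str(events["condition_label"].iloc[0]) if "condition_label" in events else ""
    gmeans, n_nonpos, pct = {}, {}, {}
    for ch in CHANNELS:
        col = f"fluor_{ch}"
        if col not in events:
            continue
        values = events[col].to_numpy(float)
        if np.all(np.isnan(values)):
            continue
        gmeans[ch], n_nonpos[ch] = _gmean(values)
        if cutoffs and ch in cutoffs:
            pct[ch] = percent_positive(values[np.isfinite(values)], cutoffs[ch])
    return SampleSummary(
        donor_id=donor,
        condition_label=condition,
        n_events=len(events),
        median_deformation=float(np.median(events["deformation"])),
        median_area_um2=float(np.median(events["area_um2"])),
        gmean_fluor=gmeans,
        pct_positive=pct,
        n_nonpositive=n_nonpos,
    )


def percent_positive(intensities, cutoff: float) -> float:
    """Percentage of events with intensity strictly above the cutoff."""
    if not (np.isfinite(cutoff) and cutoff > 0):
        raise ValueError("cutoff must be positive")
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("empty intensity list")
    return 100.0 * float(np.count_nonzero(x > cutoff)) / x.size


def positivity_cutoff(control_intensities, q: float = 99.0) -> float:
    """Positivity cutoff as a percentile of the matched non-stimulated
    (vehicle-control) sample — a standard isotype/FMO-style surrogate when
    no instrument cutoff is recorded.  Default: 99th percentile."""
    x = np.asarray(control_intensities, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("empty control sample")
    return float(np.percentile(x, q))


def fold_change(stim: SampleSummary, unstim: SampleSummary, metric: str) -> FoldChange:
    """Stimulation fold change for one donor and one metric.

    Directions follow the reporting convention: mechanics metrics
    (deformation, size) are quoted as a *decrease* factor unstim/stim,
    fluorescence metrics (CD62P, PAC-1, F-actin, ...) as an *increase*
    factor stim/unstim — both read "changed by a factor of" with a baseline
    of 1.
    """
    if stim.donor_id != unstim.donor_id:
        raise ValueError("fold change requires summaries from the same donor")
    s = stim.metric(metric)
    u = unstim.metric(metric)
    if metric in MECHANICS_METRICS:
        num, den = u, s
    else:
        num, den = s, u
    if den == 0 or not np.isfinite(den):
        raise ValueError(f"zero or non-finite denominator for metric {metric!r}")
    return FoldChange(donor_id=stim.donor_id, condition_label=stim.condition_label,
                      metric=metric, ratio=float(num / den))


def kde_density(x, y, scale: bool = True, chunk: int = 512) -> np.ndarray:
    """Per-event bivariate kernel density for scatter-plot colouring.

    Gaussian product kernel with Scott's-rule bandwidth per axis
    (h_i = σ_i · n^(−1/6) for two dimensions), evaluated at every event.
    With ``scale=True`` the densities are min-max scaled to [0, 1] for a
    linear colour scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 10:
        raise ValueError("KDE needs at least 10 events")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("KDE inputs must be finite")
    sx, sy = float(np.std(x, ddof=1)), float(np.std(y, ddof=1))
    if sx == 0 or sy == 0:
        raise ValueError("degenerate axis: zero variance")
    hx = sx * n ** (-1.0 / 6.0)
    hy = sy * n ** (-1.0 / 6.0)
    u = x / hx
    v = y / hy
    dens = np.empty(n)
    norm = 1.0 / (n * 2.0 * np.pi * hx * hy)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        du = u[start:stop, None] - u[None, :]
        dv = v[start:stop, None] - v[None, :]
        dens[start:stop] = norm * np.exp(-0.5 * (du * du + dv * dv)).sum(axis=1)
    if not scale:
        return dens
    lo, hi = dens.min(), dens.max()
    if hi == lo:
        return np.zeros(n)
    return (dens - lo) / (hi - lo)


def condition_panel_table(summaries: Sequence[SampleSummary]) -> pd.DataFrame:
    """Tidy long-format table: one row per (donor, condition, metric).

    Missing metrics appear as NaN (explicit missing marker).  Round-trips
    losslessly through ``DataFrame.to_csv`` / ``read_csv``.
    """
    if len(summaries) == 0:
        raise ValueError("no summaries given")
    rows = []
    metric_names = ["median_deformation", "median_area_um2"]
    gmean_names = sorted({ch for s in summaries for ch in s.gmean_fluor})
    pct_names = sorted({ch for s in summaries for ch in s.pct_positive})
    for s in summaries:
        for m in metric_names:
            rows.append((s.donor_id, s.condition_label, m, s.metric(m)))
        for ch in gmean_names:
            rows.append((s.donor_id, s.condition_label, f"gmean_{ch}",
                         s.gmean_fluor.get(ch, np.nan)))
        for ch in pct_names:
            rows.append((s.donor_id, s.condition_label, f"pct_positive_{ch}",
                         s.pct_positive.get(ch, np.nan)))
    return pd.DataFrame(rows, columns=["donor_id", "condition_label", "metric", "value"])


def condition_means(panel: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD across donors for each (condition, metric) of a tidy panel."""
    grouped = panel.groupby(["condition_label", "metric"])["value"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n_donors="count")
    return out.reset_index()
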
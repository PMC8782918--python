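"""Synthetic single-platelet populations for deformability cytometry.

The generator emulates the statistical structure of real-time deformability
cytometry (RT-DC) measurements of human platelets in a 15 x 15 µm
microfluidic constriction, in two modes:

* **analytic** — events carry exact ellipse geometry (area, perimeter,
  deformation) so the downstream feature/statistics pipeline can be tested
  against closed-form ground truth without any imaging step;
* **raster** — :func:`render_frame` rasterises single events into
  anti-aliased bright-field frames (with channel walls, configurable blur
  and noise) for the segmentation pipeline, and
  :func:`render_confocal_platelet` produces two-channel confocal-like
  images (marginal-band tubulin ring, F-actin disc) for line-profile
  analysis.

Event-level deformation, projected area and per-channel fluorescence maxima
are log-normal (strictly positive, right-skewed — the usual cytometry
convention).  Built-in :data:`PRESETS` encode condition-level medians of
human platelet populations for five ex vivo anticoagulants (ACD-A,
Na-Citrate, K2-EDTA, Li-Heparin, r-Hirudin), with and without TRAP-6
stimulation, latrunculin-B-like softening, and an MYH9-like (large, stiff)
macrothrombocytopenia phenotype.  Donor-level variability is a mean-one
multiplicative jitter applied to the preset medians, so across many donors
the expected mean of per-donor medians equals the preset value.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ellipe

from .imaging import Contour

__all__ = [
    "CHANNELS",
    "DEFORMATION_MAX",
    "ChannelModel",
    "PopulationModel",
    "GroundTruthEvent",
    "ImagingConfig",
    "PRESETS",
    "preset",
    "ellipse_geometry",
    "aspect_deformation",
    "solve_aspect_for_deformation",
    "sample_events",
    "simulate_donor_panel",
    "render_frame",
    "render_confocal_platelet",
]

#: Fluorescence channels carried by every event (platelet identity marker,
#: alpha-granule release marker, activated-integrin reporter).
CHANNELS = ("CD61", "CD62P", "PAC1")

#: Upper truncation of the event-level deformation distribution.
DEFORMATION_MAX = 0.6


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# population description
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelModel:
    """Log-normal fluorescence model for one channel.

    ``gmean`` is the geometric mean (= median) in arbitrary units; since the
    distribution is log-normal the population geometric mean equals
    exp(location).  ``sigma_log`` is the natural-log-scale spread.
    """

    gmean: float
    sigma_log: float = 0.8

    def __post_init__(self):
        if not (np.isfinite(self.gmean) and self.gmean > 0):
            raise ValueError("gmean must be positive and finite")
        if not (np.isfinite(self.sigma_log) and self.sigma_log >= 0):
            raise ValueError("sigma_log must be non-negative")


def _freeze(mapping: Mapping) -> Mapping:
    return MappingProxyType(dict(mapping))


@dataclass(frozen=True)
class PopulationModel:
    """Generative description of one platelet population.

    One model per (anticoagulant x stimulation x treatment x phenotype)
    condition.  Medians are population medians; ``*_cv`` are event-level
    coefficients of variation; ``donor_sd`` maps metric names
    ('deformation', 'area', 'CD61', 'CD62P', 'PAC1') to the relative
    between-donor SD of per-donor medians; ``response_sd`` (stimulated
    conditions only) maps metric names to the relative between-donor SD of
    the stimulation fold change.
    """

    condition_label: str
    anticoagulant: str
    deformation_median: float
    area_median: float
    stimulation: str = "none"
    treatment: str = "vehicle"
    phenotype: str = "healthy"
    deformation_cv: float = 0.35
    area_cv: float = 0.30
    fluor: Mapping[str, ChannelModel] = field(default_factory=dict)
    donor_sd: Mapping[str, float] = field(default_factory=dict)
    response_sd: Mapping[str, float] = field(default_factory=dict)
    event_rate: float = 50.0

    def __post_init__(self):
        if not (np.isfinite(self.deformation_median) and 0 < self.deformation_median < 1):
            raise ValueError("deformation_median must be in (0, 1)")
        if not (np.isfinite(self.area_median) and self.area_median > 0):
            raise ValueError("area_median must be positive")
        for name, value in (("deformation_cv", self.deformation_cv), ("area_cv", self.area_cv)):
            if not (np.isfinite(value) and value >= 0):
                raise ValueError(f"{name} must be non-negative")
        if not (np.isfinite(self.event_rate) and self.event_rate > 0):
            raise ValueError("event_rate must be positive (events/s)")
        object.__setattr__(self, "fluor", _freeze(self.fluor))
        object.__setattr__(self, "donor_sd", _freeze(self.donor_sd))
        object.__setattr__(self, "response_sd", _freeze(self.response_sd))


@dataclass(frozen=True)
class GroundTruthEvent:
    """Exact geometry and signal of one simulated cell."""

    true_area_um2: float
    true_perimeter_um: float
    true_deformation: float
    aspect_ratio: float
    orientation: float = 0.0
    center_um: tuple[float, float] = (0.0, 0.0)
    fluor_true: Mapping[str, float] = field(default_factory=dict)
    timestamp_s: float = 0.0

    @classmethod
    def from_row(cls, row: Mapping) -> "GroundTruthEvent":
        return cls(
            true_area_um2=float(row["true_area_um2"]),
            true_perimeter_um=float(row["true_perimeter_um"]),
            true_deformation=float(row["true_deformation"]),
            aspect_ratio=float(row["aspect_ratio"]),
            orientation=float(row.get("orientation", 0.0)),
            center_um=(float(row.get("center_x_um", 0.0)), float(row.get("center_y_um", 0.0))),
            fluor_true={ch: float(row[f"fluor_{ch}"]) for ch in CHANNELS if f"fluor_{ch}" in row},
            timestamp_s=float(row.get("timestamp_s", 0.0)),
        )


# --------------------------------------------------------------------------
# ellipse shape model
# --------------------------------------------------------------------------

def ellipse_geometry(aspect_ratio, area):
    """Exact (area, perimeter) of an ellipse with the given aspect ratio.

    Semi-axes are a = q·b with π·a·b = area; the circumference is
    4·a·E(1 - b²/a²) with E the complete elliptic integral of the second
    kind, so the returned perimeter is exact to machine precision.
    """
    q = np.asarray(aspect_ratio, dtype=float)
    A = np.asarray(area, dtype=float)
    if not np.all(np.isfinite(q)) or np.any(q < 1):
        raise ValueError("aspect_ratio must be finite and >= 1")
    if not np.all(np.isfinite(A)) or np.any(A <= 0):
        raise ValueError("area must be finite and positive")
    b = np.sqrt(A / (np.pi * q))
    a = q * b
    m = 1.0 - (b / a) ** 2
    perimeter = 4.0 * a * ellipe(m)
    if np.isscalar(aspect_ratio) and np.isscalar(area):
        return float(A), float(perimeter)
    return A + 0.0, perimeter


def aspect_deformation(aspect_ratio):
    """Deformation 1 − 2√(πA)/P of an ellipse; scale-free in the area."""
    q = np.asarray(aspect_ratio, dtype=float)
    if not np.all(np.isfinite(q)) or np.any(q < 1):
        raise ValueError("aspect_ratio must be finite and >= 1")
    m = 1.0 - 1.0 / q**2
    d = 1.0 - np.pi / (2.0 * np.sqrt(q) * ellipe(m))
    return float(d) if np.isscalar(aspect_ratio) else d


_ASPECT_MAX = 1.0e4


def solve_aspect_for_deformation(d):
    """Invert the ellipse shape model: aspect ratio producing deformation d.

    Vectorised bisection on [1, 1e4]; the deformation of an ellipse is a
    strictly increasing, scale-free function of its aspect ratio, so the
    root is unique.  Converges well below 1e-9 in deformation.
    """
    d_arr = np.atleast_1d(np.asarray(d, dtype=float))
    if not np.all(np.isfinite(d_arr)) or np.any(d_arr < 0) or np.any(d_arr >= 1):
        raise ValueError("deformation must be in [0, 1)")
    d_max = aspect_deformation(_ASPECT_MAX)
    if np.any(d_arr > d_max):
        raise ValueError(f"deformation above {d_max:.6f} is outside the bracket [1, 1e4]")
    lo = np.ones_like(d_arr)
    hi = np.full_like(d_arr, _ASPECT_MAX)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        too_high = aspect_deformation(mid) >= d_arr
        hi = np.where(too_high, mid, hi)
        lo = np.where(too_high, lo, mid)
    result = 0.5 * (lo + hi)
    return float(result[0]) if np.isscalar(d) else result


# --------------------------------------------------------------------------
# event sampling
# --------------------------------------------------------------------------

def _lognormal(rng: np.random.Generator, median: float, cv: float, n: int,
               upper: float | None = None) -> np.ndarray:
    """Log-normal sample with given median and coefficient of variation,
    rejection-truncated at ``upper`` (truncation mass is negligible for all
    built-in presets, so the median is preserved)."""
    sigma = math.sqrt(math.log1p(cv * cv))
    x = median * np.exp(sigma * rng.standard_normal(n))
    if upper is not None:
        bad = x > upper
        while np.any(bad):
            x[bad] = median * np.exp(sigma * rng.standard_normal(int(bad.sum())))
            bad = x > upper
    return x


def sample_events(model: PopulationModel, n: int, seed) -> pd.DataFrame:
    """Draw ``n`` analytic ground-truth events from a population model.

    Deformation is log-normal (median ``deformation_median``, CV
    ``deformation_cv``) truncated to [0, 0.6]; each drawn deformation is
    mapped to an ellipse aspect ratio so that the isoperimetric formula
    applied to the returned (area, perimeter) reproduces it exactly.
    Projected area and per-channel fluorescence are independent log-normals;
    timestamps follow a homogeneous Poisson process at ``event_rate``.
    Reproducible given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    d = _lognormal(rng, model.deformation_median, model.deformation_cv, n, upper=DEFORMATION_MAX)
    q = solve_aspect_for_deformation(d)
    area = _lognormal(rng, model.area_median, model.area_cv, n)
    A, P = ellipse_geometry(q, area)
    true_d = 1.0 - 2.0 * np.sqrt(np.pi * A) / P
    columns = {
        "true_area_um2": A,
        "true_perimeter_um": P,
        "true_deformation": true_d,
        "aspect_ratio": q,
        "orientation": np.zeros(n),
        "center_x_um": np.zeros(n),
        "center_y_um": rng.uniform(-0.5, 0.5, n),
    }
    for ch in CHANNELS:
        cm = model.fluor.get(ch)
        if cm is None:
            columns[f"fluor_{ch}"] = np.full(n, np.nan)
        else:
            columns[f"fluor_{ch}"] = cm.gmean * np.exp(cm.sigma_log * rng.standard_normal(n))
    columns["timestamp_s"] = np.cumsum(rng.exponential(1.0 / model.event_rate, n))
    return pd.DataFrame(columns)


_JITTER_METRICS = ("deformation", "area") + CHANNELS


def _mean_one_lognormal(rng: np.random.Generator, rel_sd: float) -> float:
    """Multiplicative jitter with expectation exactly 1."""
    if rel_sd <= 0:
        return 1.0
    sigma = math.sqrt(math.log1p(rel_sd * rel_sd))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def _matched_unstim(model: PopulationModel, models: Sequence[PopulationModel]):
    if model.stimulation == "none":
        return None
    for other in models:
        if (other.stimulation == "none"
                and other.anticoagulant == model.anticoagulant
                and other.treatment == model.treatment
                and other.phenotype == model.phenotype):
            return other
    return None


def simulate_donor_panel(presets, n_donors: int = 6, n_events: int = 5000,
                         seed=0) -> pd.DataFrame:
    """Simulate a multi-donor panel of conditions, one event table per
    (donor, condition).

    Per donor, a mean-one multiplicative jitter (relative SD ``donor_sd``)
    is drawn for each metric of each non-stimulated condition.  A
    stimulated condition whose matched non-stimulated partner (same
    anticoagulant / treatment / phenotype) is in the panel *shares* that
    donor jitter, and its stimulation fold factor gets its own mean-one
    jitter (relative SD ``response_sd``) — so per-donor fold changes are
    donor-consistent and their across-donor mean is unbiased at the preset
    fold.  Random streams are split hierarchically (panel → donor →
    condition): adding donors does not perturb earlier donors.
    """
    if n_donors < 1:
        raise ValueError("n_donors must be >= 1")
    models = [preset(p) if isinstance(p, str) else p for p in presets]
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    donor_seqs = root.spawn(n_donors)
    frames = []
    for i, dseq in enumerate(donor_seqs):
        donor_id = f"D{i + 1:02d}"
        streams = dseq.spawn(len(models) + 1)
        jrng = np.random.default_rng(streams[0])
        base_jitter: dict[int, dict[str, float]] = {}
        donor_models = []
        for model in models:
            partner = _matched_unstim(model, models)
            if partner is None:
                jit = {m: _mean_one_lognormal(jrng, float(model.donor_sd.get(m, 0.0)))
                       for m in _JITTER_METRICS}
                base_jitter[id(model)] = jit
                donor_models.append(_apply_jitter(model, jit))
            else:
                jit = base_jitter.get(id(partner))
                if jit is None:  # partner listed after the stimulated preset
                    jit = {m: _mean_one_lognormal(jrng, float(partner.donor_sd.get(m, 0.0)))
                           for m in _JITTER_METRICS}
                    base_jitter[id(partner)] = jit
                resp = {m: _mean_one_lognormal(jrng, float(model.response_sd.get(m, 0.0)))
                        for m in _JITTER_METRICS}
                donor_models.append(_apply_paired_jitter(model, partner, jit, resp))
        for k, (model, donor_model) in enumerate(zip(models, donor_models)):
            events = sample_events(donor_model, n_events, streams[1 + k])
            events.insert(0, "condition_label", model.condition_label)
            events.insert(0, "donor_id", donor_id)
            frames.append(events)
    return pd.concat(frames, ignore_index=True)


def _apply_jitter(model: PopulationModel, jit: Mapping[str, float]) -> PopulationModel:
    fluor = {ch: replace(cm, gmean=cm.gmean * jit.get(ch, 1.0))
             for ch, cm in model.fluor.items()}
    return replace(model,
                   deformation_median=model.deformation_median * jit["deformation"],
                   area_median=model.area_median * jit["area"],
                   fluor=fluor)


def _apply_paired_jitter(stim: PopulationModel, unstim: PopulationModel,
                         jit: Mapping[str, float], resp: Mapping[str, float]) -> PopulationModel:
    """Donor-level medians for a stimulated condition, anchored to the
    matched non-stimulated condition of the same donor.

    Mechanics fold (a *decrease* factor, unstim/stim) and fluorescence fold
    (an *increase* factor, stim/unstim) are jittered multiplicatively with
    mean one, so E[per-donor fold] equals the preset fold.
    """
    d_fold = (unstim.deformation_median / stim.deformation_median) * resp["deformation"]
    a_fold = (unstim.area_median / stim.area_median) * resp["area"]
    fluor = {}
    for ch, cm in stim.fluor.items():
        base = unstim.fluor.get(ch)
        if base is None:
            fluor[ch] = replace(cm, gmean=cm.gmean * resp.get(ch, 1.0))
        else:
            f_fold = (cm.gmean / base.gmean) * resp.get(ch, 1.0)
            fluor[ch] = replace(cm, gmean=base.gmean * jit.get(ch, 1.0) * f_fold)
    return replace(stim,
                   deformation_median=unstim.deformation_median * jit["deformation"] / d_fold,
                   area_median=unstim.area_median * jit["area"] / a_fold,
                   fluor=fluor)


# --------------------------------------------------------------------------
# built-in condition presets
# --------------------------------------------------------------------------

_CD61_GMEAN = 2000.0     # AU; comfortably inside the 150-33000 hard gate
_CD62P_BASAL = 10.0      # AU; basal alpha-granule marker, anticoagulant-independent
_FLUOR_SIGMA = 0.8
_CD61_SIGMA = 0.5

# Non-stimulated condition medians (mean of per-donor medians) and their
# between-donor SDs: deformation, projected area (µm²).  Areas for
# Na-Citrate and r-Hirudin are interpolated choices (only three conditions
# have published sizes); see docs/methods.md.
_UNSTIM = {
    "ACD-A":      dict(d=0.127, d_sd=0.033, a=5.035, a_sd=0.49),
    "Na-Citrate": dict(d=0.111, d_sd=0.025, a=4.90,  a_sd=0.40),
    "K2-EDTA":    dict(d=0.037, d_sd=0.010, a=4.158, a_sd=0.241),
    "Li-Heparin": dict(d=0.071, d_sd=0.016, a=4.337, a_sd=0.344),
    "r-Hirudin":  dict(d=0.100, d_sd=0.023, a=4.70,  a_sd=0.40),
}

# TRAP-6 stimulation fold factors (mean, SD across donors): deformation and
# size *decrease* folds (unstim/stim), CD62P and PAC-1 *increase* folds
# (stim/unstim).
_TRAP6 = {
    "ACD-A":      dict(d=(2.76, 0.64), a=(1.28, 0.13), cd62p=(18.19, 8.88), pac1=(2.86, 0.82)),
    "Na-Citrate": dict(d=(2.58, 0.49), a=(1.14, 0.14), cd62p=(21.48, 8.54), pac1=(3.39, 0.90)),
    "K2-EDTA":    dict(d=(1.14, 0.33), a=(0.98, 0.08), cd62p=(2.03, 1.16),  pac1=(1.00, 0.15)),
    "Li-Heparin": dict(d=(1.72, 0.47), a=(1.04, 0.04), cd62p=(9.82, 7.78),  pac1=(2.64, 0.70)),
    "r-Hirudin":  dict(d=(2.27, 0.45), a=(1.18, 0.16), cd62p=(15.72, 6.76), pac1=(3.55, 0.98)),
}

# Basal activated-integrin (PAC-1) gMean: highest in Li-Heparin, lowest in
# K2-EDTA; only the Li-Heparin value is published, the rest are ordering-
# consistent choices.
_PAC1_BASAL = {
    "ACD-A": 35.0, "Na-Citrate": 30.0, "K2-EDTA": 12.0,
    "Li-Heparin": 82.48, "r-Hirudin": 25.0,
}

# Latrunculin-B softening: qualitative multiplicative increase of the
# deformation median over the matched vehicle condition (largest in ACD-A
# for resting platelets).  No published medians; see docs/methods.md.
_LATB_FACTOR_REST = {
    "ACD-A": 1.6, "Na-Citrate": 1.4, "K2-EDTA": 1.5,
    "Li-Heparin": 1.4, "r-Hirudin": 1.4,
}
_LATB_FACTOR_STIM = 1.5


def _fluor_basal(ac: str) -> dict[str, ChannelModel]:
    return {
        "CD61": ChannelModel(_CD61_GMEAN, _CD61_SIGMA),
        "CD62P": ChannelModel(_CD62P_BASAL, _FLUOR_SIGMA),
        "PAC1": ChannelModel(_PAC1_BASAL[ac], _FLUOR_SIGMA),
    }


def _build_presets() -> dict[str, PopulationModel]:
    presets: dict[str, PopulationModel] = {}
    for ac, u in _UNSTIM.items():
        donor_sd = {
            "deformation": u["d_sd"] / u["d"],
            "area": u["a_sd"] / u["a"],
            "CD61": 0.10, "CD62P": 0.30, "PAC1": 0.30,
        }
        label = f"{ac}:none"
        presets[label] = PopulationModel(
            condition_label=label, anticoagulant=ac,
            deformation_median=u["d"], area_median=u["a"],
            fluor=_fluor_basal(ac), donor_sd=donor_sd,
        )
        t = _TRAP6[ac]
        fluor_stim = {
            "CD61": ChannelModel(_CD61_GMEAN, _CD61_SIGMA),
            "CD62P": ChannelModel(_CD62P_BASAL * t["cd62p"][0], _FLUOR_SIGMA),
            "PAC1": ChannelModel(_PAC1_BASAL[ac] * t["pac1"][0], _FLUOR_SIGMA),
        }
        label_s = f"{ac}:TRAP-6"
        presets[label_s] = PopulationModel(
            condition_label=label_s, anticoagulant=ac, stimulation="TRAP-6",
            deformation_median=u["d"] / t["d"][0], area_median=u["a"] / t["a"][0],
            fluor=fluor_stim, donor_sd=donor_sd,
            response_sd={
                "deformation": t["d"][1] / t["d"][0],
                "area": t["a"][1] / t["a"][0],
                "CD62P": t["cd62p"][1] / t["cd62p"][0],
                "PAC1": t["pac1"][1] / t["pac1"][0],
            },
        )
        # latrunculin-B softened variants (qualitative calibration)
        label_l = f"{ac}:none:LatB"
        presets[label_l] = replace(
            presets[label], condition_label=label_l, treatment="LatB",
            deformation_median=min(u["d"] * _LATB_FACTOR_REST[ac], 0.3))
        label_ls = f"{ac}:TRAP-6:LatB"
        presets[label_ls] = replace(
            presets[label_s], condition_label=label_ls, treatment="LatB",
            deformation_median=min(presets[label_s].deformation_median * _LATB_FACTOR_STIM, 0.3))
    # MYH9-like (large, stiff) phenotype and its same-day healthy reference,
    # single-individual values: no donor-level jitter.
    single = [
        ("MYH9:ACD-A:none", "ACD-A", "none", "MYH9-like", 0.068, 5.77),
        ("MYH9:ACD-A:TRAP-6", "ACD-A", "TRAP-6", "MYH9-like", 0.036, 6.585),
        ("MYH9:K2-EDTA:none", "K2-EDTA", "none", "MYH9-like", 0.0195, 7.515),
        ("MYH9:K2-EDTA:TRAP-6", "K2-EDTA", "TRAP-6", "MYH9-like", 0.0195, 7.515),
        ("healthy-ref:ACD-A:none", "ACD-A", "none", "healthy", 0.122, 4.05),
        ("healthy-ref:ACD-A:TRAP-6", "ACD-A", "TRAP-6", "healthy", 0.0455, 2.595),
        ("healthy-ref:K2-EDTA:none", "K2-EDTA", "none", "healthy", 0.036, 3.27),
        ("healthy-ref:K2-EDTA:TRAP-6", "K2-EDTA", "TRAP-6", "healthy", 0.036, 3.27),
    ]
    for label, ac, stim, pheno, d_med, a_med in single:
        presets[label] = PopulationModel(
            condition_label=label, anticoagulant=ac, stimulation=stim,
            phenotype=pheno, deformation_median=d_med, area_median=a_med,
            fluor=_fluor_basal(ac))
    return presets


PRESETS: Mapping[str, PopulationModel] = MappingProxyType(_build_presets())


def preset(name: str) -> PopulationModel:
    """Look up a built-in condition preset by label, e.g. ``'ACD-A:none'``."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {', '.join(sorted(PRESETS))}"
        ) from None


# --------------------------------------------------------------------------
# raster rendering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ImagingConfig:
    """Bright-field frame geometry and optics.

    The field of view spans the full 15 µm channel height plus the walls
    (rendered as dark bands).  ``cell_contrast`` is the intensity drop of a
    fully covered cell pixel below background; blur is a Gaussian
    point-spread approximation; noise is additive Gaussian.
    """

    pixel_size_um: float = 0.34
    frame_width_um: float = 20.0
    channel_height_um: float = 15.0
    wall_thickness_um: float = 1.0
    background: float = 1.0
    cell_contrast: float = 0.5
    wall_contrast: float = 0.6
    blur_sigma_um: float = 0.0
    noise_sd: float = 0.0
    supersample: int = 8

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        width = int(round(self.frame_width_um / self.pixel_size_um))
        wall = max(1, int(round(self.wall_thickness_um / self.pixel_size_um)))
        channel = int(round(self.channel_height_um / self.pixel_size_um))
        return channel + 2 * wall, width

    @property
    def wall_px(self) -> int:
        return max(1, int(round(self.wall_thickness_um / self.pixel_size_um)))


def _fine_axis(n: int, s: int) -> np.ndarray:
    """Supersampled pixel-centre coordinates in coarse-pixel units."""
    return (np.arange(n * s) + 0.5) / s - 0.5


def render_frame(event, config: ImagingConfig | None = None, seed=None):
    """Rasterise one event into a bright-field frame.

    Returns ``(image, truth)`` where ``truth`` is the sub-pixel ellipse
    boundary as a :class:`~platemech.imaging.Contour` in pixel coordinates.
    ``event`` may be ``None`` for a background-only frame (then ``truth`` is
    ``None``).  The ellipse coverage is computed on a ``supersample``-fold
    finer grid and box-averaged, giving an anti-aliased edge whose
    half-coverage level set tracks the true boundary.
    """
    if config is None:
        config = ImagingConfig()
    if event is not None and not isinstance(event, GroundTruthEvent):
        event = GroundTruthEvent.from_row(event)
    H, W = config.shape
    ps = config.pixel_size_um
    image = np.full((H, W), config.background, dtype=float)
    wall = config.wall_px
    image[:wall, :] -= config.wall_contrast
    image[H - wall:, :] -= config.wall_contrast
    truth = None
    if event is not None:
        q = event.aspect_ratio
        b = math.sqrt(event.true_area_um2 / (math.pi * q))
        a = q * b
        theta = event.orientation
        cx, cy = event.center_um
        ext_x = math.hypot(a * math.cos(theta), b * math.sin(theta))
        ext_y = math.hypot(a * math.sin(theta), b * math.cos(theta))
        if (abs(cx) + ext_x > config.frame_width_um / 2 - ps
                or abs(cy) + ext_y > config.channel_height_um / 2 - ps):
            raise ValueError("cell does not fit inside the field of view / channel")
        s = config.supersample
        col = _fine_axis(W, s)
        row = _fine_axis(H, s)
        x_um = (col - (W - 1) / 2) * ps - cx
        y_um = (row - (H - 1) / 2) * ps - cy
        X, Y = np.meshgrid(x_um, y_um)
        ct, st = math.cos(theta), math.sin(theta)
        U = X * ct + Y * st
        V = -X * st + Y * ct
        inside = (U / a) ** 2 + (V / b) ** 2 <= 1.0
        coverage = inside.reshape(H, s, W, s).mean(axis=(1, 3))
        image -= config.cell_contrast * coverage
        t = np.linspace(0.0, 2.0 * math.pi, 721)[:-1]
        bx = a * np.cos(t) * ct - b * np.sin(t) * st + cx
        by = a * np.cos(t) * st + b * np.sin(t) * ct + cy
        truth = Contour(
            vertices=np.column_stack([bx / ps + (W - 1) / 2, by / ps + (H - 1) / 2]),
            pixel_size_um=ps, frame_id="truth")
    if config.blur_sigma_um > 0:
        from scipy.ndimage import gaussian_filter
        image = gaussian_filter(image, config.blur_sigma_um / ps)
    if config.noise_sd > 0:
        image = image + _rng(seed).normal(0.0, config.noise_sd, image.shape)
    return image, truth


# --------------------------------------------------------------------------
# confocal rendering (cytoskeleton line-profile ground truth)
# --------------------------------------------------------------------------

def render_confocal_platelet(radius_um: float, tubulin_mode: str = "ring",
                             actin_mode: str = "uniform", *,
                             pixel_size_um: float = 0.08,
                             fov_um: float | None = None,
                             ring_sigma_um: float = 0.15,
                             coiled_sigma_um: float = 0.08,
                             edge_weight: float = 2.0,
                             band_frac: float = 0.25,
                             noise_sd: float = 0.0,
                             seed=None) -> dict[str, np.ndarray]:
    """Two-channel confocal-like image of a single spread platelet.

    The tubulin channel is a circular annulus (the marginal band) with a
    Gaussian radial cross-section centred at ``radius_um`` — narrower in
    ``coiled`` mode, emulating a condensed ring.  The actin channel is a
    disc of the same radius, uniform or with the outer ``band_frac``
    fraction of the radius weighted by ``edge_weight`` (subcortical
    enrichment).  Ground truth: the tubulin edge-to-edge distance along any
    diameter is 2·radius; the actin peripheral index over the standard
    25 % / 50 % bands equals ``edge_weight`` in subcortical mode.
    """
    if not (0.5 < radius_um < 5.0):
        raise ValueError("radius_um must be in (0.5, 5) µm")
    if tubulin_mode not in ("ring", "coiled"):
        raise ValueError("tubulin_mode must be 'ring' or 'coiled'")
    if actin_mode not in ("uniform", "subcortical"):
        raise ValueError("actin_mode must be 'uniform' or 'subcortical'")
    if fov_um is None:
        # large enough for the platelet and for a standard 5 µm line profile
        fov_um = max(2.0 * radius_um + 3.0, 6.0)
    n = int(round(fov_um / pixel_size_um)) | 1  # odd: platelet centred on a pixel
    c = (n - 1) / 2
    idx = np.arange(n)
    X, Y = np.meshgrid((idx - c) * pixel_size_um, (idx - c) * pixel_size_um)
    rho = np.hypot(X, Y)
    sigma = ring_sigma_um if tubulin_mode == "ring" else coiled_sigma_um
    tubulin = np.exp(-0.5 * ((rho - radius_um) / sigma) ** 2)
    # anti-aliased radial indicator functions (half-pixel soft edges)
    disc = np.clip((radius_um - rho) / pixel_size_um + 0.5, 0.0, 1.0)
    actin = disc.copy()
    if actin_mode == "subcortical":
        inner = (1.0 - band_frac) * radius_um
        band = (np.clip((rho - inner) / pixel_size_um + 0.5, 0.0, 1.0)
                * np.clip((radius_um - rho) / pixel_size_um + 0.5, 0.0, 1.0))
        actin = disc + (edge_weight - 1.0) * band
    if noise_sd > 0:
        rng = _rng(seed)
        tubulin = tubulin + rng.normal(0.0, noise_sd, tubulin.shape)
        actin = actin + rng.normal(0.0, noise_sd, actin.shape)
    return {"tubulin": tubulin, "actin": actin}
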
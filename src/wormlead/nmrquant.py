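"""Internal drug concentration from 1D 1H NMR peak tables.

Workflow: integrate a compound-specific chemical-shift window against the
TSP reference peak (trapezoidal area over a local linear baseline, both
proton-normalised), convert the integral ratio to an extract concentration
through a standard calibration line, and scale by extract volume, worm
count (estimated from total protein) and a per-worm body volume (4 nL for a
day-1 adult by default) to obtain the in-worm molar concentration.
Detectability of a window against the endogenous-metabolite background is
called from a noise threshold plus a window-occupancy criterion.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, SpectrumError, ValidationError

TSP_WINDOW = (-0.05, 0.05)  # ppm; trimethylsilyl-propionate reference at 0
TSP_PROTONS = 9
WORM_VOLUME_L = 4e-9  # published day-1 adult volume, 4 nL


@dataclass(frozen=True)
class NmrSpectrum:
    """A 1D spectrum as (ppm, intensity) arrays, stored with ppm descending."""

    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        ppm = np.asarray(self.ppm, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if ppm.shape != inten.shape or ppm.ndim != 1:
            raise ValidationError("ppm and intensity must be equal-length 1-D arrays")
        diffs = np.diff(ppm)
        if np.all(diffs > 0):  # ascending input auto-normalised to descending
            ppm, inten = ppm[::-1], inten[::-1]
        elif not np.all(diffs < 0):
            raise ValidationError("ppm axis must be strictly monotone")
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "intensity", inten)

    @classmethod
    def from_csv(cls, path, **meta) -> "NmrSpectrum":
        frame = pd.read_csv(path)
        if not {"ppm", "intensity"} <= set(frame.columns):
            raise ValidationError(f"{path}: need columns ppm,intensity")
        return cls(frame.ppm.to_numpy(), frame.intensity.to_numpy(), meta=dict(meta))


@dataclass(frozen=True)
class PeakWindow:
    compound_id: str
    lo_ppm: float
    hi_ppm: float
    protons: int

    def __post_init__(self):
        if not self.lo_ppm < self.hi_ppm:
            raise ValidationError(f"{self.compound_id}: window lo_ppm must be < hi_ppm")
        if self.protons < 1:
            raise ValidationError(f"{self.compound_id}: protons must be >= 1")


@dataclass(frozen=True)
class CalibrationCurve:
    slope: float  # integral ratio per molar (extract concentration)
    intercept: float
    r2: float
    standards: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class WormSampleSize:
    n_worms: float
    method: str = "protein-based"

    def __post_init__(self):
        if self.n_worms <= 0:
            raise ValidationError("worm count must be positive")


@dataclass(frozen=True)
class InternalConcentration:
    molar: float
    below_detection: bool


def _window_area(s: NmrSpectrum, lo: float, hi: float, baseline: bool = True) -> float:
    """Trapezoidal area of [lo, hi] ppm above a linear endpoint baseline."""
    ppm_min, ppm_max = float(s.ppm.min()), float(s.ppm.max())
    if lo < ppm_min or hi > ppm_max:
        raise SpectrumError(f"window [{lo}, {hi}] outside axis [{ppm_min}, {ppm_max}]")
    mask = (s.ppm >= lo) & (s.ppm <= hi)
    if mask.sum() < 2:
        raise SpectrumError(f"window [{lo}, {hi}] covers fewer than two axis points")
    x = s.ppm[mask][::-1]  # ascending for integration
    y = s.intensity[mask][::-1]
    if baseline:
        base = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
        y = y - base
    return float(np.trapezoid(y, x))


def integrate_window(
    s: NmrSpectrum,
    w: PeakWindow,
    tsp_window: tuple[float, float] = TSP_WINDOW,
    tsp_protons: int = TSP_PROTONS,
    baseline: bool = True,
) -> float:
    """Proton-normalised integral ratio of a peak window to the TSP reference.

    ``(area_window / protons) / (area_TSP / tsp_protons)``, both areas taken
    above a per-window linear baseline through the window endpoints (pass
    ``baseline=False`` for raw trapezoidal areas).
    """
    tsp_area = _window_area(s, *tsp_window, baseline=baseline)
    if tsp_area <= 0:
        raise SpectrumError("TSP reference peak absent or non-positive")
    area = _window_area(s, w.lo_ppm, w.hi_ppm, baseline=baseline)
    return (area / w.protons) / (tsp_area / tsp_protons)


def fit_calibration(standards) -> CalibrationCurve:
    """Ordinary least-squares line through (extract concentration, integral ratio) standards."""
    pairs = [(float(c), float(r)) for c, r in standards]
    if len(pairs) < 3:
        raise FitError("calibration needs at least three standards")
    conc = np.array([p[0] for p in pairs])
    ratio = np.array([p[1] for p in pairs])
    if len(np.unique(conc)) < 2:
        raise FitError("degenerate calibration: all standards at one concentration")
    res = stats.linregress(conc, ratio)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        standards=tuple(pairs),
    )


def worm_count_from_protein(total_protein_ug: float, protein_per_worm_ug: float) -> WormSampleSize:
    """Estimate worms in a lysate from total protein and a per-worm protein yield."""
    if total_protein_ug <= 0 or protein_per_worm_ug <= 0:
        raise ValidationError("protein amounts must be positive")
    return WormSampleSize(n_worms=total_protein_ug / protein_per_worm_ug)


def internal_concentration(
    integral_ratio: float,
    cal: CalibrationCurve,
    extract_volume_l: float,
    sample: WormSampleSize,
    volume_per_worm_l: float = WORM_VOLUME_L,
    tolerance: float = 1e-12,
) -> InternalConcentration:
    """In-worm molar concentration from an integral ratio.

    extract conc = (ratio - intercept) / slope; moles = conc x extract
    volume; internal = moles / (n_worms x per-worm volume).  A computed
    concentration at or below zero is reported as 0 M below-detection rather
    than a negative number.
    """
    if cal.slope <= 0:
        raise ValidationError("calibration slope must be positive")
    if extract_volume_l <= 0 or volume_per_worm_l <= 0:
        raise ValidationError("volumes must be positive")
    conc_extract = (integral_ratio - cal.intercept) / cal.slope
    if conc_extract <= tolerance:
        return InternalConcentration(molar=0.0, below_detection=True)
    moles = conc_extract * extract_volume_l
    return InternalConcentration(
        molar=moles / (sample.n_worms * volume_per_worm_l), below_detection=False
    )


def detectability(
    s: NmrSpectrum,
    w: PeakWindow,
    background: NmrSpectrum,
    k: float = 3.0,
    occlusion_threshold: float = 0.5,
) -> tuple[bool, dict]:
    """Is a compound window distinguishable from the metabolite background?

    Detectable iff the sample's window maximum exceeds the background's
    median + k x MAD (a noise floor over the whole background spectrum) AND
    the background occupies less than ``occlusion_threshold`` of the
    sample's raw window area.  Returns (flag, diagnostics).
    """
    if s.ppm.shape != background.ppm.shape or not np.allclose(s.ppm, background.ppm):
        raise SpectrumError("sample and background ppm axes are misaligned")
    mask = (s.ppm >= w.lo_ppm) & (s.ppm <= w.hi_ppm)
    if mask.sum() < 2:
        raise SpectrumError("window covers fewer than two axis points")
    window_max = float(s.intensity[mask].max())
    med = float(np.median(background.intensity))
    mad = float(stats.median_abs_deviation(background.intensity))
    floor = med + k * mad
    sample_area = max(_window_area(s, w.lo_ppm, w.hi_ppm, baseline=False), 0.0)
    bg_area = max(_window_area(background, w.lo_ppm, w.hi_ppm, baseline=False), 0.0)
    occupancy = bg_area / sample_area if sample_area > 0 else 1.0
    diagnostics = {
        "window_max": window_max,
        "noise_floor": floor,
        "above_floor": window_max > floor,
        "occupancy": occupancy,
        "occluded": occupancy >= occlusion_threshold,
    }
    return bool(window_max > floor and occupancy < occlusion_threshold), diagnostics
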
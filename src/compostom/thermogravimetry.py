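"""TG/DTG/DTA processing and the R1/R2 thermal-stability indices.

A combustion run records sample mass (% of initial) and a DTA heat-flow
signal (positive = exothermic) on an increasing temperature grid. Organic
matter burns in two main exothermic regions: a labile one (carbohydrates,
aliphatics; by default 250–400 °C) and a recalcitrant one (complex
aromatics; by default 400–580 °C). The stability indices are

* R1 = mass loss in region 2 / mass loss in region 1 (from TG)
* R2 = peak area in region 2 / peak area in region 1 (from DTA)

Both rise as compost organic matter stabilises. The moisture step
(< 150 °C) is excluded from all index computations.

DTG is the negative temperature-derivative of the mass trace
(positive = mass-loss rate), obtained by Savitzky–Golay local-polynomial
differentiation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "Thermogram",
    "ThermalRegion",
    "ThermalIndices",
    "DEFAULT_P1",
    "DEFAULT_P2",
    "compute_dtg",
    "detect_dtg_peaks",
    "region_mass_loss",
    "dta_peak_area",
    "thermal_indices",
    "read_thermogram",
    "write_indices",
]


@dataclass
class Thermogram:
    """One TG/DTA run: temperature grid (°C), mass (% initial), heat flow."""

    temperature: np.ndarray
    mass: np.ndarray
    heat_flow: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        self.heat_flow = np.asarray(self.heat_flow, dtype=float)
        n = self.temperature.size
        if not (self.mass.size == self.heat_flow.size == n):
            raise ValueError("temperature, mass and heat_flow must have equal length")
        if n < 100:
            raise ValueError("thermogram needs at least 100 points")
        d = np.diff(self.temperature)
        if np.any(d <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if d.max() > 5.0:
            raise ValueError("temperature spacing must not exceed 5 °C")
        if self.temperature[0] > 150.0 or self.temperature[-1] < 600.0:
            raise ValueError("thermogram must span at least [150, 600] °C")
        if self.mass[0] > 100.0 + 1e-9 or np.any(self.mass <= 0) or np.any(self.mass > 100.0 + 1e-9):
            raise ValueError("mass must be % of initial sample mass, in (0, 100]")


@dataclass(frozen=True)
class ThermalRegion:
    """Labelled temperature window, e.g. P1 = (250, 400) °C."""

    label: str
    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if not (150.0 <= self.t_low < self.t_high <= 650.0):
            raise ValueError(
                f"region {self.label}: need 150 <= t_low < t_high <= 650, got "
                f"({self.t_low}, {self.t_high})"
            )


DEFAULT_P1 = ThermalRegion("P1", 250.0, 400.0)
DEFAULT_P2 = ThermalRegion("P2", 400.0, 580.0)


@dataclass
class ThermalIndices:
    p1_mass_loss: float
    p2_mass_loss: float
    r1: float
    p1_area: float
    p2_area: float
    r2: float

    def to_dict(self) -> dict:
        return {
            "p1_mass_loss": self.p1_mass_loss, "p2_mass_loss": self.p2_mass_loss,
            "r1": self.r1, "p1_area": self.p1_area, "p2_area": self.p2_area,
            "r2": self.r2,
        }


def _window_points(temperature: np.ndarray, smooth_window: float) -> int:
    dT = float(np.median(np.diff(temperature)))
    w = int(round(smooth_window / dT))
    if w < 3:
        raise ValueError(
            f"smoothing window {smooth_window} °C covers {w} grid points; need at least 3"
        )
    return w + 1 if w % 2 == 0 else w


def compute_dtg(
    gram: Thermogram,
    smooth_window: Optional[float] = None,
    smooth_order: int = 2,
) -> np.ndarray:
    """DTG trace −d(mass)/dT in %/°C on the thermogram's own grid.

    ``smooth_window`` is in °C (default: 15 grid points converted to °C);
    differentiation is Savitzky–Golay with the given polynomial order on a
    uniform grid, falling back to finite differences smoothed by the same
    filter when the grid is not uniform. Endpoints use the filter's
    polynomial extension (window truncation behaviour).
    """
    T = gram.temperature
    dT = np.diff(T)
    if smooth_window is None:
        w = 15
    else:
        w = _window_points(T, smooth_window)
    if w < 3:
        raise ValueError("smoothing window must cover at least 3 grid points")
    if w > T.size:
        raise ValueError("smoothing window larger than the thermogram")
    if smooth_order >= w:
        raise ValueError("polynomial order must be below the window length")
    uniform = np.allclose(dT, dT[0], rtol=1e-6, atol=1e-9)
    if uniform:
        return -_signal.savgol_filter(gram.mass, w, smooth_order, deriv=1, delta=float(dT[0]))
    grad = np.gradient(gram.mass, T)
    return -_signal.savgol_filter(grad, w, smooth_order)


def detect_dtg_peaks(
    temperature: np.ndarray,
    dtg: np.ndarray,
    windows: Sequence[ThermalRegion],
    min_prominence: float = 0.05,
) -> list[tuple[str, float, float]]:
    """Local DTG maxima per window as (window label, peak °C, height).

    ``min_prominence`` is a fraction of the global DTG maximum. Peaks are
    sorted by temperature; a window may contribute several peaks or, with a
    warning, none.
    """
    temperature = np.asarray(temperature, float)
    dtg = np.asarray(dtg, float)
    scale = float(np.max(dtg)) if dtg.size else 0.0
    if scale <= 0:
        return []
    idx, _ = _signal.find_peaks(dtg, prominence=min_prominence * scale)
    out: list[tuple[str, float, float]] = []
    for win in windows:
        mask = (temperature >= win.t_low) & (temperature <= win.t_high)
        if not mask.any():
            raise ValueError(f"window {win.label} [{win.t_low}, {win.t_high}] has no overlap with the grid")
        hits = [i for i in idx if win.t_low <= temperature[i] <= win.t_high]
        if not hits:
            warnings.warn(f"no DTG peak found in window {win.label} [{win.t_low}, {win.t_high}] °C",
                          stacklevel=2)
        out.extend((win.label, float(temperature[i]), float(dtg[i])) for i in hits)
    out.sort(key=lambda p: p[1])
    return out


def _check_region(gram: Thermogram, region: ThermalRegion) -> None:
    if region.t_low < gram.temperature[0] or region.t_high > gram.temperature[-1]:
        raise ValueError(
            f"region {region.label} [{region.t_low}, {region.t_high}] outside the "
            f"thermogram span [{gram.temperature[0]}, {gram.temperature[-1]}]"
        )


def region_mass_loss(gram: Thermogram, region: ThermalRegion) -> float:
    """Mass loss (%) across a region: mass(t_low) − mass(t_high).

    Boundary masses are linearly interpolated on the temperature grid, so
    the loss is exactly additive over adjacent regions. A (noise-induced)
    negative loss is clamped at 0 with a warning.
    """
    _check_region(gram, region)
    m_lo, m_hi = np.interp([region.t_low, region.t_high], gram.temperature, gram.mass)
    loss = float(m_lo - m_hi)
    if loss < 0:
        warnings.warn(
            f"negative mass loss ({loss:.3g} %) in region {region.label}; clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return loss


def dta_peak_area(
    gram: Thermogram,
    region: ThermalRegion,
    baseline: str = "linear_endpoints",
) -> float:
    """Baseline-corrected DTA peak area (signal·°C) over a region.

    The integral is trapezoidal over [t_low, t_high] with interpolated
    endpoints. Baselines: ``linear_endpoints`` (straight line joining the
    signal at the region edges — invariant to a constant signal offset) or
    ``horizontal_min`` (flat line at the in-region minimum).
    """
    _check_region(gram, region)
    T, H = gram.temperature, gram.heat_flow
    inner = (T > region.t_low) & (T < region.t_high)
    x = np.concatenate(([region.t_low], T[inner], [region.t_high]))
    y = np.concatenate((
        np.interp([region.t_low], T, H), H[inner], np.interp([region.t_high], T, H)
    ))
    if baseline == "linear_endpoints":
        base = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    elif baseline == "horizontal_min":
        base = np.full_like(y, y.min())
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    return float(np.trapezoid(y - base, x))


def thermal_indices(
    gram: Thermogram,
    p1: ThermalRegion = DEFAULT_P1,
    p2: ThermalRegion = DEFAULT_P2,
    baseline: str = "linear_endpoints",
) -> ThermalIndices:
    """Assemble the R1/R2 index pair for one thermogram.

    R1 = P2/P1 mass losses (TG); R2 = P2/P1 peak areas (DTA). P1 must
    precede P2 on the temperature axis.
    """
    if p1.t_low >= p2.t_low:
        raise ValueError("P1 must precede P2 on the temperature axis")
    m1 = region_mass_loss(gram, p1)
    m2 = region_mass_loss(gram, p2)
    a1 = dta_peak_area(gram, p1, baseline)
    a2 = dta_peak_area(gram, p2, baseline)
    if m1 <= 0:
        raise ZeroDivisionError("P1 mass loss is zero: R1 undefined (check region windows)")
    if a1 <= 0:
        raise ZeroDivisionError("P1 DTA area is non-positive: R2 undefined (check baseline/windows)")
    return ThermalIndices(m1, m2, m2 / m1, a1, a2, a2 / a1)


def read_thermogram(path) -> Thermogram:
    """Read a 3-column delimited text thermogram.

    Columns: temperature_c, mass_pct (% of initial) or mass_mg (absolute,
    normalised to % of the first value), heat_flow. A mass_pct trace not
    starting near 100 % is re-normalised with a warning.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    try:
        T = df[cols["temperature_c"]].to_numpy(float)
        h = df[cols["heat_flow"]].to_numpy(float)
    except KeyError as exc:
        raise ValueError(f"missing thermogram column: {exc}") from exc
    if "mass_pct" in cols:
        m = df[cols["mass_pct"]].to_numpy(float)
        if not (90.0 <= m[0] <= 100.0):
            warnings.warn(
                f"mass_pct trace starts at {m[0]:.3g}, not ~100 %; renormalising",
                stacklevel=2,
            )
            m = 100.0 * m / m[0]
    elif "mass_mg" in cols:
        m = df[cols["mass_mg"]].to_numpy(float)
        m = 100.0 * m / m[0]
    else:
        raise ValueError("missing thermogram column: 'mass_pct' or 'mass_mg'")
    return Thermogram(T, m, h)


def write_indices(indices: ThermalIndices, path, label: str = "") -> None:
    payload = {"sample": label, **indices.to_dict()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
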
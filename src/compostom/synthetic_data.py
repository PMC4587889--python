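"""Synthetic compost-trial data with known ground truth.

Every input kind the analysis pipeline consumes can be generated here with
the statistical shape the analysis assumes and an exact truth record, so
each stage is testable without instrument data:

* daily pile/ambient temperature series (double-exponential heating with
  turning-triggered re-heating spikes and a slow sinusoidal ambient),
* first-order OM-loss series,
* TG/DTA thermograms built from Gaussian mass-loss events and exotherms,
* FT-IR spectra as Gaussian bands on an optional linear baseline,
* ¹³C NMR spectra as one Gaussian per chemical-shift region.

Gaussian components are used throughout because their integrals have
closed forms, which makes every generator an exact oracle for the module
that analyses its output. Noise is additive Gaussian on the ordinate only
and every generator is deterministic under a fixed seed.

Three stock scenarios mimic the example piles: the grape-marc pile (B)
carries the largest labile-carbon fraction and therefore heats fastest and
highest; the exhausted-grape-marc piles (A, C) are similar to each other
and cooler, with C slowest to start (polyphenol inhibition).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import datasets
from .ftir import DEFAULT_BANDS, relative_absorbance
from .kinetics import OMLossSeries, predict_om_loss
from .nmr import DEFAULT_REGIONS, RegionScheme
from .spectra import Spectrum, WAVENUMBER, CHEMICAL_SHIFT, write_jcamp
from .temperature import TemperatureSeries
from .thermogravimetry import Thermogram

__all__ = [
    "PileScenario",
    "SCENARIOS",
    "make_temperature_series",
    "make_om_loss_series",
    "make_thermogram",
    "make_maturation_thermogram",
    "make_ftir_spectrum",
    "make_nmr_spectrum",
    "gaussian_loss_in_region",
    "gaussian_area_in_region",
    "write_fixture_set",
]


@dataclass(frozen=True)
class PileScenario:
    """Generating parameters for one simulated composting pile."""

    pile_id: str
    labile_fraction: float
    recalcitrant_fraction: float
    a_max_true: float          # % asymptotic OM degradation
    k_true: float              # d^-1
    heating_amplitude: float   # °C scale of pile-minus-ambient offset
    turning_days: tuple[int, ...] = (7, 21, 35, 49, 63, 77)

    def __post_init__(self) -> None:
        if not (0.0 <= self.labile_fraction <= 1.0 and 0.0 <= self.recalcitrant_fraction <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.labile_fraction + self.recalcitrant_fraction > 1.0:
            raise ValueError("labile + recalcitrant fractions must not exceed 1")
        if not (0.0 < self.a_max_true < 100.0):
            raise ValueError("a_max_true must lie in (0, 100)")
        if self.k_true <= 0:
            raise ValueError("k_true must be positive")


# Kinetic parameters are each pile's reported first-order fit; labile
# fractions and heating amplitudes encode the B > A ≈ C heating contrast.
SCENARIOS: dict[str, PileScenario] = {
    "A": PileScenario("A", labile_fraction=0.35, recalcitrant_fraction=0.40,
                      a_max_true=49.6, k_true=0.0131, heating_amplitude=24.0),
    "B": PileScenario("B", labile_fraction=0.60, recalcitrant_fraction=0.30,
                      a_max_true=44.2, k_true=0.0215, heating_amplitude=30.0),
    "C": PileScenario("C", labile_fraction=0.30, recalcitrant_fraction=0.42,
                      a_max_true=50.4, k_true=0.0091, heating_amplitude=23.0),
}


def _heating_offsets(scenario: PileScenario, days: int) -> np.ndarray:
    """Deterministic daily pile-minus-ambient offsets (°C)."""
    d = np.arange(days, dtype=float)
    tau_rise = 6.0 - 4.0 * scenario.labile_fraction   # labile C ignites faster
    tau_decay = 35.0
    amp = scenario.heating_amplitude * (0.5 + scenario.labile_fraction)
    offs = amp * (1.0 - np.exp(-d / tau_rise)) * np.exp(-d / tau_decay)
    for t_j in scenario.turning_days:
        mask = d >= t_j
        # turning re-heats in proportion to the substrate left to degrade
        offs[mask] += 0.35 * amp * np.exp(-t_j / tau_decay) * np.exp(-(d[mask] - t_j) / 4.0)
    return offs


def make_temperature_series(
    scenario: PileScenario,
    days: int = 120,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[TemperatureSeries, dict]:
    """Daily pile/ambient series plus exact truth.

    Truth holds the noiseless per-day offsets, so the EXothermic Index for
    any end day has the closed-form value ``offsets[:end].sum()``.
    """
    if days < 30:
        raise ValueError("need at least 30 days of composting")
    rng = np.random.default_rng(seed)
    d = np.arange(days, dtype=float)
    ambient = 16.0 + 4.0 * np.sin(2.0 * np.pi * d / 120.0)
    offsets = _heating_offsets(scenario, days)
    pile = ambient + offsets
    if noise_sd > 0:
        pile = pile + rng.normal(0.0, noise_sd, size=days)
    series = TemperatureSeries(d, pile, ambient, list(scenario.turning_days))
    truth = {
        "daily_offsets": offsets,
        "exi_full": float(offsets.sum()),
        "noise_sd": noise_sd,
    }
    return series, truth


def make_om_loss_series(
    scenario: PileScenario,
    sample_days: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[OMLossSeries, dict]:
    """OM-loss observations from the first-order model plus Gaussian noise."""
    t = np.asarray(sample_days, dtype=float)
    rng = np.random.default_rng(seed)
    clean = predict_om_loss(scenario.a_max_true, scenario.k_true, t)
    noisy = np.clip(clean + rng.normal(0.0, noise_sd, size=t.size), 0.0, 100.0)
    series = OMLossSeries(t, noisy)
    truth = {"a_max": scenario.a_max_true, "k": scenario.k_true, "clean": clean}
    return series, truth


def gaussian_loss_in_region(
    components: Sequence[tuple[float, float, float]],
    t_low: float,
    t_high: float,
) -> float:
    """Exact mass loss (%) of Gaussian-CDF components inside [t_low, t_high]."""
    return float(sum(
        loss * (norm.cdf(t_high, c, s) - norm.cdf(t_low, c, s))
        for c, s, loss in components
    ))


def gaussian_area_in_region(
    dta_components: Sequence[tuple[float, float, float]],
    t_low: float,
    t_high: float,
) -> float:
    """Exact integrated exotherm area inside [t_low, t_high]."""
    return float(sum(
        area * (norm.cdf(t_high, c, s) - norm.cdf(t_low, c, s))
        for c, s, area in dta_components
    ))


def make_thermogram(
    components: Sequence[tuple[float, float, float]],
    dta_components: Sequence[tuple[float, float, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    temp_range: tuple[float, float] = (25.0, 650.0),
    step: float = 0.5,
    drift: float = 0.0,
) -> tuple[Thermogram, dict]:
    """TG/DTA run from Gaussian events.

    ``components``: (center °C, sigma °C, mass-loss %) — each contributes a
    cumulative-Gaussian mass drop. ``dta_components``: (center, sigma,
    area) Gaussian exotherms; ``drift`` adds a linear heat-flow baseline.
    Truth holds the component lists for closed-form region integrals.
    """
    total = sum(c[2] for c in components)
    if total >= 100.0:
        raise ValueError(f"total mass loss {total} % must stay below 100 %")
    rng = np.random.default_rng(seed)
    T = np.arange(temp_range[0], temp_range[1] + step / 2, step)
    mass = np.full_like(T, 100.0)
    for c, s, loss in components:
        mass -= loss * norm.cdf(T, c, s)
    heat = np.zeros_like(T)
    for c, s, area in dta_components:
        heat += area * norm.pdf(T, c, s)
    heat += drift * (T - T[0])
    if noise_sd > 0:
        mass = np.clip(mass + rng.normal(0.0, noise_sd, T.size), 1e-6, 100.0)
        heat = heat + rng.normal(0.0, noise_sd, T.size)
    gram = Thermogram(T, mass, heat)
    truth = {"components": list(components), "dta_components": list(dta_components),
             "drift": drift, "noise_sd": noise_sd}
    return gram, truth


def make_maturation_thermogram(
    stage: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Thermogram, dict]:
    """Thermogram along a simulated maturation axis, stage ∈ [0, 1].

    The labile mass-loss events (carbohydrates, 250–400 °C) shrink and the
    recalcitrant event (complex aromatics, ~475 °C) grows with stage, so
    both the TG-based R1 and the DTA-based R2 stability indices increase
    strictly with stage.
    """
    if not (0.0 <= stage <= 1.0):
        raise ValueError("stage must lie in [0, 1]")
    p1_loss = 50.0 - 16.0 * stage    # 50 -> 34 %
    p2_loss = 17.0 + 6.0 * stage     # 17 -> 23 %
    p1_area = 750.0 - 100.0 * stage  # exotherm areas, arbitrary units·°C
    p2_area = 110.0 + 700.0 * stage
    components = [
        (300.0, 20.0, 0.55 * p1_loss),
        (350.0, 18.0, 0.45 * p1_loss),
        (475.0, 16.0, p2_loss),
    ]
    dta_components = [(330.0, 28.0, p1_area), (478.0, 22.0, p2_area)]
    gram, truth = make_thermogram(components, dta_components, noise_sd=noise_sd, seed=seed)
    truth["stage"] = stage
    return gram, truth


def make_ftir_spectrum(
    band_heights: Mapping[float, float],
    baseline_slope: float = 0.0,
    baseline_offset: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    band_sigma: float = 6.0,
) -> tuple[Spectrum, dict]:
    """FT-IR spectrum on a 4000–400 cm⁻¹ grid (2 cm⁻¹ spacing).

    Each band is a Gaussian of the given height at its nominal position;
    ``baseline_slope`` (per cm⁻¹) and ``baseline_offset`` add a linear
    background. Truth is the exact rA profile of the generating heights.
    """
    if any(h < 0 for h in band_heights.values()):
        raise ValueError("band heights must be non-negative")
    rng = np.random.default_rng(seed)
    x = np.arange(400.0, 4000.0 + 1.0, 2.0)
    y = baseline_offset + baseline_slope * (x - x[0])
    for pos, h in band_heights.items():
        y = y + h * np.exp(-0.5 * ((x - pos) / band_sigma) ** 2)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, x.size)
    spec = Spectrum(x, y, WAVENUMBER, metadata={"synthetic": True})
    truth = {"heights": dict(band_heights), "ra": None, "ratio_1037_1384": None}
    if len(band_heights) >= 2 and sum(band_heights.values()) > 0:
        profile = relative_absorbance(dict(band_heights))
        truth["ra"] = profile.ra
        truth["ratio_1037_1384"] = profile.ratio_1037_1384
    return spec, truth


def make_nmr_spectrum(
    region_targets: Mapping[str, float],
    linewidths: Optional[Mapping[str, float]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    scheme: RegionScheme = DEFAULT_REGIONS,
    total_intensity: float = 100.0,
) -> tuple[Spectrum, dict]:
    """¹³C spectrum on a [−20, 220] ppm grid (0.2 ppm spacing).

    One Gaussian per region, centered mid-region with sigma = width/12
    (overridable per region via ``linewidths``), scaled so the region
    integrals hit ``region_targets`` (%, must sum to 100).
    """
    targets = dict(region_targets)
    ssum = sum(targets.values())
    if abs(ssum - 100.0) > 1e-6:
        raise ValueError(f"region targets must sum to 100, got {ssum}")
    labels = set(scheme.labels())
    unknown = set(targets) - labels
    if unknown:
        raise ValueError(f"unknown region labels: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    x = np.arange(-20.0, 220.0 + 0.1, 0.2)
    y = np.zeros_like(x)
    for label, high, low in scheme.regions:
        pct = targets.get(label, 0.0)
        if pct == 0.0:
            continue
        width = high - low
        sigma = (linewidths or {}).get(label, width / 12.0)
        center = (high + low) / 2.0
        area = total_intensity * pct / 100.0
        y += area * norm.pdf(x, center, sigma)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, x.size)
    spec = Spectrum(x, y, CHEMICAL_SHIFT, metadata={"synthetic": True})
    truth = {"targets": targets, "noise_sd": noise_sd}
    return spec, truth


def _chemical_fixture() -> pd.DataFrame:
    """Per-sample chemical input table for the stock scenarios.

    TN is reconstructed from the example WSC and WSC/TN columns and TOC
    from TOC/TN, giving raw-measurement records consistent with the
    example index table.
    """
    chem = datasets.load_chemical()
    gi = datasets.germination_index()
    rows = []
    for _, r in chem.iterrows():
        tn = r["wsc"] / r["wsc_tn"]
        rows.append({
            "pile_id": r["pile_id"], "phase": r["phase"], "day": r["day"],
            "toc": round(r["toc_tn"] * tn, 2), "tn": round(tn, 3),
            "wsc": r["wsc"], "cfa": r["cfa"], "cha": r["cha"],
            "gi": gi[r["pile_id"]] if r["phase"] == "maturity" else "",
        })
    return pd.DataFrame(rows)


def write_fixture_set(outdir, seed: int = 0) -> dict:
    """Write the canonical synthetic fixture set used by the test suite.

    Emits, per stock scenario: a chemical sample table, OM-loss series,
    daily temperature series, initial/mature thermograms, and
    example-shaped FT-IR (JCAMP-DX) and NMR (two-column text) spectra.
    Ground truth for every file goes to ``truth.json``. Returns the truth
    mapping. Deterministic under a fixed seed.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth: dict = {"seed": seed}
    rng = np.random.default_rng(seed)

    _chemical_fixture().to_csv(out / "chemical.csv", index=False)

    ftir_df, band_pos = datasets.load_ftir(bands=True)
    nmr_df = datasets.load_nmr()
    region_order = ["alkyl", "n_alkyl_methoxy", "o_alkyl", "o2_alkyl",
                    "aromatic", "o_aromatic", "carbonyl"]
    scheme_labels = ["alkyl", "N-alkyl/methoxy", "O-alkyl", "O2-alkyl",
                     "aromatic", "O-aromatic", "carbonyl"]

    for pid, scenario in SCENARIOS.items():
        days = sorted({0.0, 7.0, 14.0, 21.0, 28.0, 35.0, 42.0, 49.0, 56.0,
                       63.0, 70.0, 77.0, 84.0, 91.0, 98.0, 105.0})
        om, om_truth = make_om_loss_series(scenario, days, noise_sd=1.0,
                                           seed=int(rng.integers(2**31)))
        pd.DataFrame({"day": om.times, "om_loss_pct": om.losses}).to_csv(
            out / f"omloss_{pid}.csv", index=False)
        truth[f"omloss_{pid}"] = {"a_max": om_truth["a_max"], "k": om_truth["k"]}

        temp, t_truth = make_temperature_series(scenario, days=120,
                                                seed=int(rng.integers(2**31)),
                                                noise_sd=0.3)
        pd.DataFrame({"day": temp.times, "pile_temp_c": temp.pile_temp,
                      "ambient_temp_c": temp.ambient_temp}).to_csv(
            out / f"temperature_{pid}.csv", index=False)
        truth[f"temperature_{pid}"] = {
            "exi_full": t_truth["exi_full"],
            "daily_offsets": t_truth["daily_offsets"].tolist(),
        }

        for phase, stage in (("initial", 0.0), ("maturity", 1.0)):
            gram, g_truth = make_maturation_thermogram(
                stage, noise_sd=0.02, seed=int(rng.integers(2**31)))
            pd.DataFrame({"temperature_c": gram.temperature, "mass_pct": gram.mass,
                          "heat_flow": gram.heat_flow}).to_csv(
                out / f"tg_{pid}_{phase}.csv", index=False)
            truth[f"tg_{pid}_{phase}"] = {
                "components": g_truth["components"],
                "dta_components": g_truth["dta_components"],
                "stage": stage,
            }

    for _, row in ftir_df.iterrows():
        name = f"ftir_{row['pile_id']}_{row['phase']}"
        heights = {b: 0.01 * row[f"ra_{int(b)}"] for b in band_pos}
        spec, f_truth = make_ftir_spectrum(heights, baseline_slope=2e-6,
                                           baseline_offset=0.01,
                                           noise_sd=1e-4,
                                           seed=int(rng.integers(2**31)))
        write_jcamp(spec, out / f"{name}.jdx", title=name)
        truth[name] = {"ra": f_truth["ra"], "ratio_1037_1384": f_truth["ratio_1037_1384"]}

    for _, row in nmr_df.iterrows():
        name = f"nmr_{row['pile_id']}_{row['phase']}"
        raw = {lab: float(row[col]) for col, lab in zip(region_order, scheme_labels)}
        total = sum(raw.values())
        targets = {k: 100.0 * v / total for k, v in raw.items()}  # renormalise rounding
        spec, n_truth = make_nmr_spectrum(targets, noise_sd=0.002,
                                          seed=int(rng.integers(2**31)))
        xs, ys = spec.ascending()
        pd.DataFrame({"ppm": xs, "intensity": ys}).to_csv(
            out / f"{name}.tsv", sep="\t", index=False)
        truth[name] = {"targets": n_truth["targets"]}

    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return truth
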
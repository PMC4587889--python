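"""Bundled example dataset: a 168-day co-composting trial of
winery–distillery wastes with animal manures.

Three piles composted by the turning system in 350 L thermo-composters:

* pile A — 76 % exhausted grape marc + 24 % cattle manure
* pile B — 72 % grape marc + 28 % cattle manure
* pile C — 67 % exhausted grape marc + 33 % poultry manure

Each pile was sampled at four phases: initial (day 0), thermophilic
(day 28), end of the bio-oxidative phase (day 105) and maturity
(day 168). The tables below hold the reported chemical indices, TG/DTA
mass losses and peak areas, FT-IR relative absorbances, ¹³C NMR region
intensities, fitted first-order kinetic parameters and final-compost
germination indices. They are the package's worked example and the input
to the acceptance checks.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "load_chemical",
    "load_thermal",
    "load_ftir",
    "load_nmr",
    "kinetic_parameters",
    "germination_index",
    "PHASE_DAYS",
]

PHASE_DAYS = {"initial": 0, "thermophilic": 28, "end_bio_oxidative": 105, "maturity": 168}

_CHEM_COLUMNS = ["pile_id", "phase", "day", "toc_tn", "wsc", "wsc_tn",
                 "cfa", "cha", "hr", "hi", "pha", "cha_cfa"]
_CHEM_ROWS = [
    ("A", "initial", 0, 21.9, 3.14, 1.42, 3.54, 2.98, 12.99, 5.94, 45.72, 0.84),
    ("A", "thermophilic", 28, 18.4, 2.80, 1.10, 3.14, 3.02, 12.89, 6.32, 49.01, 0.96),
    ("A", "end_bio_oxidative", 105, 17.9, 2.70, 1.05, 2.77, 1.60, 9.33, 3.41, 36.58, 0.58),
    ("A", "maturity", 168, 17.4, 1.10, 0.42, 1.24, 1.16, 5.23, 2.52, 48.15, 0.93),
    ("B", "initial", 0, 21.1, 4.27, 1.82, 3.86, 4.59, 17.24, 9.20, 54.46, 1.20),
    ("B", "thermophilic", 28, 19.2, 3.72, 1.54, 4.08, 4.61, 18.04, 9.57, 53.06, 1.13),
    ("B", "end_bio_oxidative", 105, 17.6, 3.51, 1.35, 3.13, 4.00, 15.43, 8.65, 56.06, 1.28),
    ("B", "maturity", 168, 17.1, 1.86, 0.69, 2.91, 1.43, 9.44, 3.11, 32.97, 0.49),
    ("C", "initial", 0, 14.8, 3.29, 1.15, 3.53, 2.69, 17.24, 5.96, 54.46, 1.20),
    ("C", "thermophilic", 28, 12.7, 2.84, 1.05, 2.95, 3.35, 13.87, 7.37, 53.14, 1.13),
    ("C", "end_bio_oxidative", 105, 13.9, 2.68, 0.85, 3.05, 1.84, 11.09, 4.18, 37.66, 0.60),
    ("C", "maturity", 168, 13.5, 0.98, 0.31, 1.43, 0.81, 5.34, 1.93, 36.20, 0.57),
]


def load_chemical() -> pd.DataFrame:
    """Chemical organic-matter parameters per pile and phase (% dry matter).

    Columns: TOC/TN, WSC, WSC/TN, Cfa, Cha and the reported derived
    indices HR, HI, Pha, Cha/Cfa. Note: the reported derived columns for
    pile C at the initial phase (HR, Pha, Cha/Cfa) are internally
    inconsistent with that row's own Cfa/Cha inputs (they duplicate pile
    B's initial row) — treat that row's derived values with caution.
    """
    return pd.DataFrame(_CHEM_ROWS, columns=_CHEM_COLUMNS)


_THERMAL_COLUMNS = ["pile_id", "phase", "p1_mass_loss", "p2_mass_loss", "r1",
                    "p1_area", "p2_area", "r2"]
_THERMAL_ROWS = [
    ("A", "initial", 51.9, 19.8, 0.38, 572.0, 76.0, 0.13),
    ("A", "maturity", 42.2, 26.7, 0.63, 576.0, 902.0, 1.57),
    ("B", "initial", 57.6, 22.3, 0.39, 752.0, 137.0, 0.18),
    ("B", "maturity", 39.9, 27.8, 0.70, 891.0, 1425.0, 1.60),
    ("C", "initial", 49.6, 18.0, 0.36, 804.0, 114.0, 0.14),
    ("C", "maturity", 36.0, 22.5, 0.62, 699.0, 696.0, 1.00),
]


def load_thermal() -> pd.DataFrame:
    """TG mass losses (%) and DTA peak areas for the two main exothermic
    regions (P1 ≈ 250–400 °C, P2 ≈ 400–580 °C) with the reported R1 = P2/P1
    mass-loss and R2 = P2/P1 area ratios, at the initial and maturity phases.
    """
    return pd.DataFrame(_THERMAL_ROWS, columns=_THERMAL_COLUMNS)


_FTIR_BANDS = [2927.0, 2854.0, 1640.0, 1548.0, 1420.0, 1384.0, 1037.0, 875.0]
_FTIR_COLUMNS = ["pile_id", "phase", "day"] + [f"ra_{int(b)}" for b in _FTIR_BANDS] + ["ratio_1037_1384"]
_FTIR_ROWS = [
    ("A", "initial", 0, 10.4, 12.9, 9.9, 12.6, 10.7, 12.5, 11.4, 19.6, 0.91),
    ("A", "thermophilic", 28, 12.7, 15.5, 8.8, 11.3, 11.5, 12.0, 9.8, 18.5, 0.81),
    ("A", "end_bio_oxidative", 105, 13.2, 16.3, 8.5, 10.5, 11.0, 11.4, 10.2, 19.0, 0.89),
    ("A", "maturity", 168, 13.8, 16.3, 8.9, 10.2, 10.8, 11.3, 10.4, 18.2, 0.92),
    ("B", "initial", 0, 11.8, 14.7, 9.3, 12.0, 11.9, 12.2, 10.0, 18.2, 0.82),
    ("B", "thermophilic", 28, 12.4, 15.2, 9.2, 11.5, 11.6, 12.0, 10.3, 17.9, 0.86),
    ("B", "end_bio_oxidative", 105, 12.4, 14.7, 10.1, 11.5, 11.8, 11.9, 10.7, 17.1, 0.89),
    ("B", "maturity", 168, 11.9, 15.2, 9.5, 10.2, 10.7, 11.8, 11.3, 19.3, 0.96),
    ("C", "initial", 0, 13.6, 16.7, 9.2, 12.3, 9.1, 10.9, 10.8, 17.5, 0.99),
    ("C", "thermophilic", 28, 13.4, 15.7, 10.1, 12.3, 9.9, 11.1, 11.3, 16.2, 1.02),
    ("C", "end_bio_oxidative", 105, 13.6, 15.9, 10.5, 12.1, 9.5, 10.6, 11.2, 16.6, 1.06),
    ("C", "maturity", 168, 14.9, 17.6, 10.0, 10.6, 8.5, 10.0, 10.8, 17.5, 1.08),
]


def load_ftir(bands: bool = False):
    """FT-IR relative absorbances (% of the summed band heights) over the
    eight-band panel, plus the reported 1037/1384 ratio.

    With ``bands=True`` also returns the band positions (cm⁻¹).
    """
    df = pd.DataFrame(_FTIR_ROWS, columns=_FTIR_COLUMNS)
    return (df, list(_FTIR_BANDS)) if bands else df


_NMR_COLUMNS = ["pile_id", "phase", "day", "alkyl", "n_alkyl_methoxy", "o_alkyl",
                "o2_alkyl", "aromatic", "o_aromatic", "carbonyl", "alkyl_oalkyl"]
_NMR_ROWS = [
    ("A", "initial", 0, 30.7, 17.0, 31.7, 7.8, 3.3, 3.5, 6.1, 0.97),
    ("A", "thermophilic", 28, 36.4, 15.9, 23.2, 8.0, 5.7, 3.7, 7.3, 1.60),
    ("A", "end_bio_oxidative", 105, 37.9, 16.1, 21.2, 7.7, 6.3, 3.9, 6.9, 1.79),
    ("A", "maturity", 168, 37.3, 14.3, 15.5, 6.9, 7.1, 4.8, 14.2, 2.40),
    ("B", "initial", 0, 33.6, 15.3, 28.6, 8.5, 2.9, 3.7, 7.4, 1.18),
    ("B", "thermophilic", 28, 34.3, 13.7, 28.1, 9.2, 3.6, 3.6, 7.5, 1.22),
    ("B", "end_bio_oxidative", 105, 33.3, 14.8, 29.1, 9.5, 3.8, 3.0, 6.6, 1.14),
    ("B", "maturity", 168, 34.9, 15.2, 25.9, 8.5, 3.3, 4.0, 8.2, 1.35),
    ("C", "initial", 0, 30.8, 14.2, 30.5, 10.5, 3.5, 3.5, 7.0, 1.01),
    ("C", "thermophilic", 28, 34.4, 14.6, 26.9, 8.5, 3.2, 4.0, 8.5, 1.28),
    ("C", "end_bio_oxidative", 105, 33.9, 15.5, 26.8, 8.9, 3.7, 3.9, 7.5, 1.27),
    ("C", "maturity", 168, 34.3, 15.5, 23.6, 7.9, 3.4, 5.0, 10.2, 1.45),
]


def load_nmr() -> pd.DataFrame:
    """¹³C NMR relative intensity (%) of each chemical-shift region plus
    the reported Alkyl/O-Alkyl ratio, per pile and phase.
    """
    return pd.DataFrame(_NMR_ROWS, columns=_NMR_COLUMNS)


def kinetic_parameters() -> dict:
    """Fitted first-order OM-degradation parameters per pile.

    A (% max OM degradation, with standard deviation), k (d⁻¹, with sd),
    and the reported fit statistics (the "rms" column is a normalised
    residual statistic whose exact definition was not reported; it is not
    SS_res/(n−2), which would equal see²).
    """
    return {
        "A": {"a_max": 49.6, "a_sd": 8.1, "k": 0.0131, "k_sd": 0.0040,
              "rms": 0.878, "f": 65.8, "see": 4.89},
        "B": {"a_max": 44.2, "a_sd": 6.7, "k": 0.0215, "k_sd": 0.0072,
              "rms": 0.769, "f": 31.0, "see": 6.45},
        "C": {"a_max": 50.4, "a_sd": 9.1, "k": 0.0091, "k_sd": 0.0030,
              "rms": 0.880, "f": 95.8, "see": 5.99},
    }


def germination_index() -> dict:
    """Final-compost germination index (%) per pile (cress-seed bioassay)."""
    return {"A": 78.2, "B": 68.4, "C": 61.8}
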
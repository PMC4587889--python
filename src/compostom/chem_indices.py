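"""Classical chemical maturity and humification indices for compost samples.

Implements the index set routinely reported in composting studies:
humification ratio (HR), humification index (HI), percentage of humic
acids (Pha), the Cha/Cfa polymerisation rate, organic-matter loss from the
ash mass balance, elemental ratios (TOC/TN, WSC/TN) and threshold-based
maturity flags (TOC/TN < 20, WSC ≤ 1.7 %, germination index > 50 %).

All inputs are percentages on a dry-matter basis. Functions validate their
domain and raise :class:`ValueError` on non-physical input; anomalies that
can occur in real (noisy) data — a negative OM loss from an ash balance,
for instance — produce a :class:`warnings.warn` instead of an error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "CompostSampleRecord",
    "HumicFractionSet",
    "AshPair",
    "MaturityThresholds",
    "humification_ratio",
    "humification_index",
    "percentage_humic_acids",
    "polymerisation_rate",
    "om_loss",
    "elemental_ratio",
    "percent_decrease",
    "maturity_flags",
    "index_table",
    "read_samples",
    "write_report",
]

PHASES = ("initial", "thermophilic", "end_bio_oxidative", "maturity")


@dataclass
class CompostSampleRecord:
    """One compost sample's chemical measurements (% dry matter).

    ``toc`` may be absent when only the TOC/TN ratio was measured; indices
    that need total carbon then require an explicit ``ct`` argument.
    """

    pile_id: str
    phase: str
    day: int
    toc: Optional[float] = None
    tn: Optional[float] = None
    wsc: Optional[float] = None
    cfa: Optional[float] = None
    cha: Optional[float] = None
    ash: Optional[float] = None
    gi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown composting phase {self.phase!r}; expected one of {PHASES}")
        if self.day < 0:
            raise ValueError("day must be non-negative")
        for name in ("toc", "tn", "wsc", "cfa", "cha", "ash", "gi"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100] %")


@dataclass
class HumicFractionSet:
    """Alkali-extractable C fractions: total extractable (Cext), fulvic-like
    (Cfa) and humic-like (Cha), all % dry matter.

    When ``cext`` is not supplied it is defined as Cfa + Cha. When it is,
    it must be consistent with the parts to within ``tolerance`` (absolute).
    """

    cfa: float
    cha: float
    cext: Optional[float] = None
    tolerance: float = field(default=0.05, repr=False)

    def __post_init__(self) -> None:
        if self.cfa < 0 or self.cha < 0:
            raise ValueError("Cfa and Cha must be non-negative")
        if self.cext is None:
            self.cext = self.cfa + self.cha
        else:
            if self.cext < self.cha or self.cext < self.cfa:
                raise ValueError("Cext must be at least as large as each fraction")
            if abs(self.cext - (self.cfa + self.cha)) > self.tolerance:
                raise ValueError(
                    f"Cext={self.cext} inconsistent with Cfa+Cha={self.cfa + self.cha}"
                    f" beyond tolerance {self.tolerance}"
                )


@dataclass(frozen=True)
class AshPair:
    """Initial (x1) and final (x2) ash contents, % dry matter, both in (0, 100)."""

    x1: float
    x2: float

    def __post_init__(self) -> None:
        for name, v in (("x1", self.x1), ("x2", self.x2)):
            if not (0.0 < v < 100.0):
                raise ValueError(f"{name}={v} must lie strictly inside (0, 100) %")


def humification_ratio(cext: float, ct: float) -> float:
    """Humification ratio HR = 100 * Cext / CT (%)."""
    if ct <= 0:
        raise ValueError("total carbon CT must be positive")
    if not (0.0 <= cext <= ct):
        raise ValueError("Cext must lie in [0, CT]")
    return 100.0 * cext / ct


def humification_index(cha: float, ct: float) -> float:
    """Humification index HI = 100 * Cha / CT (%)."""
    if ct <= 0:
        raise ValueError("total carbon CT must be positive")
    if not (0.0 <= cha <= ct):
        raise ValueError("Cha must lie in [0, CT]")
    return 100.0 * cha / ct


def percentage_humic_acids(cha: float, cext: float) -> float:
    """Percentage of humic acids Pha = 100 * Cha / Cext (%)."""
    if cext <= 0:
        raise ValueError("Cext must be positive")
    if not (0.0 <= cha <= cext):
        raise ValueError("Cha must lie in [0, Cext]")
    return 100.0 * cha / cext


def polymerisation_rate(cha: float, cfa: float) -> float:
    """Polymerisation rate Cha/Cfa (dimensionless)."""
    if cfa <= 0:
        raise ValueError("Cfa must be positive")
    if cha < 0:
        raise ValueError("Cha must be non-negative")
    return cha / cfa


def om_loss(ash: AshPair) -> float:
    """Organic-matter loss (%) from the ash mass balance.

    OM loss = 100 - 100 * [x1 * (100 - x2)] / [x2 * (100 - x1)].

    Zero when the ash content did not change; positive when ash was
    enriched (x2 > x1). A negative value signals a mass-balance anomaly
    and is returned with a warning rather than raised, since early
    composting data can be noisy.
    """
    x1, x2 = ash.x1, ash.x2
    loss = 100.0 - 100.0 * (x1 * (100.0 - x2)) / (x2 * (100.0 - x1))
    if loss < -1e-9:
        warnings.warn(
            f"negative OM loss ({loss:.2f} %): final ash {x2} < initial ash {x1}, "
            "mass-balance anomaly",
            stacklevel=2,
        )
    return loss


def elemental_ratio(numerator: float, denominator: float) -> float:
    """Simple elemental ratio, used for TOC/TN and WSC/TN."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return numerator / denominator


def percent_decrease(initial: float, final: float) -> float:
    """Relative decrease 100 * (initial - final) / initial (%)."""
    if initial <= 0:
        raise ValueError("initial value must be positive")
    return 100.0 * (initial - final) / initial


@dataclass(frozen=True)
class MaturityThresholds:
    """Decision thresholds for the maturity flags.

    TOC/TN strictly below ``tocn_max``; WSC at or below ``wsc_max``
    (inclusive, matching the 'lower or close to 1.7 %' guideline);
    germination index strictly above ``gi_min``.
    """

    tocn_max: float = 20.0
    wsc_max: float = 1.7
    gi_min: float = 50.0


def maturity_flags(
    record: CompostSampleRecord,
    thresholds: MaturityThresholds = MaturityThresholds(),
    tocn: Optional[float] = None,
) -> dict:
    """Threshold-based maturity flags for one sample.

    Returns a mapping with keys ``tocn_mature``, ``wsc_mature`` and
    ``gi_nonphytotoxic``; each value is True, False, or None when the
    required measurement is missing ("undetermined", never a silent False).

    ``tocn`` overrides the ratio computed from record.toc/record.tn, for
    datasets where only the ratio itself was reported.
    """
    if tocn is None and record.toc is not None and record.tn not in (None, 0):
        tocn = record.toc / record.tn
    return {
        "tocn_mature": None if tocn is None else bool(tocn < thresholds.tocn_max),
        "wsc_mature": None if record.wsc is None else bool(record.wsc <= thresholds.wsc_max),
        "gi_nonphytotoxic": None if record.gi is None else bool(record.gi > thresholds.gi_min),
    }


def index_table(
    records: list[CompostSampleRecord],
    ct: Optional[dict] = None,
    thresholds: MaturityThresholds = MaturityThresholds(),
) -> pd.DataFrame:
    """Per-sample chemical-index table mirroring the classical report layout.

    ``ct`` optionally maps (pile_id, phase) -> total carbon (% dm) for HR/HI
    when records carry no TOC. Columns that cannot be computed for a sample
    are left as NaN/None.
    """
    rows = []
    for r in records:
        row: dict = {
            "pile_id": r.pile_id,
            "phase": r.phase,
            "day": r.day,
            "toc_tn": None,
            "wsc": r.wsc,
            "wsc_tn": None,
            "cfa": r.cfa,
            "cha": r.cha,
            "hr": None,
            "hi": None,
            "pha": None,
            "cha_cfa": None,
        }
        if r.toc is not None and r.tn:
            row["toc_tn"] = elemental_ratio(r.toc, r.tn)
        if r.wsc is not None and r.tn:
            row["wsc_tn"] = elemental_ratio(r.wsc, r.tn)
        if r.cfa is not None and r.cha is not None:
            fr = HumicFractionSet(cfa=r.cfa, cha=r.cha)
            if fr.cext > 0:
                row["pha"] = percentage_humic_acids(fr.cha, fr.cext)
            if fr.cfa > 0:
                row["cha_cfa"] = polymerisation_rate(fr.cha, fr.cfa)
            ct_val = r.toc
            if ct is not None:
                ct_val = ct.get((r.pile_id, r.phase), ct_val)
            if ct_val:
                row["hr"] = humification_ratio(fr.cext, ct_val)
                row["hi"] = humification_index(fr.cha, ct_val)
        row.update(maturity_flags(r, thresholds, tocn=row["toc_tn"]))
        rows.append(row)
    return pd.DataFrame(rows)


def read_samples(path) -> list[CompostSampleRecord]:
    """Read sample records from delimited text (CSV/TSV, sniffed separator).

    One row per sample; column names match the record field names
    (pile_id, phase, day, toc, tn, wsc, cfa, cha, ash, gi). Missing
    optional columns or empty cells become None.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"pile_id", "phase", "day"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        kwargs = {"pile_id": str(row["pile_id"]), "phase": str(row["phase"]), "day": int(row["day"])}
        for name in ("toc", "tn", "wsc", "cfa", "cha", "ash", "gi"):
            if name in df.columns and pd.notna(row[name]):
                kwargs[name] = float(row[name])
        records.append(CompostSampleRecord(**kwargs))
    return records


def write_report(table: pd.DataFrame, csv_path=None, json_path=None, ndigits_ratio=2, ndigits_pct=1):
    """Serialise an index table as CSV and/or JSON.

    Rounding (2 d.p. for ratios, 1 d.p. for percentages by default) is
    applied only at serialisation; the in-memory table keeps full precision.
    """
    out = table.copy()
    for col in ("toc_tn", "wsc_tn", "cha_cfa"):
        if col in out:
            out[col] = out[col].astype(float).round(ndigits_ratio)
    for col in ("wsc", "cfa", "cha", "hr", "hi", "pha"):
        if col in out:
            out[col] = out[col].astype(float).round(ndigits_pct)
    if csv_path is not None:
        out.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(out.to_dict(orient="records"), indent=2) + "\n")
    return out
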
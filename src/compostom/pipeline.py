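"""Per-pile, per-phase orchestration across all analysis stages.

A single TOML config lists the input files and parameters per technique;
:func:`run_pipeline` runs every stage whose inputs are present, skips the
rest (logged), and writes a consolidated report: one CSV per
table-analogue (chemical indices, thermal indices, FT-IR profiles, NMR
regions), JSON reports for the kinetic fits and temperature/EXI results,
one JSON bundle with a provenance map, and a plain-text run log carrying
the software version and the config hash. Reports contain no timestamps,
so re-running on identical inputs yields byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import chem_indices, kinetics, temperature, thermogravimetry, ftir, nmr
from .spectra import read_spectrum

__all__ = ["IndexReport", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    pass


@dataclass
class IndexReport:
    """Consolidated per-run results with a provenance map."""

    chemical: pd.DataFrame | None = None
    kinetic_fits: dict = field(default_factory=dict)
    temperature: dict = field(default_factory=dict)
    thermal: pd.DataFrame | None = None
    ftir: pd.DataFrame | None = None
    nmr: pd.DataFrame | None = None
    provenance: list = field(default_factory=list)
    errors: dict = field(default_factory=dict)
    log: list = field(default_factory=list)

    def completed_stages(self) -> list[str]:
        done = []
        if self.chemical is not None:
            done.append("chemical")
        if self.kinetic_fits:
            done.append("kinetics")
        if self.temperature:
            done.append("temperature")
        if self.thermal is not None:
            done.append("thermal")
        if self.ftir is not None:
            done.append("ftir")
        if self.nmr is not None:
            done.append("nmr")
        return done


def load_config(path) -> dict:
    p = Path(path)
    try:
        with open(p, "rb") as fh:
            cfg = tomllib.load(fh)
    except (OSError, tomllib.TOMLDecodeError) as exc:
        raise PipelineError(f"unreadable config {p}: {exc}") from exc
    if not cfg:
        raise PipelineError(f"config {p} is empty")
    cfg["_base_dir"] = p.parent
    cfg["_hash"] = hashlib.sha256(p.read_bytes()).hexdigest()
    return cfg


def _resolve(cfg: dict, rel) -> Path:
    base = cfg.get("_base_dir", Path("."))
    path = Path(rel)
    return path if path.is_absolute() else base / path


def _stage_chemical(cfg: dict, report: IndexReport) -> None:
    sec = cfg["chemical"]
    src = _resolve(cfg, sec["samples"])
    records = chem_indices.read_samples(src)
    thresholds = chem_indices.MaturityThresholds(
        tocn_max=sec.get("tocn_max", 20.0),
        wsc_max=sec.get("wsc_max", 1.7),
        gi_min=sec.get("gi_min", 50.0),
    )
    report.chemical = chem_indices.index_table(records, thresholds=thresholds)
    report.provenance.append({"stage": "chemical", "input": str(src),
                              "operation": "index_table", "n_samples": len(records)})
    report.log.append(f"chemical: {len(records)} samples from {src.name}")


def _stage_kinetics(cfg: dict, report: IndexReport) -> None:
    sec = cfg["kinetics"]
    for pile, rel in sorted(sec["series"].items()):
        src = _resolve(cfg, rel)
        series = kinetics.read_series(src)
        fit = kinetics.fit_first_order(series)
        summary = kinetics.fit_summary(fit, alpha=sec.get("alpha", 0.001))
        report.kinetic_fits[pile] = {**fit.to_dict(), "p_value": summary["p_value"],
                                     "significant": summary["significant"]}
        report.provenance.append({"stage": "kinetics", "pile": pile, "input": str(src),
                                  "operation": "fit_first_order", "n_obs": fit.n_obs})
        report.log.append(
            f"kinetics[{pile}]: a_max={fit.a_max:.2f} k={fit.k_rate:.5f} "
            f"r2={fit.r_squared:.4f} ({src.name})"
        )


def _stage_temperature(cfg: dict, report: IndexReport) -> None:
    sec = cfg["temperature"]
    delta = sec.get("delta", 2.0)
    persistence = sec.get("persistence", 7)
    clip = sec.get("clip_negative", False)
    for pile, rel in sorted(sec["series"].items()):
        src = _resolve(cfg, rel)
        series = temperature.daily_means(temperature.read_series(src))
        end_day = temperature.detect_bio_oxidative_end(series, delta=delta,
                                                       persistence=persistence)
        eff_end = end_day if end_day is not None else int(series.times[-1]) + 1
        exi = temperature.exothermic_index(series, eff_end, clip_negative=clip)
        report.temperature[pile] = {"end_day": end_day, "exi_cumulated_c": exi,
                                    "n_days": int(series.times.size)}
        report.provenance.append({"stage": "temperature", "pile": pile, "input": str(src),
                                  "operation": "exothermic_index",
                                  "parameters": {"delta": delta, "persistence": persistence,
                                                 "clip_negative": clip}})
        report.log.append(f"temperature[{pile}]: end_day={end_day} EXI={exi:.1f} ({src.name})")


def _stage_thermal(cfg: dict, report: IndexReport) -> None:
    sec = cfg["thermal"]
    p1_lo, p1_hi = sec.get("p1", [250.0, 400.0])
    p2_lo, p2_hi = sec.get("p2", [400.0, 580.0])
    p1 = thermogravimetry.ThermalRegion("P1", p1_lo, p1_hi)
    p2 = thermogravimetry.ThermalRegion("P2", p2_lo, p2_hi)
    rows = []
    for label, rel in sorted(sec["runs"].items()):
        src = _resolve(cfg, rel)
        gram = thermogravimetry.read_thermogram(src)
        idx = thermogravimetry.thermal_indices(gram, p1, p2,
                                               baseline=sec.get("baseline", "linear_endpoints"))
        rows.append({"sample": label, **idx.to_dict()})
        report.provenance.append({"stage": "thermal", "sample": label, "input": str(src),
                                  "operation": "thermal_indices",
                                  "parameters": {"p1": [p1_lo, p1_hi], "p2": [p2_lo, p2_hi]}})
        report.log.append(f"thermal[{label}]: R1={idx.r1:.3f} R2={idx.r2:.3f} ({src.name})")
    report.thermal = pd.DataFrame(rows)


def _stage_ftir(cfg: dict, report: IndexReport) -> None:
    sec = cfg["ftir"]
    bands = tuple(
        ftir.BandDefinition(nominal=float(b)) for b in sec.get("bands", [])
    ) or ftir.DEFAULT_BANDS
    rows = []
    for label, rel in sorted(sec["spectra"].items()):
        src = _resolve(cfg, rel)
        spec = read_spectrum(src, kind="wavenumber_cm-1")
        profile = ftir.ftir_profile(spec, bands)
        row = {"sample": label}
        row.update({f"ra_{int(b)}": v for b, v in sorted(profile.ra.items(), reverse=True)})
        row["ratio_1037_1384"] = profile.ratio_1037_1384
        rows.append(row)
        report.provenance.append({"stage": "ftir", "sample": label, "input": str(src),
                                  "operation": "ftir_profile",
                                  "parameters": {"bands": [b.nominal for b in bands]}})
        report.log.append(f"ftir[{label}]: 1037/1384={profile.ratio_1037_1384:.3f} ({src.name})")
    report.ftir = pd.DataFrame(rows)


def _stage_nmr(cfg: dict, report: IndexReport) -> None:
    sec = cfg["nmr"]
    scheme = nmr.DEFAULT_REGIONS
    if "regions" in sec:
        scheme = nmr.RegionScheme(tuple(
            (r["label"], float(r["high"]), float(r["low"])) for r in sec["regions"]
        ))
    rows = []
    for label, rel in sorted(sec["spectra"].items()):
        src = _resolve(cfg, rel)
        spec = read_spectrum(src, kind="chemical_shift_ppm")
        integrals = nmr.integrate_regions(spec, scheme,
                                          baseline_offset=sec.get("baseline_offset", "none"))
        row = {"sample": label}
        row.update(integrals.relative)
        row["alkyl_oalkyl"] = integrals.alkyl_oalkyl
        rows.append(row)
        report.provenance.append({"stage": "nmr", "sample": label, "input": str(src),
                                  "operation": "integrate_regions",
                                  "parameters": {"regions": list(scheme.regions)}})
        report.log.append(f"nmr[{label}]: alkyl/O-alkyl={integrals.alkyl_oalkyl:.3f} ({src.name})")
    report.nmr = pd.DataFrame(rows)


_STAGES = {
    "chemical": _stage_chemical,
    "kinetics": _stage_kinetics,
    "temperature": _stage_temperature,
    "thermal": _stage_thermal,
    "ftir": _stage_ftir,
    "nmr": _stage_nmr,
}


def run_pipeline(config, outdir=None, strict: bool = False) -> IndexReport:
    """Run every configured stage and (optionally) write the report.

    ``config`` is a path to a TOML file or an already-loaded mapping.
    Missing sections are skipped; a stage error is recorded per stage and
    raised only under ``strict`` (or when every configured stage failed).
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    if not any(name in cfg for name in _STAGES):
        raise PipelineError("config lists no analysis stages")
    report = IndexReport()
    report.log.append(f"compostom {__version__}")
    if "_hash" in cfg:
        report.log.append(f"config sha256 {cfg['_hash']}")
    attempted = 0
    for name, stage in _STAGES.items():
        if name not in cfg:
            report.log.append(f"{name}: no inputs configured, skipped")
            continue
        attempted += 1
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("always")
                stage(cfg, report)
        except Exception as exc:  # noqa: BLE001 - per-stage error capture
            report.errors[name] = f"{type(exc).__name__}: {exc}"
            report.log.append(f"{name}: FAILED ({exc})")
            if strict:
                raise PipelineError(f"stage {name} failed: {exc}") from exc
    if attempted and len(report.errors) == attempted:
        raise PipelineError(f"all stages failed: {report.errors}")
    if outdir is not None:
        write_report(report, outdir)
    return report


def write_report(report: IndexReport, outdir) -> None:
    """Write CSV tables, the JSON bundle and the run log under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"version": __version__, "stages": report.completed_stages(),
                    "errors": report.errors, "provenance": report.provenance}
    if report.chemical is not None:
        report.chemical.to_csv(out / "chemical_indices.csv", index=False)
        bundle["chemical"] = report.chemical.to_dict(orient="records")
    if report.kinetic_fits:
        (out / "kinetics.json").write_text(
            json.dumps(report.kinetic_fits, indent=2, sort_keys=True) + "\n")
        bundle["kinetics"] = report.kinetic_fits
    if report.temperature:
        (out / "temperature.json").write_text(
            json.dumps(report.temperature, indent=2, sort_keys=True) + "\n")
        bundle["temperature"] = report.temperature
    for name, df in (("thermal_indices", report.thermal),
                     ("ftir_profiles", report.ftir),
                     ("nmr_regions", report.nmr)):
        if df is not None:
            df.to_csv(out / f"{name}.csv", index=False)
            bundle[name] = df.to_dict(orient="records")
    (out / "report.json").write_text(json.dumps(bundle, indent=2, sort_keys=True,
                                                default=str) + "\n")
    (out / "run.log").write_text("\n".join(report.log) + "\n")
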
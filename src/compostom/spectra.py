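"""Spectrum container and readers/writers (two-column text, JCAMP-DX).

A :class:`Spectrum` is an abscissa/ordinate pair with an axis kind —
wavenumber (cm⁻¹, FT-IR) or chemical shift (ppm, NMR). On construction the
axis is normalised to descending order, the plotting convention of both
techniques; integration routines re-sort internally as needed.

The JCAMP-DX support covers the uncompressed forms actually produced by
instrument "export as JDX" paths: ``##XYDATA=(X++(Y..Y))`` with AFFN
numbers and ``##XYPOINTS=(XY..XY)``. The compressed SQZ/DIF/DUP encodings
are detected and rejected with a clear message.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Spectrum", "read_spectrum", "write_jcamp", "SpectrumParseError"]

WAVENUMBER = "wavenumber_cm-1"
CHEMICAL_SHIFT = "chemical_shift_ppm"
_AXIS_KINDS = (WAVENUMBER, CHEMICAL_SHIFT)

# JCAMP pseudo-digits used by SQZ/DIF/DUP compression
_COMPRESSED_CHARS = re.compile(r"[@A-DF-Za-df-z%JKLMNOPQRSjklmnopqrs]")


class SpectrumParseError(ValueError):
    """Raised on malformed spectrum files; names the offending line."""


@dataclass
class Spectrum:
    """Abscissa/ordinate trace with an axis kind and free-form metadata."""

    x: np.ndarray
    y: np.ndarray
    kind: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.kind not in _AXIS_KINDS:
            raise ValueError(f"axis kind must be one of {_AXIS_KINDS}, got {self.kind!r}")
        d = np.diff(self.x)
        if np.any(d == 0) or (np.any(d > 0) and np.any(d < 0)):
            raise ValueError("axis must be strictly monotone")
        if d.size and d[0] > 0:  # normalise to descending
            self.x = self.x[::-1].copy()
            self.y = self.y[::-1].copy()

    def __len__(self) -> int:
        return self.x.size

    def ascending(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) sorted ascending, for quadrature/interpolation."""
        return self.x[::-1], self.y[::-1]

    @property
    def x_min(self) -> float:
        return float(self.x[-1])

    @property
    def x_max(self) -> float:
        return float(self.x[0])


def _infer_kind(x: np.ndarray) -> str:
    # FT-IR wavenumbers live in the hundreds-to-thousands of cm-1; 13C
    # chemical shifts in roughly [-20, 230] ppm.
    return WAVENUMBER if float(np.max(x)) > 400.0 else CHEMICAL_SHIFT


def _jcamp_kind(xunits: str) -> str:
    u = xunits.strip().upper()
    if u in ("1/CM", "CM-1", "CM^-1", "WAVENUMBER"):
        return WAVENUMBER
    if u == "PPM":
        return CHEMICAL_SHIFT
    raise SpectrumParseError(f"unknown JCAMP ##XUNITS {xunits!r}; expected 1/CM or PPM")


def _parse_jcamp(text: str, path: str) -> Spectrum:
    meta: dict = {}
    lines = text.splitlines()
    xs: list[float] = []
    ys: list[float] = []
    mode = None  # None | 'xydata' | 'xypoints'
    xfactor = yfactor = 1.0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("$$")[0].strip()  # strip JCAMP comments
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "END":
                break
            if key == "XYDATA":
                if "X++(Y..Y)" not in value.replace(" ", ""):
                    raise SpectrumParseError(
                        f"{path}:{lineno}: unsupported ##XYDATA form {value!r}"
                    )
                mode = "xydata"
            elif key == "XYPOINTS":
                mode = "xypoints"
            elif key == "XFACTOR":
                xfactor = float(value)
            elif key == "YFACTOR":
                yfactor = float(value)
            else:
                meta[key] = value
            continue
        if mode is None:
            raise SpectrumParseError(f"{path}:{lineno}: data before ##XYDATA/##XYPOINTS")
        if _COMPRESSED_CHARS.search(line.replace("E+", "").replace("E-", "").replace("e+", "").replace("e-", "")):
            raise SpectrumParseError(
                f"{path}:{lineno}: compressed JCAMP encodings (SQZ/DIF/DUP) are not "
                "supported; re-export with uncompressed AFFN XYDATA"
            )
        try:
            if mode == "xydata":
                vals = [float(v) for v in re.split(r"[,\s]+", line) if v]
                x0 = vals[0] * xfactor
                yvals = [v * yfactor for v in vals[1:]]
                # abscissa step from the declared grid
                if "DELTAX" in meta:
                    dx = float(meta["DELTAX"]) * 1.0
                elif "FIRSTX" in meta and "LASTX" in meta and "NPOINTS" in meta:
                    n = int(float(meta["NPOINTS"]))
                    dx = (float(meta["LASTX"]) - float(meta["FIRSTX"])) / (n - 1)
                else:
                    raise SpectrumParseError(
                        f"{path}:{lineno}: XYDATA requires ##DELTAX or FIRSTX/LASTX/NPOINTS"
                    )
                for j, yv in enumerate(yvals):
                    xs.append(x0 + j * dx)
                    ys.append(yv)
            else:
                vals = [float(v) for v in re.split(r"[,;\s]+", line) if v]
                if len(vals) % 2:
                    raise SpectrumParseError(f"{path}:{lineno}: odd value count in XYPOINTS")
                xs.extend(v * xfactor for v in vals[0::2])
                ys.extend(v * yfactor for v in vals[1::2])
        except SpectrumParseError:
            raise
        except ValueError as exc:
            raise SpectrumParseError(f"{path}:{lineno}: cannot parse numbers: {exc}") from exc
    if not xs:
        raise SpectrumParseError(f"{path}: no data points found")
    if "XUNITS" not in meta:
        raise SpectrumParseError(f"{path}: missing ##XUNITS")
    kind = _jcamp_kind(meta["XUNITS"])
    return Spectrum(np.array(xs), np.array(ys), kind, metadata=meta)


def read_spectrum(path, kind: str | None = None) -> Spectrum:
    """Read a spectrum from JCAMP-DX or two-column delimited text.

    JCAMP files are recognised by their ``##TITLE``/``##`` records and
    carry their own axis units. For plain text, ``kind`` selects the axis
    (``wavenumber_cm-1`` or ``chemical_shift_ppm``); left as None it is
    inferred from the abscissa range.
    """
    p = Path(path)
    text = p.read_text()
    if text.lstrip().startswith("##"):
        spec = _parse_jcamp(text, str(p))
        if kind is not None and kind != spec.kind:
            raise ValueError(f"requested kind {kind!r} but file declares {spec.kind!r}")
        return spec
    rows = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[,;\s]+", line)
        if lineno == 1 and any(not _is_number(v) for v in parts):
            continue  # header row
        if len(parts) < 2:
            raise SpectrumParseError(f"{p}:{lineno}: expected two columns")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise SpectrumParseError(f"{p}:{lineno}: cannot parse numbers: {exc}") from exc
    if not rows:
        raise SpectrumParseError(f"{p}: no data points found")
    x = np.array([r[0] for r in rows])
    y = np.array([r[1] for r in rows])
    return Spectrum(x, y, kind or _infer_kind(x), metadata={"source": str(p)})


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_jcamp(spectrum: Spectrum, path, title: str = "spectrum") -> None:
    """Write an uncompressed AFFN ``(X++(Y..Y))`` JCAMP-DX file.

    Requires a uniformly spaced axis (instrument exports are); round-trips
    through :func:`read_spectrum` at full float precision.
    """
    x, y = spectrum.ascending()
    dx = np.diff(x)
    if not np.allclose(dx, dx[0], rtol=1e-9, atol=1e-12):
        raise ValueError("JCAMP XYDATA requires a uniformly spaced axis")
    xunits = "1/CM" if spectrum.kind == WAVENUMBER else "PPM"
    lines = [
        "##TITLE=" + title,
        "##JCAMP-DX=4.24",
        "##DATA TYPE=" + ("INFRARED SPECTRUM" if spectrum.kind == WAVENUMBER else "NMR SPECTRUM"),
        f"##XUNITS={xunits}",
        "##YUNITS=ABSORBANCE" if spectrum.kind == WAVENUMBER else "##YUNITS=ARBITRARY",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        f"##FIRSTX={x[0]:.10g}",
        f"##LASTX={x[-1]:.10g}",
        f"##DELTAX={dx[0]:.10g}",
        f"##NPOINTS={x.size}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for i in range(0, x.size, per_line):
        chunk = y[i:i + per_line]
        lines.append(" ".join([f"{x[i]:.10g}"] + [f"{v:.12g}" for v in chunk]))
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")
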
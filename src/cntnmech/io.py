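"""Plain-text file formats.

Force curves travel as a small TSV dialect: a ``#``-prefixed ``key =
value`` metadata header, a column-header line, then two tab-separated
numeric columns ``separation_nm`` and ``force_pN`` printed at 9
significant digits (read-write round trips reproduce the payload
bit-identically at that precision).  Native instrument formats are not
parsed; any converter that emits this dialect plugs in upstream.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .curve import ForceCurve

__all__ = [
    "CurveParseError",
    "read_curve_file",
    "write_curve_file",
    "read_events_table",
    "write_events_table",
]

_EXPECTED_COLS = ("separation_nm", "force_pN")
_FLOAT_META = ("v_um_per_s", "k_c_N_per_m")
_INT_META = ("seed",)


class CurveParseError(ValueError):
    """Malformed curve file; message carries the line number."""


def write_curve_file(curve: ForceCurve, path: str | Path) -> Path:
    """Write one curve in the package TSV dialect; returns the path."""
    path = Path(path)
    lines = []
    meta = dict(curve.meta)
    meta.setdefault("units", "nm,pN")
    for key, value in meta.items():
        lines.append(f"# {key} = {value}")
    lines.append("\t".join(_EXPECTED_COLS))
    for s, f in zip(curve.separation, curve.force):
        lines.append(f"{s:.9g}\t{f:.9g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_curve_file(path: str | Path) -> ForceCurve:
    """Parse a curve file, validating units, columns and monotonicity."""
    path = Path(path)
    meta: dict = {}
    sep: list[float] = []
    force: list[float] = []
    header_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                cols = tuple(c.strip() for c in line.split("\t"))
                if cols != _EXPECTED_COLS:
                    raise CurveParseError(
                        f"{path}:{lineno}: expected columns {_EXPECTED_COLS}, got {cols}"
                        " (unit mismatch?)"
                    )
                header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise CurveParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            try:
                sep.append(float(fields[0]))
                force.append(float(fields[1]))
            except ValueError as exc:
                raise CurveParseError(f"{path}:{lineno}: non-numeric value") from exc
    if not header_seen:
        raise CurveParseError(f"{path}: missing column header line")
    units = meta.get("units", "nm,pN")
    if units.replace(" ", "") != "nm,pN":
        raise CurveParseError(f"{path}: unit mismatch, expected nm,pN got {units!r}")
    for key in _FLOAT_META:
        if key in meta:
            meta[key] = float(meta[key])
    for key in _INT_META:
        if key in meta:
            meta[key] = int(meta[key])
    s = np.asarray(sep)
    if np.any(np.diff(s) <= 0):
        bad = int(np.flatnonzero(np.diff(s) <= 0)[0])
        raise CurveParseError(
            f"{path}: separations not strictly increasing near data row {bad + 1}"
        )
    return ForceCurve(s, np.asarray(force), meta)


def write_events_table(events: pd.DataFrame, path: str | Path) -> Path:
    """Write a per-event table (curve id, index, Fmax, Lc, dL, label)."""
    path = Path(path)
    events.to_csv(path, sep="\t", index=False, float_format="%.9g")
    return path


def read_events_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
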
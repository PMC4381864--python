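"""File formats: GNOM ``.out`` P(r) blocks, plain P(r) tables, time-series
and rate-table CSV, TSV/JSON reports.

All writes are atomic (write to a temp file in the destination directory,
then rename), so an interrupted run never leaves a truncated report.
"""

from __future__ import annotations

import json
import os
import re
import tempfile
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import PrCurve, RateSeries, TimeSeries
from .errors import FormatError, ParseError, StrapkinError

__all__ = [
    "read_gnom_out",
    "write_gnom_out",
    "read_pr_table",
    "write_pr_table",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_rate_csv",
    "write_rate_csv",
    "write_report",
    "write_json",
    "atomic_write_text",
]

# Matches the column header of the distance-distribution block in both the
# classic GNOM output and newer dialects ("R   P(R)   ERROR").
_PR_HEADER = re.compile(r"^\s*R\s+P\(R\)\s+ERROR\s*$")
_PR_SECTION = re.compile(r"Distance distribution", re.IGNORECASE)


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write ``text`` to ``path`` via a temp file + rename in one directory."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _is_float(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_gnom_out(path: str | Path) -> PrCurve:
    """Parse the distance-distribution block of a GNOM ``.out`` file.

    Tolerant to the classic and newer header dialects: the block is located
    by its ``R  P(R)  ERROR`` column header (or a "Distance distribution"
    section title followed by that header) and read as consecutive numeric
    rows of two or three columns.  The curve label is set from the filename.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    start = None
    for i, line in enumerate(lines):
        if _PR_HEADER.match(line):
            start = i + 1
            break
    if start is None:
        raise FormatError(
            f"{path.name}: no distance-distribution block "
            "(missing 'R  P(R)  ERROR' header)"
        )

    r, p, err = [], [], []
    i = start
    # allow blank lines between the header and the data
    while i < len(lines) and not lines[i].strip():
        i += 1
    while i < len(lines):
        tokens = lines[i].split()
        if not tokens:
            break
        if not _is_float(tokens[0]):
            break
        if len(tokens) not in (2, 3) or not all(_is_float(tok) for tok in tokens):
            raise ParseError(
                f"{path.name}: malformed P(r) row at line {i + 1}: {lines[i]!r}",
                line_number=i + 1,
            )
        vals = [float(tok) for tok in tokens]
        r.append(vals[0])
        p.append(vals[1])
        err.append(vals[2] if len(vals) == 3 else np.nan)
        i += 1

    if len(r) < 2:
        raise ParseError(
            f"{path.name}: distance-distribution block has no numeric rows",
            line_number=start + 1,
        )
    err_arr = None if np.all(np.isnan(err)) else np.asarray(err)
    return PrCurve(r=np.asarray(r), p=np.asarray(p), err=err_arr, label=path.stem)


def write_gnom_out(curve: PrCurve, path: str | Path) -> None:
    """Write a P(r) curve in a GNOM-``.out``-like dialect."""
    lines = [
        "           ####    G N O M      (strapkin synthetic dialect)    ####",
        "",
        "           Distance distribution  function of particle",
        "",
        "       R          P(R)      ERROR",
    ]
    err = curve.err if curve.err is not None else np.zeros_like(curve.p)
    for r, p, e in zip(curve.r, curve.p, err):
        lines.append(f"  {r:12.4E}  {p:12.4E}  {e:12.4E}")
    lines.append("")
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_pr_table(path: str | Path) -> PrCurve:
    """Read a plain 2- or 3-column (r, P, [err]) text/CSV file."""
    path = Path(path)
    try:
        data = np.loadtxt(path, ndmin=2)
    except ValueError:
        try:
            data = np.loadtxt(path, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise ParseError(f"{path.name}: could not parse P(r) table: {exc}") from exc
    if data.size == 0 or data.shape[1] < 2:
        raise FormatError(f"{path.name}: expected 2 or 3 numeric columns")
    err = data[:, 2] if data.shape[1] >= 3 else None
    return PrCurve(r=data[:, 0], p=data[:, 1], err=err, label=path.stem)


def write_pr_table(curve: PrCurve, path: str | Path) -> None:
    cols = [curve.r, curve.p] + ([curve.err] if curve.err is not None else [])
    body = "\n".join("  ".join(f"{v:.8E}" for v in row) for row in zip(*cols))
    atomic_write_text(path, body + "\n")


def read_timeseries_csv(path: str | Path, time_unit: str = "min") -> list[TimeSeries]:
    """Read ``t_min,value,channel`` CSV into one TimeSeries per channel.

    With ``time_unit='s'`` the time column is interpreted as seconds and
    converted to minutes on ingest (rates downstream are then min⁻¹).
    """
    if time_unit not in ("s", "min"):
        raise StrapkinError(f"time_unit must be 's' or 'min', got {time_unit!r}")
    df = pd.read_csv(path)
    required = {"t_min", "value", "channel"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{Path(path).name}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    scale = 1.0 / 60.0 if time_unit == "s" else 1.0
    out = []
    for channel, grp in df.groupby("channel", sort=False):
        t = grp["t_min"].to_numpy(dtype=float) * scale
        if grp.duplicated(subset="t_min").any():
            raise FormatError(f"duplicate time point in channel {channel!r}")
        if np.any(np.diff(t) <= 0):
            raise FormatError(f"time not strictly increasing in channel {channel!r}")
        out.append(TimeSeries(t=t, y=grp["value"].to_numpy(dtype=float), channel=str(channel)))
    return out


def write_timeseries_csv(series: Sequence[TimeSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"t_min": ts.t, "value": ts.y, "channel": ts.channel}) for ts in series
    ]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["t_min", "value", "channel"]
    )
    atomic_write_text(path, df.to_csv(index=False))


def read_rate_csv(path: str | Path) -> list[RateSeries]:
    """Read ``protein,T_C,k_per_min`` CSV into one RateSeries per protein."""
    df = pd.read_csv(path)
    required = {"protein", "T_C", "k_per_min"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{Path(path).name}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    return [
        RateSeries(
            T_C=grp["T_C"].to_numpy(dtype=float),
            k=grp["k_per_min"].to_numpy(dtype=float),
            label=str(protein),
        )
        for protein, grp in df.groupby("protein", sort=False)
    ]


def write_rate_csv(series: Sequence[RateSeries], path: str | Path) -> None:
    rows = [
        {"protein": rs.label, "T_C": T, "k_per_min": k}
        for rs in series
        for T, k in zip(rs.T_C, rs.k)
    ]
    df = pd.DataFrame(rows, columns=["protein", "T_C", "k_per_min"])
    atomic_write_text(path, df.to_csv(index=False))


def _format_value(col: str, v) -> str:
    if isinstance(v, (int, np.integer)) or v is None:
        return "" if v is None else str(v)
    if isinstance(v, (float, np.floating)):
        if np.isnan(v):
            return ""
        if "percent" in col or col.endswith("_pct"):
            return f"{v:.1f}"  # percents to 1 decimal
        return f"{v:.4g}"  # rates etc. to 4 significant figures
    return str(v)


def write_report(rows: Iterable[Mapping], columns: Sequence[str], path: str | Path) -> None:
    """Write a TSV report with a stable column order and fixed precision.

    Percent columns print 1 decimal; other numerics 4 significant figures.
    An empty row set still yields a valid header-only file.
    """
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(_format_value(c, row.get(c)) for c in columns))
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_json(obj, path: str | Path) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")
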
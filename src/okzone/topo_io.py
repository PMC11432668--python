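"""Plain-text topography exchange format (TOPO-CSV).

A portable stand-in for proprietary topographer exports.  Layout:

.. code-block:: text

    # format_version: 1
    # eye: OD
    # grid: polar
    # units: mm
    angle_deg,radius_mm,height_mm
    0,0,0
    0,0.5,-0.0160259
    ...

Header lines are ``# key: value``; required keys are ``format_version``,
``eye`` (OD|OS), ``grid`` (polar|cartesian) and ``units`` (mm).  Then one CSV
record per sample — ``angle_deg,radius_mm,height_mm`` for polar grids or
``x_mm,y_mm,height_mm`` for Cartesian ones.  An empty height field marks a
masked node.  Heights are written with 17 significant digits, so finite
float64 values round-trip bit-identically.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import CartesianGrid, PolarGrid
from .surface import CornealSurface

__all__ = ["read_topo_csv", "write_topo_csv", "TopoFormatError"]

_REQUIRED_KEYS = ("format_version", "eye", "grid", "units")
_POLAR_COLS = ["angle_deg", "radius_mm", "height_mm"]
_CART_COLS = ["x_mm", "y_mm", "height_mm"]


class TopoFormatError(ValueError):
    """Raised when a TOPO-CSV file does not conform to the dialect."""


def _parse_header(lines: list[str]) -> dict[str, str]:
    header: dict[str, str] = {}
    for ln in lines:
        body = ln[1:].strip()
        if ":" not in body:
            raise TopoFormatError(f"malformed header line: {ln!r}")
        key, _, value = body.partition(":")
        header[key.strip()] = value.strip()
    missing = [k for k in _REQUIRED_KEYS if k not in header]
    if missing:
        raise TopoFormatError(f"missing required header keys: {missing}")
    return header


def read_topo_csv(path: str | Path) -> CornealSurface:
    """Read a TOPO-CSV file into a :class:`CornealSurface`.

    The records must form a complete lattice (every angle/radius or x/y
    combination present exactly once).  Unparseable rows and lattice
    violations raise rather than being silently dropped.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    hdr_lines = [ln for ln in lines if ln.startswith("#")]
    header = _parse_header(hdr_lines)

    eye = header["eye"]
    if eye not in ("OD", "OS"):
        raise TopoFormatError(f"laterality must be OD or OS, got {eye!r}")
    gkind = header["grid"]
    if gkind not in ("polar", "cartesian"):
        raise TopoFormatError(f"grid must be 'polar' or 'cartesian', got {gkind!r}")
    if header["units"] != "mm":
        raise TopoFormatError(f"units must be 'mm', got {header['units']!r}")

    body = "\n".join(ln for ln in lines if not ln.startswith("#") and ln.strip())
    if not body:
        raise TopoFormatError("file contains no data records")
    cols = _POLAR_COLS if gkind == "polar" else _CART_COLS
    try:
        df = pd.read_csv(io.StringIO(body), dtype=float, float_precision="round_trip")
    except ValueError as exc:
        raise TopoFormatError(f"unparseable data records: {exc}") from exc
    if list(df.columns) != cols:
        raise TopoFormatError(f"expected columns {cols}, got {list(df.columns)}")
    if df[cols[0]].isna().any() or df[cols[1]].isna().any():
        raise TopoFormatError("coordinate fields must not be empty")

    a = df[cols[0]].to_numpy()
    b = df[cols[1]].to_numpy()
    h = df[cols[2]].to_numpy()  # NaN where the height field was empty (masked)

    ua = np.unique(a)
    ub = np.unique(b)
    if ua.size * ub.size != len(df):
        raise TopoFormatError(
            "records do not form a complete lattice "
            f"({ua.size} x {ub.size} levels but {len(df)} rows; duplicates or holes)"
        )
    ia = np.searchsorted(ua, a)
    ib = np.searchsorted(ub, b)
    flat = ia * ub.size + ib
    if np.unique(flat).size != len(df):
        raise TopoFormatError("duplicated coordinate pair in records")

    if gkind == "polar":
        grid = PolarGrid(ua, ub)  # validates angle range, monotone radii
        heights = np.full(grid.shape, np.nan)
        heights[ia, ib] = h
    else:
        grid = CartesianGrid(ua, ub)
        heights = np.full(grid.shape, np.nan)
        heights[ib, ia] = h  # row-major (y, x) layout
    return CornealSurface(grid, heights, eye)


def write_topo_csv(surface: CornealSurface, path: str | Path) -> Path:
    """Write a surface to TOPO-CSV.  Round-trips through :func:`read_topo_csv`."""
    if surface.n_valid() == 0:
        raise ValueError("no valid samples: refusing to write an all-masked surface")
    path = Path(path)
    if surface.is_polar:
        grid: PolarGrid = surface.grid  # type: ignore[assignment]
        cols = _POLAR_COLS
        gkind = "polar"
        aa = np.repeat(grid.meridian_angles, grid.n_radii)
        bb = np.tile(grid.radii, grid.n_angles)
        hh = surface.heights.ravel()
    else:
        cg: CartesianGrid = surface.grid  # type: ignore[assignment]
        cols = _CART_COLS
        gkind = "cartesian"
        x, y = cg.node_xy()
        aa, bb, hh = x.ravel(), y.ravel(), surface.heights.ravel()

    def fmt(v: float) -> str:
        return "" if not np.isfinite(v) else format(v, ".17g")

    with path.open("w", encoding="utf-8") as fh:
        fh.write("# format_version: 1\n")
        fh.write(f"# eye: {surface.laterality}\n")
        fh.write(f"# grid: {gkind}\n")
        fh.write("# units: mm\n")
        fh.write(",".join(cols) + "\n")
        for a, b, h in zip(aa, bb, hh):
            fh.write(f"{format(a, '.17g')},{format(b, '.17g')},{fmt(h)}\n")
    return path
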
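"""CSV/JSON round-tripping for point patterns, sweep tables and omega tables.

Conventions: counts are written exactly; real values at 12 significant
digits; undefined values (e.g. ``ln`` of a zero count) are written as empty
cells, never as ``inf``/``nan`` text.  Point-pattern CSV starts with a
``# width=<W> height=<H>`` metadata line followed by an ``x,y`` header.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import sawcount
from .pointpi import PointPattern
from .sawcount import OmegaTable, omega_analytic

__all__ = [
    "write_point_csv",
    "read_point_csv",
    "omega_frame",
    "write_omega_csv",
    "sweep_frame",
    "write_sweep_csv",
    "read_observations_csv",
]

_REAL_FMT = "%.12g"


def write_point_csv(pattern: PointPattern, path) -> None:
    """Write a point pattern with its field-of-view header line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# width={_REAL_FMT % pattern.width} height={_REAL_FMT % pattern.height}\n")
        fh.write("x,y\n")
        for x, y in pattern.points:
            fh.write(f"{_REAL_FMT % x},{_REAL_FMT % y}\n")


def read_point_csv(path) -> PointPattern:
    """Read a point pattern, validating the header and field bounds.

    Raises ``ValueError`` with a row-numbered message for malformed or
    out-of-bounds rows, and for a missing metadata header.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing '# width=... height=...' header line")
        meta = dict(
            item.split("=", 1) for item in first.lstrip("#").split() if "=" in item
        )
        try:
            width = float(meta["width"])
            height = float(meta["height"])
        except (KeyError, ValueError):
            raise ValueError(f"{path}: header must carry width= and height=") from None
        header = fh.readline().strip()
        if header.replace(" ", "") != "x,y":
            raise ValueError(f"{path}: expected 'x,y' column header, got {header!r}")
        pts = []
        for lineno, line in enumerate(fh, start=3):
            line = line.strip()
            if not line:
                continue
            try:
                x_s, y_s = line.split(",")
                x, y = float(x_s), float(y_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed point row {line!r}") from None
            if not (0.0 <= x <= width and 0.0 <= y <= height):
                raise ValueError(
                    f"{path}:{lineno}: point ({x}, {y}) outside the declared "
                    f"{width} x {height} field"
                )
            pts.append((x, y))
    return PointPattern(width=width, height=height, points=np.array(pts).reshape(-1, 2))


def omega_frame(tables: list[OmegaTable]) -> pd.DataFrame:
    """One row per step: counts, their logs, D, and the analytic comparison."""
    rows = []
    for t in tables:
        ln_open = math.log(t.omega_open) if t.omega_open > 0 else np.nan
        ln_blocked = math.log(t.omega_blocked) if t.omega_blocked > 0 else np.nan
        try:
            d = sawcount.log_omega_difference(t)
        except ValueError:
            d = np.nan
        rows.append(
            {
                "n_step": t.n_step,
                "omega_total": t.omega_total,
                "omega_open": t.omega_open,
                "omega_blocked": t.omega_blocked,
                "n_half_left": t.n_half_left,
                "n_half_right": t.n_half_right,
                "n_full": t.n_full,
                "ln_omega_open": ln_open,
                "ln_omega_blocked": ln_blocked,
                "D": d,
                "omega_analytic": omega_analytic(t.n_step),
            }
        )
    return pd.DataFrame(rows)


def write_omega_csv(tables: list[OmegaTable], path) -> None:
    omega_frame(tables).to_csv(path, index=False, float_format=_REAL_FMT)


def sweep_frame(cells) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "n_dots": c.n_dots,
                "n_trials": c.n_trials,
                "mean_pi": c.mean_pi,
                "sd_pi": c.sd_pi,
            }
            for c in cells
        ]
    )


def write_sweep_csv(cells, path) -> None:
    sweep_frame(cells).to_csv(path, index=False, float_format=_REAL_FMT)


def read_observations_csv(path) -> list[tuple[int, str]]:
    """Read observed-lattice rows with columns ``motif_count`` and ``class``."""
    df = pd.read_csv(path)
    missing = {"motif_count", "class"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [(int(r.motif_count), str(r["class"])) for _, r in df.iterrows()]
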
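"""Reading and writing activation matrices as CSV and OpenSim storage files.

On disk, rows are gait-cycle grid points and columns are muscles (plus an
optional leading time column); in memory an activation matrix is muscles x
grid points, matching the factorization convention.  Files with a
different number of time rows are resampled to the 101-point normalized
gait grid by linear interpolation.  Tiny negative activations (optimal
control solver round-off) are clipped to zero with a logged warning;
substantial negative values are an error.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .conditions import N_GRID_POINTS

logger = logging.getLogger(__name__)

#: Largest negative activation magnitude treated as solver round-off.
NEGATIVE_CLIP_TOL = 1e-3


def write_activations_csv(
    path: str | Path, E: np.ndarray, muscle_names: list[str] | tuple[str, ...]
) -> None:
    """Write E (muscles x T) as CSV: header of muscle names, T data rows."""
    E = np.asarray(E, dtype=float)
    if E.shape[0] != len(muscle_names):
        raise ValueError(
            f"E has {E.shape[0]} muscle rows but {len(muscle_names)} names given"
        )
    pd.DataFrame(E.T, columns=list(muscle_names)).to_csv(path, index=False)


def write_activations_sto(
    path: str | Path,
    E: np.ndarray,
    muscle_names: list[str] | tuple[str, ...],
    time: np.ndarray | None = None,
    name: str = "activations",
) -> None:
    """Write E (muscles x T) in the OpenSim storage (.sto) dialect.

    Header block terminated by ``endheader``, then a tab-delimited label
    row starting with ``time`` and one row per grid point.  ``time``
    defaults to normalized cycle time 0..1.
    """
    E = np.asarray(E, dtype=float)
    if E.shape[0] != len(muscle_names):
        raise ValueError(
            f"E has {E.shape[0]} muscle rows but {len(muscle_names)} names given"
        )
    T = E.shape[1]
    if time is None:
        time = np.linspace(0.0, 1.0, T)
    time = np.asarray(time, dtype=float)
    if time.shape != (T,):
        raise ValueError(f"time must have shape ({T},), got {time.shape}")
    with open(path, "w") as fh:
        fh.write(f"{name}\n")
        fh.write("version=1\n")
        fh.write(f"nRows={T}\n")
        fh.write(f"nColumns={len(muscle_names) + 1}\n")
        fh.write("inDegrees=no\n")
        fh.write("endheader\n")
        fh.write("time\t" + "\t".join(muscle_names) + "\n")
        for t in range(T):
            row = "\t".join(f"{v:.10g}" for v in E[:, t])
            fh.write(f"{time[t]:.10g}\t{row}\n")


def _read_sto(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        lines = fh.readlines()
    end = None
    for i, line in enumerate(lines):
        if line.strip().lower() == "endheader":
            end = i
            break
    if end is None:
        raise ValueError(f"{path}: malformed STO header (no 'endheader' line)")
    body = lines[end + 1 :]
    if not body:
        raise ValueError(f"{path}: no column-label row after 'endheader'")
    labels = body[0].split()
    data = []
    for ln in body[1:]:
        if not ln.strip():
            continue
        fields = ln.split()
        if len(fields) != len(labels):
            raise ValueError(
                f"{path}: data row has {len(fields)} fields, expected {len(labels)}"
            )
        data.append([float(v) for v in fields])
    return pd.DataFrame(data, columns=labels)


def load_activation_file(
    path: str | Path,
    format: str | None = None,
    T: int = N_GRID_POINTS,
) -> tuple[np.ndarray, list[str]]:
    """Load an activation matrix plus muscle names from CSV or .sto.

    Returns (E, muscle_names) with E muscles x ``T``, resampled by linear
    interpolation on normalized time when the file has a different number
    of rows.  A leading ``time`` column (case-insensitive) is stripped and,
    if present, used as the interpolation abscissa.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = "sto" if path.suffix.lower() == ".sto" else "csv"
    if format == "csv":
        df = pd.read_csv(path)
    elif format == "sto":
        df = _read_sto(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'sto'")

    cols = list(df.columns)
    if cols and cols[0].strip().lower() == "time":
        time = df[cols[0]].to_numpy(dtype=float)
        df = df[cols[1:]]
    else:
        time = np.linspace(0.0, 1.0, len(df))
    muscle_names = [c.strip() for c in df.columns]
    values = df.to_numpy(dtype=float)  # rows = grid points

    vmin = values.min() if values.size else 0.0
    if vmin < 0:
        if vmin < -NEGATIVE_CLIP_TOL:
            raise ValueError(
                f"{path}: negative activation {vmin:.3g} exceeds round-off "
                f"tolerance {NEGATIVE_CLIP_TOL}"
            )
        logger.warning(
            "%s: clipping %d small negative activations (min %.3g) to zero",
            path,
            int((values < 0).sum()),
            vmin,
        )
        values = np.clip(values, 0.0, None)

    if len(values) != T:
        if len(values) < 2:
            raise ValueError(f"{path}: need at least 2 time rows to resample")
        span = time[-1] - time[0]
        t_norm = (time - time[0]) / span if span > 0 else np.linspace(0, 1, len(values))
        t_new = np.linspace(0.0, 1.0, T)
        values = np.column_stack(
            [np.interp(t_new, t_norm, values[:, j]) for j in range(values.shape[1])]
        )
    return values.T.copy(), muscle_names


__all__ = [
    "write_activations_csv",
    "write_activations_sto",
    "load_activation_file",
    "NEGATIVE_CLIP_TOL",
]
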
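"""Delimited-text and TIFF I/O for the package's data types."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import COUNT_COLUMNS, CountTable, DecaySeries
from .spots import SpotCall
from .telegraph import Pmf


def read_count_table(path: str | Path, operator_label: str | None = None) -> CountTable:
    """Read a per-cell count table (CSV with cell_id,length_um,mrna_count)."""
    df = pd.read_csv(path)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    label = operator_label if operator_label is not None else Path(path).stem
    return CountTable(df[COUNT_COLUMNS].copy(), label)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def read_decay_series(path: str | Path) -> list[DecaySeries]:
    """Read decay series (CSV with time_min,relative_level,replicate)."""
    df = pd.read_csv(path)
    for c in ("time_min", "relative_level", "replicate"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    out = []
    for rep, sub in df.groupby("replicate", sort=True):
        sub = sub.sort_values("time_min")
        out.append(
            DecaySeries(
                sub["time_min"].to_numpy(float),
                sub["relative_level"].to_numpy(float),
                replicate_id=str(rep),
            )
        )
    return out


def write_decay_series(series: list[DecaySeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"time_min": s.times, "relative_level": s.levels, "replicate": s.replicate_id}
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_pmf(pmf: Pmf, path: str | Path) -> None:
    """Two-column delimited text: m, probability."""
    pd.DataFrame({"m": pmf.support, "probability": pmf.probs}).to_csv(
        path, sep="\t", index=False
    )


def read_pmf(path: str | Path) -> Pmf:
    df = pd.read_csv(path, sep="\t")
    probs = df["probability"].to_numpy(float)
    return Pmf(probs, len(probs) - 1, max(0.0, 1.0 - probs.sum()))


def write_spot_calls(calls: list[SpotCall], path: str | Path) -> None:
    """Delimited text: z,y,x,peak,intensity,cell_label."""
    pd.DataFrame(
        [
            {
                "z": c.z_plane,
                "y": c.y,
                "x": c.x,
                "peak": c.peak_value,
                "intensity": c.integrated_intensity,
                "cell_label": -1 if c.cell_label is None else c.cell_label,
            }
            for c in calls
        ],
        columns=["z", "y", "x", "peak", "intensity", "cell_label"],
    ).to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_round_floats(obj), indent=2, sort_keys=True) + "\n")


def _round_floats(obj, sig: int = 6):
    """Round floats to 6 significant digits for cross-platform determinism."""
    if isinstance(obj, float):
        if obj == 0 or not np.isfinite(obj):
            return obj
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def save_stack_tiff(voxels: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(
        path, np.asarray(voxels, dtype=np.float32), photometric="minisblack"
    )


def load_stack_tiff(path: str | Path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=float)
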
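"""Field export: CSV snapshot tables and legacy-ASCII VTK volumes."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import DiscreteDomain
from .solver import OxygenHistory

_COORD_COLUMNS = ("x_um", "y_um", "z_um")


def history_to_frame(history: OxygenHistory,
                     domain: DiscreteDomain) -> pd.DataFrame:
    """Long-format snapshot table: stage, time_s, node_index, coordinates,
    o_uM."""
    coords = domain.coordinates()
    frames = []
    for stage in history.stages:
        for t, values in zip(stage.times, stage.values):
            df = pd.DataFrame({"stage": stage.stage, "time_s": t,
                               "node_index": np.arange(domain.n_nodes)})
            for ax in range(domain.ndim):
                df[_COORD_COLUMNS[ax]] = coords[:, ax]
            df["o_uM"] = values
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def field_to_frame(field: np.ndarray, domain: DiscreteDomain,
                   name: str = "value") -> pd.DataFrame:
    """Per-node scalar field (CNED, FEDMF, ...) as a coordinate table."""
    coords = domain.coordinates()
    df = pd.DataFrame({"node_index": np.arange(domain.n_nodes)})
    for ax in range(domain.ndim):
        df[_COORD_COLUMNS[ax]] = coords[:, ax]
    df[name] = np.asarray(field).reshape(-1)
    return df


def write_vtk(path: str | Path, domain: DiscreteDomain,
              fields: dict[str, np.ndarray]) -> None:
    """Write scalar fields on the structured grid as a legacy ASCII VTK
    STRUCTURED_POINTS file (2D grids get a single-layer z dimension)."""
    shape = tuple(domain.shape) + (1,) * (3 - domain.ndim)
    lines = [
        "# vtk DataFile Version 3.0",
        "flashox structured field export",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {shape[0]} {shape[1]} {shape[2]}",
        "ORIGIN 0 0 0",
        f"SPACING {domain.dx} {domain.dx} {domain.dx}",
        f"POINT_DATA {domain.n_nodes}",
    ]
    for name, field in fields.items():
        data = np.asarray(field, dtype=float).reshape(domain.shape)
        # VTK expects x fastest; our flat order has the last axis fastest
        flat = data.transpose().reshape(-1)
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(" ".join(f"{v:.6g}" for v in flat[i:i + 9])
                     for i in range(0, flat.size, 9))
    Path(path).write_text("\n".join(lines) + "\n")
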
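"""File output: PNG snapshots, CSV exports, legacy VTK volumes, summaries."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .celltypes import N_TYPES, PALETTE, TYPE_NAMES

__all__ = ["snapshot", "save_state_png", "save_field_png", "save_vtk",
           "cells_to_csv", "write_summary"]

_PALETTE_ARR = np.zeros((N_TYPES, 3), dtype=np.uint8)
for _t, _rgb in PALETTE.items():
    _PALETTE_ARR[_t] = _rgb


def save_state_png(state, path, scale: int = 4):
    """Render the type map with the standard layer palette (y up)."""
    img = _PALETTE_ARR[state.tmap[::-1, :]]
    im = Image.fromarray(img, mode="RGB")
    im = im.resize((im.width * scale, im.height * scale), Image.NEAREST)
    im.save(path)
    return path


def save_field_png(field_, path, scale: int = 4, vmax: float | None = None):
    """Blue-to-red heatmap of a scalar field (y up)."""
    import matplotlib.cm as cm

    c = field_.c[::-1, :]
    vmax = vmax or (c.max() if c.max() > 0 else 1.0)
    rgba = cm.jet(np.clip(c / vmax, 0, 1))
    im = Image.fromarray((rgba[..., :3] * 255).astype(np.uint8), mode="RGB")
    im = im.resize((im.width * scale, im.height * scale), Image.NEAREST)
    im.save(path)
    return path


def save_vtk(state, path):
    """Legacy ASCII VTK structured-points dump of spins and types."""
    H, W = state.spin.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("corneasim lattice snapshot\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {W} {H} 1\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {state.voxel_edge} {state.voxel_edge} 1\n")
        fh.write(f"POINT_DATA {W * H}\n")
        fh.write("SCALARS cell_id int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, state.spin.reshape(1, -1), fmt="%d")
        fh.write("SCALARS cell_type int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, state.tmap.reshape(1, -1), fmt="%d")
    return path


def cells_to_csv(cells, path):
    """Export the live-cell registry (id, type, volume, centroid)."""
    ids = cells.live_ids()
    df = pd.DataFrame({
        "id": ids,
        "type": [TYPE_NAMES[t] for t in cells.ctype[ids]],
        "volume": cells.vol[ids],
        "centroid_x": cells.sumx[ids] / cells.vol[ids],
        "centroid_y": cells.sumy[ids] / cells.vol[ids],
    })
    df.to_csv(path, index=False)
    return path


def snapshot(state, fields, path, kind: str = "png"):
    """Write one snapshot file of the requested kind."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if kind == "png":
        return save_state_png(state, path)
    if kind == "vtk":
        return save_vtk(state, path)
    if kind.startswith("field:"):
        return save_field_png(fields[kind.split(":", 1)[1]], path)
    raise ValueError(f"unknown snapshot kind {kind!r}")


def write_summary(sim, path):
    """Run summary JSON with provenance header."""
    from .metrics import stability_day, stratification_day

    m = sim.metrics
    summary = {
        "provenance": {
            "config_digest": sim.config.digest(),
            "seed": sim.seed,
            "package": "corneasim-0.1.0",
        },
        "mcs": sim.state.mcs,
        "days": sim.state.day,
        "final_counts": sim.counts(),
        "stratification_day": stratification_day(m),
        "stability_day": stability_day(m),
        "final_thickness_um": m[-1].thickness_com if m else None,
    }
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return path
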
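"""Snapshot, event and timeseries writers (CSV + metadata JSON).

All numeric columns carry unit suffixes in their headers. Outputs from the
same (config, seed) are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ..coupling import RealisationResult
from ..mechanics import CellPopulation, STEM
from .config import RunConfig, config_hash

__all__ = [
    "snapshot_frame",
    "write_snapshot",
    "write_events",
    "write_thickness",
    "write_metadata",
    "write_outputs",
]

SNAPSHOT_COLUMNS = [
    "id", "type", "x_CD", "y_CD", "z_CD", "radius_CD", "age_hr",
    "s", "e", "c_i", "is_surface",
]

EVENT_COLUMNS = ["cell_id", "time_hr", "age_hr", "z_CD", "s", "clump_id"]


def snapshot_frame(cells: CellPopulation, t: float) -> pd.DataFrame:
    n = cells.n
    return pd.DataFrame({
        "id": cells.ids[:n],
        "type": np.where(cells.types[:n] == STEM, "stem", "differentiated"),
        "x_CD": cells.positions[:n, 0],
        "y_CD": cells.positions[:n, 1],
        "z_CD": cells.positions[:n, 2],
        "radius_CD": cells.radii[:n],
        "age_hr": t - cells.birth_times[:n],
        "s": cells.chem[:n, 1],
        "e": cells.chem[:n, 0],
        "c_i": cells.chem[:n, 4],
        "is_surface": cells.is_surface[:n],
    })


def write_snapshot(cells: CellPopulation, t: float, path) -> None:
    snapshot_frame(cells, t).to_csv(path, index=False, float_format="%.6g")


def write_events(events: list, path) -> None:
    rows = [{"cell_id": e.cell_id, "time_hr": e.time, "age_hr": e.age,
             "z_CD": e.z, "s": e.s, "clump_id": e.clump_id} for e in events]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False,
                                                     float_format="%.6g")


def write_thickness(thickness: pd.DataFrame, path, realisation: int | None = None) -> None:
    df = thickness.copy()
    if realisation is not None:
        df.insert(0, "realisation", realisation)
    df.to_csv(path, index=False, float_format="%.6g")


def write_metadata(cfg: RunConfig, path, extra: dict | None = None) -> None:
    meta = {"config": cfg.to_dict(), "config_hash": config_hash(cfg)}
    if extra:
        meta.update(extra)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def write_outputs(results: list[RealisationResult], cfg: RunConfig, outdir) -> list[str]:
    """Write thickness CSV, events CSV, final snapshots and metadata JSON.

    Returns the list of files written (paths relative to ``outdir``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    frames = []
    for r in results:
        df = r.thickness.copy()
        df.insert(0, "realisation", r.realisation)
        frames.append(df)
        epath = out / f"events_r{r.realisation}.csv"
        write_events(r.removal_events, epath)
        written.append(epath.name)
        t_final = float(r.thickness["t_hr"].iloc[-1]) if len(r.thickness) else 0.0
        spath = out / f"snapshot_r{r.realisation}.csv"
        write_snapshot(r.final_population, t_final, spath)
        written.append(spath.name)
    tpath = out / "thickness.csv"
    pd.concat(frames, ignore_index=True).to_csv(tpath, index=False, float_format="%.6g")
    written.append(tpath.name)
    mpath = out / "metadata.json"
    write_metadata(cfg, mpath, extra={"n_realisations": len(results)})
    written.append(mpath.name)
    return written
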
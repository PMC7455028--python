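"""CSV schemas, run manifests and table round-tripping.

CSV is the canonical interchange format: outputs at this model's scale
are small and must stay diffable. Numbers are written with 17 significant
digits so tables round-trip bit-identically through text.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from .engine import Snapshot, TrajectoryRecord

__all__ = [
    "SCHEMAS",
    "SchemaError",
    "write_csv",
    "read_csv",
    "snapshots_to_frame",
    "trajectories_to_frame",
    "frame_to_trajectories",
    "write_manifest",
]

SCHEMAS: Dict[str, List[str]] = {
    "snapshots": ["time", "agent_type", "id", "x", "y", "phenotype", "s", "labelled"],
    "trajectories": ["bead_id", "t", "r", "omega"],
    "bead_summaries": ["bead_id", "t_cross", "T_wait", "V_r", "core_reached"],
    "histograms": ["t", "bin_left", "bin_right", "frequency"],
    "composition": ["phenotype", "r_inner", "r_outer", "width", "area", "proportion"],
    "sweep": [
        "run_id", "tau", "omega_q", "T_wait", "V_r",
        "prop_prolif", "prop_quiescent", "prop_hypoxic", "prop_necrotic", "seed",
    ],
}


class SchemaError(ValueError):
    """Raised when a table does not match its declared schema."""


def write_csv(df: pd.DataFrame, schema: str, path) -> None:
    """Write a table in a named schema (column order enforced)."""
    cols = _check(df, schema)
    df[cols].to_csv(path, index=False, float_format="%.17g")


def read_csv(schema: str, path) -> pd.DataFrame:
    """Read and validate a table; column order in the file is free."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema '{schema}'")
    df = pd.read_csv(path, float_precision="round_trip")
    cols = _check(df, schema)
    return df[cols]


def _check(df: pd.DataFrame, schema: str) -> List[str]:
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema '{schema}'")
    cols = SCHEMAS[schema]
    missing = set(cols) - set(df.columns)
    extra = set(df.columns) - set(cols)
    if missing or extra:
        raise SchemaError(
            f"schema '{schema}' mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
        )
    return cols


def snapshots_to_frame(snapshots: List[Snapshot]) -> pd.DataFrame:
    """Long-format table of all agents over all snapshot times."""
    rows = []
    for snap in snapshots:
        n = snap.cell_ids.size
        if n:
            rows.append(
                pd.DataFrame(
                    {
                        "time": snap.time,
                        "agent_type": "cell",
                        "id": snap.cell_ids,
                        "x": snap.cell_pos[:, 0],
                        "y": snap.cell_pos[:, 1],
                        "phenotype": snap.cell_phenotype,
                        "s": snap.cell_s,
                        "labelled": snap.cell_labelled,
                    }
                )
            )
        if snap.bead_ids.size:
            rows.append(
                pd.DataFrame(
                    {
                        "time": snap.time,
                        "agent_type": "bead",
                        "id": snap.bead_ids,
                        "x": snap.bead_pos[:, 0],
                        "y": snap.bead_pos[:, 1],
                        "phenotype": -1,
                        "s": 0.5,
                        "labelled": False,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=SCHEMAS["snapshots"])
    return pd.concat(rows, ignore_index=True)


def trajectories_to_frame(trajectories: List[TrajectoryRecord]) -> pd.DataFrame:
    rows = [
        pd.DataFrame(
            {"bead_id": tr.bead_id, "t": tr.times, "r": tr.r, "omega": tr.omega}
        )
        for tr in trajectories
    ]
    if not rows:
        return pd.DataFrame(columns=SCHEMAS["trajectories"])
    return pd.concat(rows, ignore_index=True)


def frame_to_snapshots(df: pd.DataFrame) -> List[Snapshot]:
    """Rebuild snapshot objects from a long-format agent table."""
    import numpy as np

    from .state import Phenotype

    _check(df, "snapshots")
    out = []
    for time, grp in df.groupby("time", sort=True):
        cells = grp[grp["agent_type"] == "cell"]
        beads = grp[grp["agent_type"] == "bead"]
        cell_pos = cells[["x", "y"]].to_numpy(float)
        centroid = cell_pos.mean(axis=0) if len(cells) else np.zeros(2)
        r = (
            np.hypot(*(cell_pos - centroid).T)
            if len(cells)
            else np.zeros(0)
        )
        phen = cells["phenotype"].to_numpy(np.int8)
        out.append(
            Snapshot(
                time=float(time),
                cell_ids=cells["id"].to_numpy(np.int64),
                cell_pos=cell_pos,
                cell_phenotype=phen,
                cell_s=cells["s"].to_numpy(float),
                cell_labelled=cells["labelled"].to_numpy(bool),
                bead_ids=beads["id"].to_numpy(np.int64),
                bead_pos=beads[["x", "y"]].to_numpy(float),
                centroid=centroid,
                radius=float(r.max()) if r.size else 0.0,
                compartment_outer={
                    int(p): float(r[phen == int(p)].max()) if (phen == int(p)).any() else 0.0
                    for p in Phenotype
                },
            )
        )
    return out


def frame_to_trajectories(df: pd.DataFrame) -> List[TrajectoryRecord]:
    """Rebuild trajectory records from a long-format table."""
    _check(df, "trajectories")
    out = []
    for bead_id, grp in df.groupby("bead_id", sort=True):
        grp = grp.sort_values("t")
        out.append(
            TrajectoryRecord(
                bead_id=int(bead_id),
                times=grp["t"].to_numpy(float),
                r=grp["r"].to_numpy(float),
                omega=grp["omega"].to_numpy(float),
            )
        )
    return out


def transitions_to_frame(transitions) -> pd.DataFrame:
    """Phenotype-transition log as a (time, cell_id, from, to, trigger) table."""
    return pd.DataFrame(
        {
            "time": [tr.time for tr in transitions],
            "cell_id": [tr.cell_id for tr in transitions],
            "from": [tr.from_phenotype.name for tr in transitions],
            "to": [tr.to_phenotype.name for tr in transitions],
            "trigger": [tr.trigger for tr in transitions],
        }
    )


def write_manifest(outdir, cfg, seed: int, files: Dict[str, int],
                   started: str = "", finished: str = "") -> Path:
    """Write the run manifest: config echo, seed, and output inventory."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "seed": seed,
        "started": started or datetime.datetime.now().isoformat(),
        "finished": finished or datetime.datetime.now().isoformat(),
        "outputs": files,
    }
    path = outdir / "manifest.json"
    tmp = path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    tmp.replace(path)
    return path
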
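"""Snapshot and table input/output: JSON community snapshots, CSV
interaction matrices and edge lists, assembly logs and trial trajectories."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .assembly import AssemblyLog
from .community import Community, GuildState, InteractionMatrix
from .dynamics import Trajectory
from .params import ModelParams

__all__ = [
    "community_to_dict",
    "community_from_dict",
    "save_community",
    "load_community",
    "matrix_to_csv",
    "matrix_from_csv",
    "edge_list",
    "trajectory_to_frame",
    "assembly_log_to_dict",
    "save_assembly_log",
    "trait_trajectory_frame",
]


def community_to_dict(community: Community) -> dict:
    d = {
        "params": community.params.to_dict(),
        "animals": {"traits": community.animals.traits.tolist(),
                    "densities": community.animals.densities.tolist()},
        "plants": {"traits": community.plants.traits.tolist(),
                   "densities": community.plants.densities.tolist()},
        "alien_index": community.alien_index,
        "alien_sigma_m": community.alien_sigma_m,
    }
    if community.animal_ids is not None:
        d["animal_ids"] = community.animal_ids.tolist()
    if community.plant_ids is not None:
        d["plant_ids"] = community.plant_ids.tolist()
    return d


def community_from_dict(d: dict) -> Community:
    return Community(
        GuildState(np.array(d["animals"]["traits"], dtype=float),
                   np.array(d["animals"]["densities"], dtype=float)),
        GuildState(np.array(d["plants"]["traits"], dtype=float),
                   np.array(d["plants"]["densities"], dtype=float)),
        ModelParams.from_dict(d["params"]),
        d.get("alien_index"), d.get("alien_sigma_m"),
        np.array(d["animal_ids"]) if "animal_ids" in d else None,
        np.array(d["plant_ids"]) if "plant_ids" in d else None)


def save_community(community: Community, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(community_to_dict(community), indent=2))


def load_community(path: Union[str, Path]) -> Community:
    return community_from_dict(json.loads(Path(path).read_text()))


def matrix_to_csv(Q: Union[np.ndarray, InteractionMatrix],
                  path: Union[str, Path]) -> None:
    """Write Q with row headers A<i> (animals) and column headers P<j>."""
    if isinstance(Q, InteractionMatrix):
        Q = Q.Q
    n, m = Q.shape
    df = pd.DataFrame(Q, index=[f"A{i}" for i in range(n)],
                      columns=[f"P{j}" for j in range(m)])
    df.to_csv(path)


def matrix_from_csv(path: Union[str, Path]) -> InteractionMatrix:
    df = pd.read_csv(path, index_col=0)
    return InteractionMatrix(df.to_numpy(dtype=float))


def edge_list(Q: Union[np.ndarray, InteractionMatrix]) -> pd.DataFrame:
    """Sparse edge list (animal, plant, q) of the nonzero interactions."""
    if isinstance(Q, InteractionMatrix):
        Q = Q.Q
    rows, cols = np.nonzero(Q)
    return pd.DataFrame({"animal": [f"A{i}" for i in rows],
                         "plant": [f"P{j}" for j in cols],
                         "q": Q[rows, cols]})


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """Long-format (time, morph_id, guild, density) table of a recorded
    integration."""
    records = []
    n = traj.animal_densities.shape[1]
    m = traj.plant_densities.shape[1]
    for k, t in enumerate(traj.times):
        for i in range(n):
            records.append((t, i, "animal", traj.animal_densities[k, i]))
        for j in range(m):
            records.append((t, j, "plant", traj.plant_densities[k, j]))
    return pd.DataFrame(records,
                        columns=["time", "morph_id", "guild", "density"])


def assembly_log_to_dict(log: AssemblyLog) -> dict:
    return {
        "params": log.params.to_dict(),
        "seed": log.seed,
        "n_events": log.n_events,
        "converged": log.converged,
        "events": [{"time": e.time, "guild": e.guild,
                    "parent_id": e.parent_id,
                    "parent_trait": e.parent_trait,
                    "daughter_id": e.daughter_id,
                    "daughter_trait": e.daughter_trait}
                   for e in log.events],
        "final_community": community_to_dict(log.final_community),
    }


def save_assembly_log(log: AssemblyLog, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(assembly_log_to_dict(log), indent=2))


def trait_trajectory_frame(log: AssemblyLog) -> pd.DataFrame:
    """Long-format (time, morph_id, guild, trait) table of the recorded
    evolutionary trees (requires ``assemble_network(record=True)``)."""
    records = []
    for t, ids_a, xs, ids_p, ys in log.trajectory:
        for i, x in zip(ids_a, xs):
            records.append((t, int(i), "animal", float(x)))
        for j, y in zip(ids_p, ys):
            records.append((t, int(j), "plant", float(y)))
    return pd.DataFrame(records,
                        columns=["time", "morph_id", "guild", "trait"])
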
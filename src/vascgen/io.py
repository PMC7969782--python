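"""Serialisation of vascular forests.

The interchange format is a flat parent-pointer table (CSV or JSON), one
row per vessel: trivially expressive enough for N-ary trees, unary chains
and imported anatomical trees without a bespoke parser.  A legacy ASCII
VTK polydata export carries radius, flow, stage and bifurcation level as
per-cell attributes for rendering in ParaView and friends.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import tree as T

_COLUMNS = [
    "id", "parent",
    "xp_x", "xp_y", "xp_z", "xd_x", "xd_y", "xd_z",
    "radius", "flow", "role", "behaviour", "stage", "level",
    "outlet_fraction", "root_inflow",
]


def forest_to_table(forest: T.VascularForest) -> pd.DataFrame:
    """Flatten a forest into the interchange table."""
    n = forest.n
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "parent": forest.parent[:n],
            "xp_x": forest.xp[:n, 0], "xp_y": forest.xp[:n, 1], "xp_z": forest.xp[:n, 2],
            "xd_x": forest.xd[:n, 0], "xd_y": forest.xd[:n, 1], "xd_z": forest.xd[:n, 2],
            "radius": forest.radius[:n],
            "flow": forest.flow[:n],
            "role": [T.ROLE_NAMES[int(r)] for r in forest.role[:n]],
            "behaviour": [T.BEHAVIOUR_NAMES[int(b)] for b in forest.behaviour[:n]],
            "stage": forest.stage[:n],
            "level": forest.level[:n],
            "outlet_fraction": forest.outlet_fraction[:n],
            "root_inflow": [forest.root_inflow.get(i, 0.0) for i in range(n)],
        }
    )
    return df[_COLUMNS]


def table_to_forest(df: pd.DataFrame) -> T.VascularForest:
    """Rebuild a forest from an interchange table (inverse of forest_to_table).

    Vessel ids become the forest indices (after rank-mapping non-contiguous
    ids), so a write/read cycle reproduces the table exactly.
    """
    ids = df["id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise ValueError("duplicate vessel ids in table")
    order = np.argsort(ids, kind="stable")
    rank = {int(ids[i]): int(np.searchsorted(ids[order], ids[i])) for i in range(len(ids))}
    known = set(rank)
    for r in df.itertuples(index=False):
        if int(r.parent) >= 0 and int(r.parent) not in known:
            raise ValueError(f"vessel {int(r.id)}: parent id {int(r.parent)} not in table")

    n = len(df)
    forest = T.VascularForest(capacity=max(n, 8))
    forest.n = n
    forest._version += 1
    forest.children = [[] for _ in range(n)]
    for r in df.itertuples(index=False):
        i = rank[int(r.id)]
        forest.xp[i] = (r.xp_x, r.xp_y, r.xp_z)
        forest.xd[i] = (r.xd_x, r.xd_y, r.xd_z)
        forest.length[i] = float(np.linalg.norm(forest.xd[i] - forest.xp[i]))
        forest.radius[i] = float(r.radius)
        forest.flow[i] = float(r.flow)
        forest.role[i] = T.ROLE_CODES[str(r.role)]
        forest.behaviour[i] = T.BEHAVIOUR_CODES[str(r.behaviour)]
        forest.stage[i] = int(r.stage)
        forest.outlet_fraction[i] = float(r.outlet_fraction)
        forest.beta[i] = 1.0
        p = int(r.parent)
        forest.parent[i] = rank[p] if p >= 0 else -1
        if p < 0:
            forest.roots.append(i)
            forest.root_inflow[i] = float(r.root_inflow)
    for i in range(n):
        p = int(forest.parent[i])
        if p >= 0:
            forest.children[p].append(i)
    for r in forest.roots:
        forest._refresh_subtree_meta(r)
    reached = sum(len(forest.subtree(r)) for r in forest.roots)
    if reached != n:
        raise ValueError("table contains vessels unreachable from any root")
    forest.validate()
    return forest


def write_tree(forest: T.VascularForest, path, fmt: str | None = None):
    """Write a forest as CSV, JSON or legacy VTK polydata, chosen by suffix."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    df = forest_to_table(forest)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1))
    elif fmt == "vtk":
        path.write_text(to_vtk(forest))
    else:
        raise ValueError(f"unknown tree format {fmt!r}")


def read_tree(path, fmt: str | None = None) -> T.VascularForest:
    """Read an interchange table back into a forest."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        raise ValueError(f"unknown tree format {fmt!r}")
    return table_to_forest(df)


def to_vtk(forest: T.VascularForest) -> str:
    """Legacy ASCII VTK polydata: one 2-point line cell per vessel segment.

    Unary chains come out as geometrically connected consecutive cells,
    each carrying its own radius/flow attributes.
    """
    n = forest.n
    lines = [
        "# vtk DataFile Version 3.0",
        "vascgen vascular forest",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {2 * n} double",
    ]
    for i in range(n):
        lines.append(" ".join(f"{v:.12g}" for v in forest.xp[i]))
        lines.append(" ".join(f"{v:.12g}" for v in forest.xd[i]))
    lines.append(f"LINES {n} {3 * n}")
    for i in range(n):
        lines.append(f"2 {2 * i} {2 * i + 1}")
    lines.append(f"CELL_DATA {n}")
    for name, arr in (
        ("radius", forest.radius[:n]),
        ("flow", forest.flow[:n]),
        ("stage", forest.stage[:n]),
        ("level", forest.level[:n]),
    ):
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{float(v):.12g}" for v in arr)
    return "\n".join(lines) + "\n"
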
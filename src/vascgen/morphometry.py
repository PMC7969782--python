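"""Morphometric summaries of generated forests.

Per-stage (and per-initial-branch) radius distributions, terminal counts,
total intravascular volume and bifurcation-level histograms — the numbers
one compares against ex-vivo morphometry.  A histogram of log-radius is
used to flag multimodality descriptively: stages that both transport
blood onward and terminate locally show a large-radius mode next to the
terminal mode.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import costs as C
from . import tree as T


def _group_keys(forest: T.VascularForest, grouping: str) -> np.ndarray:
    n = forest.n
    if grouping == "stage":
        return forest.stage[:n].copy()
    if grouping == "branch":
        # ancestor among the children of the initial (stage 0) roots
        keys = np.full(n, -1, dtype=np.int64)
        for r in forest.roots:
            for b in forest.children[r]:
                for k in forest.subtree(b):
                    keys[k] = b
            keys[r] = r
        return keys
    raise ValueError(f"unknown grouping {grouping!r}")


def _flag_multimodal(radii: np.ndarray, bins: int = 24) -> bool:
    """Descriptive: does the log-radius histogram show >1 separated mode?"""
    if len(radii) < 10:
        return False
    h, _ = np.histogram(np.log(radii), bins=bins)
    peaks = 0
    in_gap = True
    thr = max(1, int(0.05 * h.max()))
    for v in h:
        if v > thr and in_gap:
            peaks += 1
            in_gap = False
        elif v <= thr:
            in_gap = True
    return peaks > 1


def morphometry_report(forest: T.VascularForest, grouping: str = "stage") -> pd.DataFrame:
    """Summary table with one row per group plus a 'total' row."""
    n = forest.n
    keys = _group_keys(forest, grouping)
    term = np.zeros(n, dtype=bool)
    term[forest.terminals()] = True

    rows = []
    for g in sorted(set(keys.tolist())):
        sel = keys == g
        r = forest.radius[:n][sel]
        rows.append({
            grouping: g,
            "n_vessels": int(sel.sum()),
            "n_terminals": int((sel & term).sum()),
            "radius_min": float(r.min()),
            "radius_mean": float(r.mean()),
            "radius_max": float(r.max()),
            "length_total": float(forest.length[:n][sel].sum()),
            "volume": float(np.sum(forest.length[:n][sel] * np.pi * r**2)),
            "level_max": int(forest.level[:n][sel].max()),
            "multimodal_radius": _flag_multimodal(r),
        })
    total = {
        grouping: "total",
        "n_vessels": n,
        "n_terminals": int(term.sum()),
        "radius_min": float(forest.radius[:n].min()),
        "radius_mean": float(forest.radius[:n].mean()),
        "radius_max": float(forest.radius[:n].max()),
        "length_total": float(forest.length[:n].sum()),
        "volume": C.tree_volume(forest),
        "level_max": int(forest.level[:n].max()),
        "multimodal_radius": _flag_multimodal(forest.radius[:n]),
    }
    rows.append(total)
    return pd.DataFrame(rows)


def level_histogram(forest: T.VascularForest) -> pd.Series:
    """Vessel count per bifurcation level."""
    n = forest.n
    counts = np.bincount(forest.level[:n])
    return pd.Series(counts, index=pd.RangeIndex(len(counts), name="level"), name="n_vessels")


def plot_radius_distributions(forest: T.VascularForest, path, grouping: str = "stage"):
    """Violin-style per-group radius distribution plot (written to ``path``)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = forest.n
    keys = _group_keys(forest, grouping)
    groups = sorted(set(keys.tolist()))
    data = [forest.radius[:n][keys == g] for g in groups]
    fig, ax = plt.subplots(figsize=(1.5 * len(groups) + 2, 4))
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(groups) + 1), [str(g) for g in groups])
    ax.set_xlabel(grouping)
    ax.set_ylabel("radius (mm)")
    ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
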
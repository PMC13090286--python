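"""Snapshot readers and writers.

Layout per snapshot directory::

    snap_<i>/trees.nwk   one Newick string per line: the collapsed observed
                         tree of each contributing founder (branch lengths
                         are durations; leaf labels are cell ids)
    snap_<i>/cells.tsv   cell_id, tree_id, m_tilde, m_true, x_1..x_g
    snap_<i>/meta.json   time, K (trees with >= 1 observed cell), q, seed

Exported trees are what an experimenter reconstructs: death branches and
one-sided divisions are pruned, so the trees are full binary on the observed
leaves and leaf depth equals m̃.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .measures import WeightedPointCloud
from .simulate import (DIVISION, SAMPLED, LineageNode, LineageTree,
                       ObservedCell, Snapshot, collapse_observed)

__all__ = ["write_snapshot", "read_snapshot", "write_timecourse",
           "read_timecourse", "write_cloud", "read_cloud"]


def _tree_to_newick(tree: LineageTree, leaf_map: dict[int, int]) -> str:
    def render(nid: int) -> str:
        node = tree.nodes[nid]
        length = node.end_time - node.birth_time
        if node.children is None:
            return f"c{leaf_map[nid]}:{length:.9f}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}):{length:.9f}"

    return render(tree.root) + ";"


def write_snapshot(snapshot: Snapshot, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines, rows = [], []
    tree_out_index = {}
    for k, tree in enumerate(snapshot.trees):
        col = collapse_observed(tree)
        if col is None:
            continue
        ctree, leaf_map = col
        tree_out_index[k] = len(lines)
        lines.append(_tree_to_newick(ctree, {cid: oid for cid, oid in leaf_map.items()}))
    (directory / "trees.nwk").write_text("\n".join(lines) + ("\n" if lines else ""))
    g = snapshot.states().shape[1] if snapshot.observed_cells else 0
    for c in snapshot.observed_cells:
        row = {"cell_id": f"c{c.node_id}", "tree_id": tree_out_index[c.tree_index],
               "m_tilde": c.m_tilde, "m_true": c.m_true}
        for j in range(g):
            row[f"x_{j + 1}"] = c.state[j]
        rows.append(row)
    pd.DataFrame(rows).to_csv(directory / "cells.tsv", sep="\t", index=False)
    meta = {"time": snapshot.time, "K": snapshot.n_observed_trees, "q": snapshot.q}
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))
    return directory


def _newick_to_tree(newick: str, t_sample: float) -> tuple[LineageTree, dict[int, str]]:
    dt = dendropy.Tree.get(data=newick, schema="newick",
                           suppress_internal_node_taxa=True)
    nodes: list[LineageNode] = []
    labels: dict[int, str] = {}

    def build(dnode, start_time: float, parent: int | None) -> int:
        length = float(dnode.edge.length or 0.0)
        nid = len(nodes)
        node = LineageNode(id=nid, parent=parent, birth_time=start_time,
                           end_time=start_time + length)
        nodes.append(node)
        kids = dnode.child_nodes()
        if kids:
            if len(kids) != 2:
                raise ValueError("observed lineage trees must be binary")
            node.end_event = DIVISION
            node.children = tuple(build(c, node.end_time, nid) for c in kids)
        else:
            node.end_event = SAMPLED
            node.observed = True
            labels[nid] = dnode.taxon.label if dnode.taxon else dnode.label
        return nid

    root = build(dt.seed_node, t_sample, None)
    # shift so leaves sit at t_sample (newick stores durations from the root)
    depth = max(n.end_time for n in nodes)
    shift = t_sample - depth
    for n in nodes:
        n.birth_time += shift
        n.end_time += shift
    return LineageTree(nodes=nodes, root=root, t0=nodes[root].birth_time,
                       t_sample=t_sample), labels


def read_snapshot(directory: str | Path) -> Snapshot:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    t = float(meta["time"])
    text = (directory / "trees.nwk").read_text().strip()
    trees, label_maps = [], []
    for line in (text.splitlines() if text else []):
        tree, labels = _newick_to_tree(line.strip(), t)
        trees.append(tree)
        label_maps.append({lbl: nid for nid, lbl in labels.items()})
    df = pd.read_csv(directory / "cells.tsv", sep="\t")
    xcols = [c for c in df.columns if c.startswith("x_")]
    cells = []
    for _, row in df.iterrows():
        k = int(row["tree_id"])
        cid = str(row["cell_id"])
        if k >= len(trees) or cid not in label_maps[k]:
            raise ValueError(f"cells.tsv references unknown leaf {cid!r} "
                             f"in tree {k}")
        nid = label_maps[k][cid]
        state = row[xcols].to_numpy(dtype=float)
        trees[k].nodes[nid].state_at_end = state
        cells.append(ObservedCell(tree_index=k, node_id=nid, state=state,
                                  m_tilde=int(row["m_tilde"]),
                                  m_true=int(row["m_true"])))
    return Snapshot(time=t, trees=trees, observed_cells=cells,
                    q=float(meta.get("q", 1.0)))


def write_timecourse(snapshots: list[Snapshot], directory: str | Path) -> Path:
    directory = Path(directory)
    for i, s in enumerate(snapshots):
        write_snapshot(s, directory / f"snap_{i}")
    return directory


def read_timecourse(directory: str | Path) -> list[Snapshot]:
    directory = Path(directory)
    dirs = sorted(directory.glob("snap_*"), key=lambda p: int(p.name.split("_")[1]))
    if not dirs:
        raise FileNotFoundError(f"no snap_<i> directories under {directory}")
    return [read_snapshot(d) for d in dirs]


def write_cloud(cloud: WeightedPointCloud, path: str | Path) -> Path:
    path = Path(path)
    g = cloud.points.shape[1]
    df = pd.DataFrame(cloud.points, columns=[f"x_{j + 1}" for j in range(g)])
    df["weight"] = cloud.weights
    df.to_csv(path, sep="\t", index=False)
    return path


def read_cloud(path: str | Path, time: float | None = None) -> WeightedPointCloud:
    df = pd.read_csv(path, sep="\t")
    xcols = [c for c in df.columns if c.startswith("x_")]
    return WeightedPointCloud(df[xcols].to_numpy(dtype=float),
                              df["weight"].to_numpy(dtype=float), time=time)
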
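"""Binarized expression on the lineage and in 3D: stripe clustering
along the anterior-posterior axis and lineage-diagram rendering.

Once the differential test has given each gene a binary on/off profile
over a stage's cell states, the profile can be pushed down to single
cells (every member cell of a state inherits its call), mapped onto 3D
cell positions, and the cells of one founder lineage clustered by their
binary gene-combination codes. Clusters are relabeled 1..k by ascending
mean anterior-posterior coordinate (+x = posterior), so each cluster is
a "stripe" with a gene-combination signature (genes on in at least half
of its members).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .diffexp import BinaryCallSet
from .lineage import LineageTree


def binarize_on_lineage(
    calls: BinaryCallSet,
    genes: list[str],
    state_of_cell: pd.Series,
) -> pd.DataFrame:
    """Genes x cells binary matrix: each cell inherits the on/off call of
    its assigned state (members of an equivalence group share values).

    ``state_of_cell`` maps cell id -> state name as used in ``calls``.
    A gene without a significant call at the stage raises with the list
    of available genes.
    """
    mat = calls.binary_matrix(genes)  # raises for uncalled genes
    cells = state_of_cell.index
    out = pd.DataFrame(0, index=list(genes), columns=list(cells), dtype=int)
    for cell in cells:
        state = state_of_cell[cell]
        if state not in mat.columns:
            raise KeyError(
                f"cell {cell!r} is assigned state {state!r} which is not "
                f"among the called states {list(mat.columns)}"
            )
        out[cell] = mat[state].to_numpy()
    return out


@dataclass
class StripeMap:
    """Stripe decomposition of one founder lineage at one stage."""

    stage: int
    lineage: str
    cells: pd.DataFrame        # cell, cluster, x, y, z, code
    signatures: pd.DataFrame   # cluster, mean_x, genes (semicolon-joined)
    padded: bool = False       # True if k exceeded the distinct patterns

    def write(self, cells_path, signatures_path) -> None:
        self.cells.to_csv(cells_path, sep="\t", index=False)
        self.signatures.to_csv(signatures_path, sep="\t", index=False)


def stripe_cluster(
    binary: pd.DataFrame,
    positions: pd.DataFrame,
    stage: int,
    lineage: str = "AB",
    k: int = 8,
    seed: int = 0,
) -> StripeMap:
    """k-means the cells of one lineage by their binary expression codes.

    Distances are Euclidean on the raw 0/1 vectors (monotone in Hamming
    distance). If the cells carry fewer than ``k`` distinct codes, the
    code classes are used as clusters and the largest classes are split
    along the anterior-posterior axis until ``k`` clusters exist
    (``padded`` flags this). Cluster labels are 1..k ordered by
    ascending mean x; the signature of a stripe is the set of genes on
    in at least half of its member cells.
    """
    cells = list(binary.columns)
    pos = positions.set_index("cell").loc[cells]
    X = binary.T.to_numpy(dtype=float)  # cells x genes
    n = len(cells)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} cells of lineage {lineage}")

    codes = ["".join(map(str, row)) for row in binary.T.to_numpy()]
    n_patterns = len(set(codes))
    padded = False
    if n_patterns < k:
        padded = True
        warnings.warn(
            f"only {n_patterns} distinct binary patterns for k={k}; padding "
            "by splitting the largest pattern along the A-P axis",
            stacklevel=2,
        )
        groups = {c: [i for i, cd in enumerate(codes) if cd == c]
                  for c in sorted(set(codes))}
        clusters = list(groups.values())
        while len(clusters) < k:
            clusters.sort(key=len, reverse=True)
            big = clusters.pop(0)
            if len(big) < 2:
                clusters.append(big)
                break
            order = sorted(big, key=lambda i: pos["x"].iloc[i])
            half = len(order) // 2
            clusters.extend([order[:half], order[half:]])
        labels = np.empty(n, dtype=int)
        for lab, members in enumerate(clusters):
            labels[members] = lab
    else:
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(X)

    # relabel by ascending mean anterior-posterior coordinate
    mean_x = {lab: pos["x"].to_numpy()[labels == lab].mean()
              for lab in np.unique(labels)}
    order = sorted(mean_x, key=lambda lab: (mean_x[lab], lab))
    relabel = {old: i + 1 for i, old in enumerate(order)}
    stripe = np.array([relabel[l] for l in labels])

    cells_df = pd.DataFrame({
        "cell": cells, "cluster": stripe,
        "x": pos["x"].to_numpy(), "y": pos["y"].to_numpy(),
        "z": pos["z"].to_numpy(), "code": codes,
    }).sort_values(["cluster", "cell"]).reset_index(drop=True)

    sig_rows = []
    for lab in sorted(set(stripe)):
        members = binary.loc[:, np.array(cells)[stripe == lab]]
        on = members.mean(axis=1) >= 0.5
        sig_rows.append({
            "cluster": lab,
            "mean_x": float(np.mean([mean_x[o] for o, nw in relabel.items()
                                     if nw == lab])),
            "genes": ";".join(sorted(binary.index[on])),
        })
    return StripeMap(
        stage=stage, lineage=lineage, cells=cells_df,
        signatures=pd.DataFrame(sig_rows), padded=padded,
    )


# ----------------------------------------------------------------------
# lineage-diagram rendering
# ----------------------------------------------------------------------

def render_lineage_pattern(
    binary: pd.DataFrame,
    stage: int,
    tree: LineageTree | None = None,
) -> dict:
    """Serializable lineage-diagram data: for each gene, the on/off call
    of every branch (cell) of the stage, plus the parent edges needed to
    draw the tree down to the stage's cells. Round-trips losslessly via
    :func:`parse_lineage_pattern`."""
    tree = tree or LineageTree.default()
    edges = []
    seen = set()
    for cell in sorted(binary.columns):
        child = cell
        while child != tree.root and child not in seen:
            parent = tree.parent_of(child)
            edges.append([parent, child])
            seen.add(child)
            child = parent
    return {
        "stage": int(stage),
        "cells": sorted(binary.columns),
        "edges": sorted(edges),
        "genes": {
            g: {c: int(binary.loc[g, c]) for c in binary.columns}
            for g in binary.index
        },
    }


def parse_lineage_pattern(data: dict) -> pd.DataFrame:
    """Recover the genes x cells binary matrix from rendered data."""
    genes = sorted(data["genes"])
    cells = data["cells"]
    out = pd.DataFrame(
        [[data["genes"][g][c] for c in cells] for g in genes],
        index=genes, columns=cells, dtype=int,
    )
    return out


def lineage_pattern_json(data: dict) -> str:
    return json.dumps(data, indent=1, sort_keys=True)


def plot_lineage_pattern(data: dict, gene: str, ax=None):
    """Draw one gene's on/off pattern as a lineage tree (thick = on).

    Requires matplotlib; provided for interactive use, nothing in the
    pipeline depends on it.
    """
    import matplotlib.pyplot as plt

    tree = LineageTree.default()
    cells = data["cells"]
    xs = {c: i for i, c in enumerate(sorted(cells))}
    # walk up from leaves to place internal nodes at the mean x of leaves
    depth = {c: len(tree.ancestors(c)) for c in cells}
    maxd = max(depth.values())
    nodes = {c: (xs[c], 0) for c in cells}
    for parent, child in sorted(data["edges"], key=lambda e: -len(e[1])):
        if parent not in nodes:
            kids = [n for p, n in data["edges"] if p == parent and n in nodes]
            if kids:
                nodes[parent] = (
                    float(np.mean([nodes[k][0] for k in kids])),
                    max(nodes[k][1] for k in kids) + 1,
                )
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    on_cells = {c for c, v in data["genes"][gene].items() if v}
    for parent, child in data["edges"]:
        if parent not in nodes or child not in nodes:
            continue
        (x0, y0), (x1, y1) = nodes[parent], nodes[child]
        thick = child in on_cells or (child not in cells and False)
        ax.plot([x0, x1], [y0, y1], lw=3 if thick else 0.8, color="k")
    ax.set_title(f"{gene} ({data['stage']}-cell stage)")
    ax.set_yticks([]); ax.set_xticks([])
    return ax
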
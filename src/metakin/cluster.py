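"""Hierarchical clustering of kinetic signatures into shape templates.

Signatures are compared by Euclidean distance between their curves —
relative (%) curves by default, since on absolute concentrations a
mM-scale analyte like glucose would dominate every distance — and merged
by agglomerative complete linkage.  Cutting the tree (default height 35,
in percentage-point units) yields metabolite clusters whose pointwise
median relative curves are the kinetic shape templates, each labelled
with its response pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .kinetics import KineticSignature, classify_kinetic_pattern

DEFAULT_CUT_HEIGHT = 35.0
DEFAULT_LINKAGE = "complete"
MODES = ("relative", "absolute", "row_scaled")


@dataclass(frozen=True)
class LinkageTree:
    """Agglomerative merge sequence over a metabolite panel."""

    merges: np.ndarray  # scipy linkage matrix, (n-1, 4)
    labels: tuple[str, ...]
    metric: str
    method: str

    @property
    def leaf_order(self) -> list[str]:
        if len(self.labels) == 1:
            return list(self.labels)
        return [self.labels[i] for i in leaves_list(self.merges)]


@dataclass(frozen=True)
class ShapeTemplate:
    """A cluster's median relative curve with its kinetic-pattern label."""

    cluster_id: int
    members: tuple[str, ...]
    positions: np.ndarray
    curve: np.ndarray  # median relative (%) curve
    pattern: str


def _signature_matrix(signatures: list[KineticSignature], mode: str) -> np.ndarray:
    grids = {tuple(np.round(s.positions, 9)) for s in signatures}
    if len(grids) != 1:
        raise ValueError("signatures are on mismatched grids")
    if mode == "relative":
        mat = np.vstack([s.relative for s in signatures])
    elif mode == "absolute":
        mat = np.vstack([s.fitted for s in signatures])
    elif mode == "row_scaled":
        mat = np.vstack([s.relative for s in signatures])
        mat = _scale_rows(mat)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    return mat


def _scale_rows(mat: np.ndarray) -> np.ndarray:
    """Center/scale each row to mean 0, sd 1; zero-variance rows stay 0."""
    centered = mat - mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sd > 0, centered / sd, 0.0)
    return scaled


def signature_distance_matrix(
    signatures: list[KineticSignature], mode: str = "relative"
) -> pd.DataFrame:
    """Symmetric Euclidean distance matrix between signature curves."""
    mat = _signature_matrix(signatures, mode)
    diff = mat[:, None, :] - mat[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    labels = [s.metabolite for s in signatures]
    return pd.DataFrame(dist, index=labels, columns=labels)


def hierarchical_cluster(distances: pd.DataFrame, method: str = DEFAULT_LINKAGE) -> LinkageTree:
    """Agglomerative clustering of a precomputed distance matrix.

    Deterministic for a fixed input order; merge ties are resolved by
    the lowest-index pair (scipy's ordering).  A single metabolite
    yields a trivial tree with no merges.
    """
    labels = tuple(distances.index)
    if len(labels) == 1:
        return LinkageTree(np.empty((0, 4)), labels, "euclidean", method)
    condensed = squareform(distances.to_numpy(), checks=False)
    merges = linkage(condensed, method=method)
    return LinkageTree(merges, labels, "euclidean", method)


def cut_tree(tree: LinkageTree, height: float = DEFAULT_CUT_HEIGHT) -> pd.Series:
    """Flat cluster assignment after removing merges above ``height``.

    Cluster ids are contiguous from 1, numbered by the first member in
    dendrogram leaf order.  Returns a Series metabolite -> cluster id.
    """
    if len(tree.labels) == 1:
        return pd.Series([1], index=list(tree.labels), name="cluster")
    raw = fcluster(tree.merges, t=height, criterion="distance")
    assign = pd.Series(raw, index=list(tree.labels), name="cluster")
    renumber: dict[int, int] = {}
    for leaf in tree.leaf_order:
        rid = assign[leaf]
        if rid not in renumber:
            renumber[rid] = len(renumber) + 1
    return assign.map(renumber).rename("cluster")


def derive_templates(
    assignment: pd.Series, signatures: list[KineticSignature]
) -> list[ShapeTemplate]:
    """Median relative curve of each cluster, labelled by response pattern."""
    by_name = {s.metabolite: s for s in signatures}
    missing = set(by_name) - set(assignment.index)
    if missing:
        raise ValueError(f"assignment does not cover: {sorted(missing)}")
    templates = []
    for cid in sorted(assignment.unique()):
        members = tuple(assignment.index[assignment == cid])
        stack = np.vstack([by_name[m].relative for m in members])
        curve = np.median(stack, axis=0)
        positions = by_name[members[0]].positions
        templates.append(
            ShapeTemplate(
                cluster_id=int(cid),
                members=members,
                positions=positions,
                curve=curve,
                pattern=classify_kinetic_pattern(curve, positions),
            )
        )
    return templates


def heatmap_export(
    signatures: list[KineticSignature], tree: LinkageTree, mode: str = "relative"
) -> pd.DataFrame:
    """Row-scaled signature matrix in dendrogram leaf order (display only).

    Each metabolite's curve is centered and scaled to mean 0 / sd 1
    (zero-variance rows left at 0).  Never feeds back into clustering.
    """
    mat = _signature_matrix(signatures, mode)
    scaled = _scale_rows(mat)
    labels = [s.metabolite for s in signatures]
    frame = pd.DataFrame(scaled, index=labels, columns=signatures[0].positions)
    return frame.loc[tree.leaf_order]


def tree_to_dict(tree: LinkageTree) -> dict:
    """JSON-serialisable merge list plus leaf order (for dendrogram export)."""
    return {
        "labels": list(tree.labels),
        "metric": tree.metric,
        "method": tree.method,
        "merges": [
            {"left": int(a), "right": int(b), "height": float(h), "size": int(n)}
            for a, b, h, n in tree.merges
        ],
        "leaf_order": tree.leaf_order,
    }


def dendrogram_segments(tree: LinkageTree):
    """Coordinates for plotting, via scipy's dendrogram layout."""
    return dendrogram(tree.merges, labels=list(tree.labels), no_plot=True)
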
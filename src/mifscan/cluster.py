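"""Epograms, heatmaps and conservation color maps.

An *epogram* is a dendrogram of proteins built from interaction-field
distances d = sqrt(2 − 2·SI), by analogy to a phylogram: agglomerative
clustering (UPGMA by default) on the distance matrix, with merge heights
d/2 so the tree is ultrametric under average linkage. Ties are broken by
merging the pair whose lexicographically smallest leaf labels come first,
which makes the tree deterministic and invariant to input ordering.

The linkage is implemented directly (naive O(n³), fine for protein-family
sizes) so the tie-break rule is explicit; tests cross-check cophenetic
structure against scipy's average linkage. Trees serialize to Newick with
branch lengths equal to height differences; heatmaps and color tables are
emitted as TSV, with PNG rendering as a convenience.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compare import ConservationProfile, SimilarityMatrix
from .errors import FlaggedEntriesError, MifScanError

LINKAGES = ("average", "single", "complete")


@dataclass
class _Node:
    height: float
    label: str | None = None
    children: tuple = ()

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [l for c in self.children for l in c.leaves()]


@dataclass
class Epogram:
    """Ultrametric clustering tree over a protein set.

    ``linkage_matrix`` is scipy-format (merge distances = inter-cluster d);
    node heights on the tree itself are d/2.
    """

    labels: list[str]
    root: _Node
    linkage_matrix: np.ndarray
    linkage: str = "average"

    def __post_init__(self):
        leaves = self.root.leaves()
        if sorted(leaves) != sorted(self.labels) or len(set(leaves)) != len(leaves):
            raise MifScanError("epogram leaves must be the matrix labels, once each")
        self._check_heights(self.root)

    def _check_heights(self, node: _Node) -> None:
        for child in node.children:
            if child.height > node.height + 1e-12:
                raise MifScanError("merge heights must be non-decreasing to the root")
            self._check_heights(child)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def root_height(self) -> float:
        return self.root.height

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf order of the tree traversal."""
        return self.root.leaves()

    def to_newick(self) -> str:
        def render(node: _Node, parent_height: float) -> str:
            blen = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{blen:.10g}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{blen:.10g}"

        if self.root.is_leaf:
            return f"{self.root.label}:0;"
        inner = ",".join(render(c, self.root.height) for c in self.root.children)
        return f"({inner});"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def cut(self, k: int) -> dict[str, int]:
        """Cluster assignment (label → 1..k) from cutting the tree at k clusters."""
        from scipy.cluster.hierarchy import fcluster

        flat = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, flat)}

    def cophenetic(self) -> np.ndarray:
        """Pairwise cophenetic distances (2 × merge height), label order."""
        n = self.n_leaves
        index = {lab: i for i, lab in enumerate(self.labels)}
        out = np.zeros((n, n))

        def walk(node: _Node) -> list[str]:
            if node.is_leaf:
                return [node.label]
            groups = [walk(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            ia, ib = index[a], index[b]
                            out[ia, ib] = out[ib, ia] = 2.0 * node.height
            return [l for g in groups for l in g]

        walk(self.root)
        return out


def build_epogram(matrix: SimilarityMatrix, linkage: str = "average") -> Epogram:
    """Agglomerative clustering of a similarity matrix in distance space.

    Requires a fully defined matrix (no flagged entries) with at least two
    leaves. Merge heights are half the inter-cluster distance; equal-distance
    candidates are resolved by the lexicographically smallest pair of cluster
    representative labels.
    """
    if linkage not in LINKAGES:
        raise MifScanError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if not matrix.fully_defined:
        raise FlaggedEntriesError(
            "similarity matrix contains undefined entries; impute or exclude the "
            "affected proteins before clustering"
        )
    n = matrix.n
    if n < 2:
        raise MifScanError("need at least two proteins to build an epogram")

    d = matrix.distance()
    labels = list(matrix.labels)

    # active cluster state keyed by scipy-style ids (leaves 0..n-1)
    nodes = {i: _Node(height=0.0, label=labels[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    reps = {i: labels[i] for i in range(n)}  # lexicographically smallest leaf
    dist = {(i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)}

    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for (i, j), dij in dist.items():
            key = (dij,) + tuple(sorted((reps[i], reps[j])))
            if best is None or key < best[0]:
                best = (key, i, j, dij)
        _, i, j, dij = best
        new = _Node(height=dij / 2.0, children=(nodes[i], nodes[j]))
        Z[step] = (min(i, j), max(i, j), dij, sizes[i] + sizes[j])

        others = [k for k in nodes if k not in (i, j)]
        for k in others:
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            if linkage == "average":
                dnew = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            elif linkage == "single":
                dnew = min(dik, djk)
            else:
                dnew = max(dik, djk)
            dist[tuple(sorted((next_id, k)))] = dnew
        for k in (i, j):
            for other in list(dist):
                if k in other:
                    del dist[other]
        nodes[next_id] = new
        sizes[next_id] = sizes[i] + sizes[j]
        reps[next_id] = min(reps[i], reps[j])
        del nodes[i], nodes[j], sizes[i], sizes[j], reps[i], reps[j]
        next_id += 1

    root = nodes[next_id - 1]
    return Epogram(labels=labels, root=root, linkage_matrix=Z, linkage=linkage)


def heatmap(
    matrix: SimilarityMatrix,
    order: Epogram,
    tsv_path=None,
    png_path=None,
) -> pd.DataFrame:
    """Distance matrix permuted to the epogram's leaf order.

    Writes the ordered matrix as TSV and, optionally, a PNG with the
    conventional diverging color code: red at d=0 (identical) through white
    to blue at d=2 (dissimilar). The TSV is the tested artifact; the image
    is a convenience.
    """
    if sorted(order.labels) != sorted(matrix.labels):
        raise MifScanError("epogram leaves do not match matrix labels")
    leaf_order = order.leaf_order()
    idx = [matrix.labels.index(lab) for lab in leaf_order]
    dmat = matrix.distance()[np.ix_(idx, idx)]
    df = pd.DataFrame(dmat, index=leaf_order, columns=leaf_order)
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", float_format="%.10g")
    if png_path is not None:
        from matplotlib.figure import Figure

        fig = Figure(figsize=(6, 5))
        ax = fig.add_subplot(111)
        im = ax.imshow(dmat, cmap="RdBu", vmin=0.0, vmax=2.0, interpolation="nearest")
        ax.set_xticks(range(len(leaf_order)))
        ax.set_yticks(range(len(leaf_order)))
        ax.set_xticklabels(leaf_order, rotation=90, fontsize=6)
        ax.set_yticklabels(leaf_order, fontsize=6)
        fig.colorbar(im, ax=ax, label="distance d = sqrt(2 - 2 SI)")
        fig.tight_layout()
        fig.savefig(png_path, dpi=150)
    return df


def _conservation_cmap():
    from matplotlib.colors import LinearSegmentedColormap

    return LinearSegmentedColormap.from_list(
        "conservation", ["blue", "green", "red"]
    )


def color_profile(profile: ConservationProfile, tsv_path=None) -> pd.DataFrame:
    """Per-residue color table: blue (variable) → green → red (conserved).

    Electrostatic scores map the full [−1, 1] range; hydrophobic scores map
    [0, 1] (negative hydrophobic conservation is floored to the variable
    endpoint for coloring only — the profile keeps the raw value). Flagged
    residues, where no similarity index could be computed, are black.
    """
    cmap = _conservation_cmap()
    lo, hi = (-1.0, 1.0) if profile.field_kind == "electrostatic" else (0.0, 1.0)
    rows = []
    for r in range(profile.n_residues):
        if profile.flagged[r]:
            rgb = (0.0, 0.0, 0.0)
            hexcode = "#000000"
        else:
            t = (min(max(profile.scores[r], lo), hi) - lo) / (hi - lo)
            rgba = cmap(float(t))
            rgb = tuple(round(c, 6) for c in rgba[:3])
            hexcode = "#{:02x}{:02x}{:02x}".format(
                *(int(round(255 * c)) for c in rgba[:3])
            )
        rows.append(
            {
                "residue_index": r,
                "score": profile.scores[r],
                "flagged": int(profile.flagged[r]),
                "r": rgb[0],
                "g": rgb[1],
                "b": rgb[2],
                "hex": hexcode,
            }
        )
    df = pd.DataFrame(rows)
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False, float_format="%.10g")
    return df
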
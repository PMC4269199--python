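"""Deterministic agglomerative clustering used for both community dendrograms
and OTU generation.

The engine keeps an explicit inter-cluster distance matrix updated by the
Lance–Williams recurrences (average = UPGMA, single, complete) and breaks
ties on merge distance by the lowest pair of cluster creation indices, so the
same input always yields the same merge sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Dendrogram", "agglomerate", "cut_threshold"]


@dataclass(frozen=True)
class Dendrogram:
    """Result of a full agglomeration over ``n`` leaves.

    ``merges`` holds (left, right, height, size) rows; leaves are numbered
    0..n−1 and the merge created at step k gets index n+k, as in the usual
    linkage-matrix convention.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_linkage(self) -> np.ndarray:
        """Matrix in scipy ``linkage`` layout (for plotting/inspection)."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def cut(self, threshold: float, atol: float = 1e-12) -> list[list[str]]:
        """Flat clusters from merges with height ≤ threshold (plus atol)."""
        return [
            [self.labels[i] for i in members]
            for members in cut_threshold(self.n_leaves, self.merges, threshold, atol)
        ]

    def to_newick(self) -> str:
        """Newick string with ultrametric branch lengths.

        Node heights are half the merge distance (each leaf sits at depth
        d/2 from an ancestor that merged at distance d); branch length is
        the height difference between parent and child.
        """
        n = self.n_leaves
        if n == 1:
            return f"{_quote(self.labels[0])}:0.0;"
        text: dict[int, str] = {i: _quote(self.labels[i]) for i in range(n)}
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        for k, (a, b, h, _size) in enumerate(self.merges):
            node_h = h / 2.0
            la = max(node_h - height[a], 0.0)
            lb = max(node_h - height[b], 0.0)
            idx = n + k
            text[idx] = f"({text[a]}:{la:.6g},{text[b]}:{lb:.6g})"
            height[idx] = node_h
        return text[n + len(self.merges) - 1] + ";"


def _quote(label: str) -> str:
    if any(c in label for c in " ():;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def agglomerate(
    dist: np.ndarray, labels=None, linkage: str = "average"
) -> Dendrogram:
    """Agglomerate a full symmetric distance matrix into a dendrogram.

    ``linkage`` is one of ``average`` (UPGMA), ``single``, ``complete``.
    Among candidate pairs at the minimum distance, the pair with the lowest
    (i, j) cluster indices merges first.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two items to cluster")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if labels is None:
        labels = [str(i) for i in range(n)]
    labels = tuple(str(x) for x in labels)
    if len(labels) != n:
        raise ValueError("labels length mismatch")

    if linkage not in ("average", "single", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")

    # active cluster ids -> position in the working matrix
    ids = list(range(n))
    sizes = {i: 1 for i in range(n)}
    work = d.astype(float).copy()
    np.fill_diagonal(work, np.inf)
    merges: list[tuple[int, int, float, int]] = []
    next_id = n

    for _step in range(n - 1):
        m = len(ids)
        # locate minimum; tie-break by lowest (row, col) position which,
        # because ids stay sorted by creation order, is lowest (i, j) ids
        best = None
        for r in range(m):
            for c in range(r + 1, m):
                v = work[r, c]
                if best is None or v < best[0] - 1e-15:
                    best = (v, r, c)
        assert best is not None
        h, r, c = best
        a, b = ids[r], ids[c]
        na, nb = sizes[a], sizes[b]
        # Lance-Williams update of distances to the merged cluster
        if linkage == "average":
            new_row = (na * work[r] + nb * work[c]) / (na + nb)
        elif linkage == "single":
            new_row = np.minimum(work[r], work[c])
        else:
            new_row = np.maximum(work[r], work[c])
        merges.append((a, b, float(h), na + nb))
        sizes[next_id] = na + nb
        # drop rows/cols r, c; append merged cluster at the end
        keep = [k for k in range(m) if k not in (r, c)]
        new_row = new_row[keep]
        work = work[np.ix_(keep, keep)]
        work = np.pad(work, ((0, 1), (0, 1)), constant_values=np.inf)
        work[-1, :-1] = new_row
        work[:-1, -1] = new_row
        ids = [ids[k] for k in keep] + [next_id]
        next_id += 1

    return Dendrogram(labels=labels, merges=tuple(merges))


def cut_threshold(
    n: int, merges, threshold: float, atol: float = 1e-12
) -> list[list[int]]:
    """Union leaves across all merges with height ≤ threshold + atol.

    Output clusters are ordered by their smallest leaf index, members
    ascending.
    """
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    node_root: dict[int, int] = {i: i for i in range(n)}
    next_id = n
    for a, b, h, _size in merges:
        ra, rb = find(node_root[a]), find(node_root[b])
        if h <= threshold + atol and ra != rb:
            parent[rb] = ra
            members[ra].extend(members.pop(rb))
        # the merged node maps to the representative of its left child so
        # later merges above threshold still resolve membership
        node_root[next_id] = find(ra)
        next_id += 1
    clusters = [sorted(v) for v in members.values()]
    clusters.sort(key=lambda c: c[0])
    return clusters
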
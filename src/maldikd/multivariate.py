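"""Principal component analysis and agglomerative hierarchical clustering.

PCA mean-centers the peak-matrix columns (no scaling by default) and
eigen-decomposes the sample covariance; the full eigenvalue spectrum and
the retained-variance fractions are reported, plus the top-3 scores for
3-D visualization.  Clustering is bottom-up agglomerative with Euclidean
or Hamming distances and single/complete/average linkage, deterministic
through lowest-leaf-index tie-breaking; the same routine clusters samples
(rows) or m/z values (columns).  Results export as reordered TSV heat-map
data plus Newick trees (optionally a Java TreeView CDT/GTR/ATR triplet).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import ConsistencyError, EmptySelectionError, ParameterError
from .matching import PeakMatrix


# --------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    """Eigen-decomposition of the sample covariance of a peak matrix."""

    eigenvectors: np.ndarray  # (n_features, n_components) loadings, descending eigenvalue
    eigenvalues: np.ndarray  # full spectrum, descending, >= 0
    retained_variance: np.ndarray  # eigenvalue_i / sum(eigenvalues)
    scores: np.ndarray  # (n_samples, 3) coordinates on the top 3 components
    labels: list[str]  # condition label per sample


def pca(matrix: PeakMatrix, scale: bool = False) -> PCAResult:
    """PCA of the samples x m/z matrix (binary cells analyzed as 0/1).

    Columns are mean-centered; ``scale=True`` additionally divides by the
    column standard deviation (constant columns are left unscaled).
    Eigenvalues use the unbiased (n-1) covariance normalization, so their
    sum equals the total column variance.
    """
    if matrix.n_samples < 3:
        raise ParameterError("PCA needs at least 3 samples")
    x = matrix.values.astype(float).copy()
    x -= x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x /= sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    n = matrix.n_samples
    eigenvalues = s ** 2 / (n - 1)
    total = eigenvalues.sum()
    retained = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    # deterministic sign: largest-magnitude loading of each component positive
    for k in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores3 = np.zeros((n, 3))
    k = min(3, len(s))
    scores3[:, :k] = u[:, :k] * s[:k]
    return PCAResult(
        eigenvectors=vt.T,
        eigenvalues=eigenvalues,
        retained_variance=retained,
        scores=scores3,
        labels=list(matrix.conditions),
    )


# --------------------------------------------------------------------------
# Distances


def distance(a: np.ndarray, b: np.ndarray, metric: str = "euclidean") -> float:
    """Euclidean distance, or Hamming distance as a count of differing
    positions (binary vectors only)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("vectors must have equal length")
    if metric == "euclidean":
        return float(np.linalg.norm(a - b))
    if metric == "hamming":
        if not np.all(np.isin(a, (0.0, 1.0))) or not np.all(np.isin(b, (0.0, 1.0))):
            raise ParameterError("Hamming distance requires binary vectors")
        return float(np.sum(a != b))
    raise ParameterError(f"unknown metric {metric!r}")


# --------------------------------------------------------------------------
# Agglomerative clustering


@dataclass
class DendroNode:
    """A node of the merge tree; leaves carry ``leaf_id``, internal nodes a
    merge ``height`` and two children."""

    height: float = 0.0
    leaf_id: str | None = None
    children: tuple["DendroNode", "DendroNode"] | None = None
    _leaves: list[str] = field(default_factory=list, repr=False)

    @property
    def is_leaf(self) -> bool:
        return self.leaf_id is not None

    def leaves(self) -> list[str]:
        return [self.leaf_id] if self.is_leaf else self._leaves


@dataclass
class Dendrogram:
    """Result of hierarchical clustering: the root node plus the flat merge
    history ``(height, left leaves, right leaves)`` in merge order."""

    root: DendroNode
    merges: list[tuple[float, tuple[str, ...], tuple[str, ...]]]
    leaf_ids: list[str]

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf order of the tree."""
        order: list[str] = []

        def walk(node: DendroNode) -> None:
            if node.is_leaf:
                order.append(node.leaf_id)
            else:
                walk(node.children[0])
                walk(node.children[1])

        walk(self.root)
        return order

    def heights(self) -> list[float]:
        return [m[0] for m in self.merges]

    def cut(self, k: int) -> list[set[str]]:
        """Partition the leaves into k clusters by undoing the k-1 highest
        (latest) merges."""
        if not 1 <= k <= len(self.leaf_ids):
            raise ParameterError(f"k must be in [1, {len(self.leaf_ids)}]")
        clusters = [{l} for l in self.leaf_ids]
        index = {l: i for i, l in enumerate(self.leaf_ids)}
        parent = list(range(len(self.leaf_ids)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        merged = 0
        for height, left, right in self.merges:
            if len(self.leaf_ids) - merged == k:
                break
            a, b = find(index[left[0]]), find(index[right[0]])
            parent[b] = a
            clusters[a] |= clusters[b]
            clusters[b] = set()
            merged += 1
        return [c for c in clusters if c]

    def to_newick(self) -> str:
        """Newick with branch lengths = parent height - child height."""

        def fmt(node: DendroNode, parent_height: float) -> str:
            length = max(parent_height - node.height, 0.0)
            if node.is_leaf:
                return f"{_newick_escape(node.leaf_id)}:{length:g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{length:g}"

        if self.root.is_leaf:
            return f"{_newick_escape(self.root.leaf_id)}:0;"
        inner = ",".join(fmt(c, self.root.height) for c in self.root.children)
        return f"({inner});"


def _newick_escape(label: str) -> str:
    if any(ch in label for ch in "(),:;' \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


_LINKAGES = ("single", "complete", "average")


def hcluster(
    matrix: PeakMatrix,
    axis: str = "samples",
    metric: str | None = None,
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of samples or m/z values.

    Starts with every leaf in its own cluster and repeatedly merges the
    closest pair under the linkage (single = min, complete = max, average =
    unweighted mean over all inter-cluster leaf pairs).  Ties are broken by
    the lowest (smallest-leaf-index) pair, making the merge sequence
    deterministic.  ``metric`` defaults to Hamming for binary matrices and
    Euclidean for intensity matrices.
    """
    if axis == "samples":
        vectors = matrix.values
        ids = list(matrix.sample_ids)
    elif axis == "mz":
        vectors = matrix.values.T
        ids = [f"{m:.4f}" for m in matrix.mz]
    else:
        raise ParameterError(f"unknown axis {axis!r}")
    if metric is None:
        metric = "hamming" if matrix.mode == "binary" else "euclidean"
    if linkage not in _LINKAGES:
        raise ParameterError(f"unknown linkage {linkage!r}")
    return hcluster_vectors(vectors, ids, metric, linkage)


def hcluster_vectors(
    vectors: np.ndarray,
    ids: Sequence[str],
    metric: str = "euclidean",
    linkage: str = "average",
) -> Dendrogram:
    """Cluster arbitrary row vectors (see :func:`hcluster`)."""
    vectors = np.asarray(vectors, dtype=float)
    n = len(ids)
    if n < 2:
        raise ParameterError("clustering needs >= 2 leaves")
    if len(set(ids)) != n:
        raise ParameterError("leaf ids must be unique")
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = distance(vectors[i], vectors[j], metric)

    # active clusters keyed by smallest leaf index
    nodes: dict[int, DendroNode] = {
        i: DendroNode(height=0.0, leaf_id=ids[i]) for i in range(n)
    }
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    # inter-cluster dissimilarity under the linkage
    d: dict[tuple[int, int], float] = {
        (i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[float, tuple[str, ...], tuple[str, ...]]] = []
    active = sorted(members)
    while len(active) > 1:
        best = min((d[(i, j)], i, j) for k, i in enumerate(active) for j in active[k + 1:])
        h, i, j = best
        left, right = nodes[i], nodes[j]
        merged = DendroNode(height=float(h), children=(left, right))
        merged._leaves = left.leaves() + right.leaves()
        merges.append((float(h), tuple(left.leaves()), tuple(right.leaves())))
        members[i] = members[i] + members[j]
        nodes[i] = merged
        del members[j], nodes[j]
        active = sorted(members)
        for k in active:
            if k == i:
                continue
            a, b = min(i, k), max(i, k)
            d[(a, b)] = _linkage_value(members[i], members[k], dist, linkage)
    root = nodes[active[0]]
    return Dendrogram(root=root, merges=merges, leaf_ids=list(ids))


def _linkage_value(
    ca: list[int], cb: list[int], dist: np.ndarray, linkage: str
) -> float:
    block = dist[np.ix_(ca, cb)]
    if linkage == "single":
        return float(block.min())
    if linkage == "complete":
        return float(block.max())
    return float(block.mean())


# --------------------------------------------------------------------------
# Heat-map export and peak-list restriction


def export_heatmap(
    matrix: PeakMatrix,
    sample_tree: Dendrogram,
    mz_tree: Dendrogram,
    out_prefix: str | Path,
    treeview: bool = False,
) -> dict[str, Path]:
    """Write the clustered heat-map data.

    Produces ``<prefix>.tsv`` (the matrix reordered to both trees' leaf
    orders, samples as columns and m/z values as rows), ``<prefix>.samples.nwk``
    and ``<prefix>.mz.nwk``.  With ``treeview=True`` a Java
    TreeView-compatible CDT/GTR/ATR triplet is written as well.
    """
    mz_ids = [f"{m:.4f}" for m in matrix.mz]
    if sorted(sample_tree.leaf_ids) != sorted(matrix.sample_ids):
        raise ConsistencyError("sample tree leaves do not match matrix samples")
    if sorted(mz_tree.leaf_ids) != sorted(mz_ids):
        raise ConsistencyError("m/z tree leaves do not match matrix columns")
    sample_order = sample_tree.leaf_order()
    mz_order = mz_tree.leaf_order()
    srow = {s: i for i, s in enumerate(matrix.sample_ids)}
    mcol = {m: j for j, m in enumerate(mz_ids)}
    reordered = np.array(
        [[matrix.values[srow[s], mcol[m]] for s in sample_order] for m in mz_order]
    )
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    tsv = out_prefix.with_suffix(".tsv")
    with open(tsv, "w") as fh:
        fh.write("mz\t" + "\t".join(sample_order) + "\n")
        for m, row in zip(mz_order, reordered):
            cells = "\t".join(
                str(int(v)) if matrix.mode == "binary" else repr(float(v)) for v in row
            )
            fh.write(f"{m}\t{cells}\n")
    paths["tsv"] = tsv
    for name, tree in (("samples", sample_tree), ("mz", mz_tree)):
        p = out_prefix.with_suffix(f".{name}.nwk")
        p.write_text(tree.to_newick() + "\n")
        paths[name] = p
    if treeview:
        paths.update(_export_treeview(out_prefix, sample_order, mz_order, reordered,
                                      sample_tree, mz_tree))
    return paths


def _export_treeview(
    prefix: Path,
    sample_order: list[str],
    mz_order: list[str],
    reordered: np.ndarray,
    sample_tree: Dendrogram,
    mz_tree: Dendrogram,
) -> dict[str, Path]:
    """Minimal CDT/GTR/ATR triplet (Java TreeView conventions)."""

    def tree_lines(tree: Dendrogram, order: list[str], prefix_char: str) -> list[str]:
        node_name = {l: f"{prefix_char}LEAF{order.index(l)}X" for l in tree.leaf_ids}
        lines = []
        max_h = max((m[0] for m in tree.merges), default=1.0) or 1.0
        for k, (h, left, right) in enumerate(tree.merges):
            name = f"{prefix_char}NODE{k}X"
            ln = node_name[left[0]]
            rn = node_name[right[0]]
            lines.append(f"{name}\t{ln}\t{rn}\t{1.0 - h / max_h:.6f}")
            for l in left + right:
                node_name[l] = name
        return lines

    out: dict[str, Path] = {}
    gtr = prefix.with_suffix(".gtr")
    gtr.write_text("\n".join(tree_lines(mz_tree, mz_order, "G")) + "\n")
    out["gtr"] = gtr
    atr = prefix.with_suffix(".atr")
    atr.write_text("\n".join(tree_lines(sample_tree, sample_order, "A")) + "\n")
    out["atr"] = atr
    cdt = prefix.with_suffix(".cdt")
    with open(cdt, "w") as fh:
        fh.write("GID\tUNIQID\tNAME\tGWEIGHT\t" + "\t".join(sample_order) + "\n")
        fh.write("AID\t\t\t\t" + "\t".join(f"ALEAF{i}X" for i in range(len(sample_order))) + "\n")
        fh.write("EWEIGHT\t\t\t\t" + "\t".join("1" for _ in sample_order) + "\n")
        for i, (m, row) in enumerate(zip(mz_order, reordered)):
            fh.write(f"GLEAF{i}X\t{m}\t{m}\t1\t" + "\t".join(f"{v:g}" for v in row) + "\n")
    out["cdt"] = cdt
    return out


def restrict_to_peaks(
    matrix: PeakMatrix, mz_list: Sequence[float], tolerance: float = 0.1
) -> tuple[PeakMatrix, list[float]]:
    """Keep only columns whose m/z matches a listed value within tolerance.

    Returns the restricted matrix and the listed values that matched no
    column.  Raises :class:`EmptySelectionError` when nothing survives.
    """
    if len(mz_list) == 0:
        raise ParameterError("peak list is empty")
    mz_list = [float(m) for m in mz_list]
    keep = np.zeros(len(matrix.mz), dtype=bool)
    unmatched: list[float] = []
    for target in mz_list:
        hits = np.abs(matrix.mz - target) <= tolerance
        if hits.any():
            keep |= hits
        else:
            unmatched.append(target)
    if not keep.any():
        raise EmptySelectionError("no matrix column matches the peak list")
    restricted = PeakMatrix(
        sample_ids=list(matrix.sample_ids),
        conditions=list(matrix.conditions),
        mz=matrix.mz[keep],
        values=matrix.values[:, keep],
        mode=matrix.mode,
    )
    return restricted, unmatched
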
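"""Expression filtering, log transform and unsupervised hierarchical clustering.

Samples are clustered on 1 − Pearson correlation of their log2(FPKM+1)
profiles with average linkage — the convention for expression compendia;
Euclidean distance and complete linkage are available as options.

Linkage is computed by an in-package Lance–Williams implementation so that
ties in merge distance are broken deterministically by lowest cluster index,
making trees bit-reproducible across platforms.  The result uses the SciPy
linkage-matrix encoding, so SciPy's cut utilities apply directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster

from . import io
from .io import ExpressionMatrix, SampleMetadata, StateError, ValidationError

MERGE_TOL = 1e-12  # numerical slack on monotone average-linkage heights


# ---------------------------------------------------------------------------
# Filtering and transform
# ---------------------------------------------------------------------------

def filter_by_fpkm(
    matrix: ExpressionMatrix, threshold: float = 0.1, policy: str = "max_ge"
) -> ExpressionMatrix:
    """Keep genes expressed at >= threshold FPKM (inclusive) under the policy.

    ``max_ge`` (default) keeps a gene if any sample reaches the threshold —
    "expressed somewhere"; ``mean_ge`` uses the across-sample mean instead.
    """
    if matrix.transform_state != io.RAW_FPKM:
        raise StateError("FPKM filter requires a raw_fpkm matrix")
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    if policy == "max_ge":
        keep = matrix.values.max(axis=1) >= threshold
    elif policy == "mean_ge":
        keep = matrix.values.mean(axis=1) >= threshold
    else:
        raise ValidationError(f"unknown filter policy {policy!r}")
    if not keep.any():
        raise ValidationError(
            f"FPKM filter at {threshold} removed every gene; lower the threshold"
        )
    return ExpressionMatrix(matrix.values.loc[keep].copy(), io.RAW_FPKM)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(FPKM + 1); refuses to run twice (transform-state machine)."""
    if matrix.transform_state != io.RAW_FPKM:
        raise StateError(f"matrix already in state {matrix.transform_state!r}")
    return ExpressionMatrix(np.log2(matrix.values + 1.0), io.LOG2P1)


# ---------------------------------------------------------------------------
# Linkage (Lance–Williams, deterministic tie-break)
# ---------------------------------------------------------------------------

def linkage_matrix(dist: np.ndarray, method: str = "average") -> np.ndarray:
    """Agglomerate a square distance matrix into a SciPy-format linkage matrix.

    At every step the minimal-distance active pair is merged; exact ties are
    resolved toward the pair whose clusters were created earliest (original
    leaves first, in input order), which is what the row-major argmin over
    the active-cluster matrix yields.
    """
    if method not in ("average", "complete"):
        raise ValidationError(f"unknown linkage method {method!r}")
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    n = d.shape[0]
    if n < 2:
        raise ValidationError("need >= 2 observations to cluster")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, np.inf)
    ids = np.arange(n)  # active cluster ids, scipy numbering
    sizes = np.ones(n)
    Z = np.empty((n - 1, 4))
    for step in range(n - 1):
        m = d.shape[0]
        flat = int(np.argmin(d))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        height = d[i, j]
        si, sj = sizes[i], sizes[j]
        Z[step] = (min(ids[i], ids[j]), max(ids[i], ids[j]), height, si + sj)
        if method == "average":
            merged = (si * d[i, :] + sj * d[j, :]) / (si + sj)
        else:
            merged = np.maximum(d[i, :], d[j, :])
        d[i, :] = merged
        d[:, i] = merged
        d[i, i] = np.inf
        keep = np.arange(m) != j
        d = d[np.ix_(keep, keep)]
        ids[i] = n + step
        sizes[i] = si + sj
        ids = ids[keep]
        sizes = sizes[keep]
    return Z


@dataclass
class Dendrogram:
    """Binary merge tree over named leaves (SciPy linkage encoding)."""

    leaf_ids: tuple[str, ...]
    linkage: np.ndarray
    method: str = "average"

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.linkage.shape != (n - 1, 4):
            raise ValidationError(
                f"linkage must have {n - 1} merges for {n} leaves, "
                f"got shape {self.linkage.shape}"
            )
        if (self.linkage[:, 2] < 0).any():
            raise ValidationError("merge heights must be non-negative")
        if self.method == "average":
            h = self.linkage[:, 2]
            if (np.diff(h) < -MERGE_TOL).any():
                raise ValidationError("average-linkage heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def leaves_under(self, node: int) -> list[int]:
        """Leaf indices under a node id (leaves 0..n-1, merges n..2n-2)."""
        n = self.n_leaves
        stack, out = [node], []
        while stack:
            k = stack.pop()
            if k < n:
                out.append(k)
            else:
                row = self.linkage[k - n]
                stack.extend((int(row[0]), int(row[1])))
        return sorted(out)

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster labels (1..k) from cutting the tree into k clusters."""
        labels = fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=list(self.leaf_ids), name="cluster")

    def root_split(self) -> tuple[list[str], list[str]]:
        """The two leaf-id sets produced by undoing the final merge."""
        a, b = int(self.linkage[-1, 0]), int(self.linkage[-1, 1])
        return (
            [self.leaf_ids[i] for i in self.leaves_under(a)],
            [self.leaf_ids[i] for i in self.leaves_under(b)],
        )

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()


def sample_distance(matrix: ExpressionMatrix, distance: str = "one_minus_pearson") -> np.ndarray:
    x = matrix.values.to_numpy(dtype=float)
    if distance == "one_minus_pearson":
        sd = x.std(axis=0)
        if (sd == 0).any():
            bad = [matrix.sample_ids[i] for i in np.flatnonzero(sd == 0)]
            raise ValidationError(
                f"zero-variance sample(s) under correlation distance: {', '.join(bad)}"
            )
        d = 1.0 - np.corrcoef(x.T)
    elif distance == "euclidean":
        diff = x.T[:, None, :] - x.T[None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=2))
    else:
        raise ValidationError(f"unknown distance {distance!r}")
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return d


def cluster_samples(
    matrix: ExpressionMatrix,
    distance: str = "one_minus_pearson",
    linkage: str = "average",
) -> Dendrogram:
    """Hierarchical clustering of samples over gene profiles."""
    if matrix.n_samples < 2:
        raise ValidationError("need >= 2 samples to cluster")
    if matrix.transform_state != io.LOG2P1:
        warnings.warn("clustering a matrix not in log2(FPKM+1) state")
    d = sample_distance(matrix, distance)
    return Dendrogram(tuple(matrix.sample_ids), linkage_matrix(d, linkage), linkage)


def subtree_purity(tree: Dendrogram, metadata: SampleMetadata) -> float:
    """How well the root 2-cut separates pluripotent from somatic samples.

    1.0 iff undoing the final merge reproduces the PSC/somatic partition
    exactly; otherwise the mean over the two clusters of the majority label
    fraction.
    """
    flags = metadata.pluripotent
    missing = [s for s in tree.leaf_ids if s not in flags.index]
    if missing:
        raise ValidationError(f"leaves missing metadata: {', '.join(missing)}")
    labels = flags.loc[list(tree.leaf_ids)]
    if labels.nunique() < 2:
        raise ValidationError("purity needs both pluripotent and somatic samples")
    left, right = tree.root_split()
    fracs = []
    exact = True
    for side in (left, right):
        vals = labels.loc[side]
        frac = max(vals.mean(), 1.0 - vals.mean())
        fracs.append(frac)
        if vals.nunique() != 1:
            exact = False
    if exact and set(labels.loc[left].unique()) != set(labels.loc[right].unique()):
        return 1.0
    return float(np.mean(fracs))


# ---------------------------------------------------------------------------
# Newick round trip
# ---------------------------------------------------------------------------

def to_newick(tree: Dendrogram) -> str:
    """Serialize as Newick with branch lengths encoding the merge heights."""
    n = tree.n_leaves
    heights = np.concatenate([np.zeros(n), tree.linkage[:, 2]])

    def render(node: int) -> str:
        if node < n:
            return tree.leaf_ids[node]
        row = tree.linkage[node - n]
        parts = []
        for child in (int(row[0]), int(row[1])):
            bl = heights[node] - heights[child]
            parts.append(f"{render(child)}:{bl:.12g}")
        return "(" + ",".join(parts) + ")"

    return render(2 * n - 2) + ";"


def from_newick(newick: str) -> Dendrogram:
    """Rebuild a Dendrogram from an ultrametric binary Newick string."""
    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    root = t.seed_node
    # node height = distance from the node down to any leaf (ultrametric)
    leaf_names: list[str] = []
    for leaf in t.leaf_node_iter():
        leaf_names.append(leaf.taxon.label if leaf.taxon else leaf.label)
    index = {name: i for i, name in enumerate(leaf_names)}
    n = len(leaf_names)
    merges: list[tuple[float, int, int, int]] = []  # height, a, b, size

    def walk(node) -> tuple[int, float, int]:
        """Return (cluster id, height, size) for a node."""
        children = node.child_nodes()
        if not children:
            name = node.taxon.label if node.taxon else node.label
            return index[name], 0.0, 1
        if len(children) != 2:
            raise ValidationError("Newick tree must be strictly binary")
        (ida, ha, sa), (idb, hb, sb) = (walk(c) for c in children)
        bla = children[0].edge.length or 0.0
        height = ha + bla
        merges.append((height, ida, idb, sa + sb))
        return n + len(merges) - 1, height, sa + sb

    walk(root)
    order = sorted(range(len(merges)), key=lambda k: (merges[k][0], k))
    remap = {n + old: n + new for new, old in enumerate(order)}
    Z = np.empty((n - 1, 4))
    for new, old in enumerate(order):
        h, a, b, s = merges[old]
        a = remap.get(a, a)
        b = remap.get(b, b)
        Z[new] = (min(a, b), max(a, b), h, s)
    return Dendrogram(tuple(leaf_names), Z)


def write_newick(path: str | Path, tree: Dendrogram) -> None:
    Path(path).write_text(to_newick(tree) + "\n")
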
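"""Signed weighted co-expression network built from first principles.

The chain is the classical weighted co-expression construction: pairwise
Pearson correlation r_ij of log2(FPKM+1) profiles, soft-threshold adjacency
(signed: a_ij = ((1 + r_ij)/2)^β with β = 20 by default; unsigned:
|r_ij|^β), topological overlap

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    l_ij = Σ_{u≠i,j} a_iu a_uj,   k_i = Σ_{u≠i} a_iu,

average-linkage clustering of genes on 1 − TOM with a static height cut,
module eigengenes (first principal component of the standardized module
expression, unit variance, sign-oriented with mean module expression), gene
membership kME (correlation with an eigengene), and module–trait correlation
with the exact t-transform p-value.

Note on the static cut default: soft thresholding at β = 20 concentrates
off-module TOM dissimilarities near 1 and leaves even tightly co-regulated
modules at dissimilarities around 0.9, so the cut height defaults to 0.95 —
between the within-module and background plateaus.  The height and the
minimum module size are ordinary config parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster
from scipy.special import stdtr

from . import io
from .cluster import Dendrogram, linkage_matrix
from .io import ExpressionMatrix, SampleMetadata, StateError, ValidationError

logger = logging.getLogger("pluriscreen")

GREY = "grey"
PSC_TRAIT = "PSC"

DEFAULT_BETA = 20.0
DEFAULT_CUT_HEIGHT = 0.95
DEFAULT_MIN_MODULE_SIZE = 30
DEFAULT_GENE_CAP = 5000

#: smallest representable positive double; reported when |r| = 1
MIN_P = float(np.nextafter(0.0, 1.0))


# ---------------------------------------------------------------------------
# Correlation and adjacency
# ---------------------------------------------------------------------------

def drop_constant_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Remove zero-variance genes (logged); they carry no correlation signal."""
    sd = matrix.values.std(axis=1, ddof=0)
    dropped = list(matrix.values.index[sd == 0])
    if dropped:
        logger.warning("dropping %d constant gene(s): %s", len(dropped), ", ".join(dropped))
        return ExpressionMatrix(matrix.values.loc[sd > 0].copy(), matrix.transform_state)
    return matrix


def cap_genes_by_variance(matrix: ExpressionMatrix, cap: int = DEFAULT_GENE_CAP) -> ExpressionMatrix:
    """Keep the ``cap`` most variable genes (network-size guard, logged)."""
    if matrix.n_genes <= cap:
        return matrix
    sd = matrix.values.var(axis=1, ddof=0)
    keep = sd.sort_values(ascending=False, kind="stable").index[:cap]
    keep = [g for g in matrix.gene_ids if g in set(keep)]  # preserve input order
    logger.warning("gene cap: keeping %d of %d genes by variance", cap, matrix.n_genes)
    return ExpressionMatrix(matrix.values.loc[keep].copy(), matrix.transform_state)


def pairwise_correlation(
    matrix: ExpressionMatrix, gene_subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Gene–gene Pearson correlation of log2(FPKM+1) profiles."""
    if matrix.transform_state != io.LOG2P1:
        raise StateError("correlation requires a log2(FPKM+1) matrix")
    values = matrix.values if gene_subset is None else matrix.values.loc[list(gene_subset)]
    x = values.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = [values.index[i] for i in np.flatnonzero(sd == 0)]
        raise ValidationError(f"zero-variance gene(s): {', '.join(map(str, bad))}")
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=values.index, columns=values.index)


@dataclass
class AdjacencyMatrix:
    values: pd.DataFrame
    beta: float
    network_type: str = "signed"

    def __post_init__(self) -> None:
        a = self.values.to_numpy()
        if a.shape[0] != a.shape[1]:
            raise ValidationError("adjacency must be square")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValidationError("adjacency must be symmetric")
        if (a < 0).any() or (a > 1).any():
            raise ValidationError("adjacency entries must lie in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


def soft_threshold_adjacency(
    cor: pd.DataFrame, beta: float = DEFAULT_BETA, network_type: str = "signed"
) -> AdjacencyMatrix:
    """Raise (transformed) correlations to the power β; diagonal fixed at 1."""
    if beta <= 0:
        raise ValidationError("beta must be > 0")
    r = cor.to_numpy(dtype=float)
    if network_type == "signed":
        a = ((1.0 + r) / 2.0) ** beta
    elif network_type == "unsigned":
        a = np.abs(r) ** beta
    else:
        raise ValidationError(f"unknown network_type {network_type!r}")
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(pd.DataFrame(a, index=cor.index, columns=cor.columns),
                           beta, network_type)


@dataclass
class TomMatrix:
    values: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.values.to_numpy()
        if not np.allclose(t, t.T, atol=1e-10):
            raise ValidationError("TOM must be symmetric")
        if (t < -1e-12).any() or (t > 1 + 1e-12).any():
            raise ValidationError("TOM entries must lie in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def dissimilarity(self) -> np.ndarray:
        d = 1.0 - self.values.to_numpy(dtype=float)
        d = np.clip((d + d.T) / 2.0, 0.0, None)
        np.fill_diagonal(d, 0.0)
        return d


def topological_overlap(adj: AdjacencyMatrix) -> TomMatrix:
    """Topological overlap: direct adjacency plus shared third-party neighbours."""
    a = adj.values.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # l_ij = sum_{u != i,j} a_iu a_uj  (diagonal of a is zero)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TomMatrix(pd.DataFrame(tom, index=adj.values.index, columns=adj.values.columns))


def topological_overlap_bruteforce(adj: AdjacencyMatrix) -> np.ndarray:
    """O(n³) triple-loop reference implementation (oracle for testing)."""
    a = adj.values.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = 0.0
            ki = 0.0
            kj = 0.0
            for u in range(n):
                if u != i and u != j:
                    l += a[i, u] * a[u, j]
                if u != i:
                    ki += a[i, u]
                if u != j:
                    kj += a[j, u]
            tom[i, j] = (l + a[i, j]) / (min(ki, kj) + 1.0 - a[i, j])
    return tom


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

@dataclass
class ModuleAssignment:
    """Gene → module label; size-ranked names, ``grey`` for unassigned."""

    labels: pd.Series
    min_module_size: int
    cut_height: float
    tree: Dendrogram | None = None

    @property
    def module_names(self) -> list[str]:
        return [m for m in self.labels.unique() if m != GREY]

    def genes_in(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != GREY].value_counts()


def detect_modules(
    tom: TomMatrix,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
) -> ModuleAssignment:
    """Average-linkage clustering on 1 − TOM with a static height cut.

    Clusters smaller than ``min_module_size`` are relabelled grey; the rest
    are renamed module_1 (largest), module_2, ... with ties broken by the
    first gene's position.
    """
    if min_module_size < 1:
        raise ValidationError("min_module_size must be >= 1")
    if not (0.0 < cut_height < 1.0):
        raise ValidationError("cut_height must lie in (0, 1)")
    genes = tom.gene_ids
    Z = linkage_matrix(tom.dissimilarity(), "average")
    tree = Dendrogram(tuple(genes), Z)
    flat = fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(GREY, index=pd.Index(genes, name="gene_id"), name="module")
    # order clusters by size desc, then first-appearance for determinism
    first_pos = {}
    counts = {}
    for pos, c in enumerate(flat):
        counts[c] = counts.get(c, 0) + 1
        first_pos.setdefault(c, pos)
    ranked = sorted(
        (c for c, s in counts.items() if s >= min_module_size),
        key=lambda c: (-counts[c], first_pos[c]),
    )
    for rank, c in enumerate(ranked, start=1):
        labels.iloc[np.flatnonzero(flat == c)] = f"module_{rank}"
    return ModuleAssignment(labels, min_module_size, cut_height, tree)


# ---------------------------------------------------------------------------
# Eigengenes
# ---------------------------------------------------------------------------

@dataclass
class Eigengene:
    module: str
    values: pd.Series  # per-sample, mean 0, unit variance (ddof=1)
    explained_variance: float


@dataclass
class EigengeneSet:
    eigengenes: dict[str, Eigengene] = field(default_factory=dict)

    def __getitem__(self, module: str) -> Eigengene:
        return self.eigengenes[module]

    def __iter__(self):
        return iter(self.eigengenes.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({m: e.values for m, e in self.eigengenes.items()})


def standardize_genes(values: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score across samples (sample sd, ddof=1)."""
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = list(values.index[sd == 0])
        raise ValidationError(f"zero-variance gene(s): {', '.join(map(str, bad))}")
    return values.sub(mu, axis=0).div(sd, axis=0)


def module_eigengene(
    matrix: ExpressionMatrix, genes: Sequence[str], module: str = "module"
) -> Eigengene:
    """First principal component of the module's standardized expression.

    Scaled to unit variance over samples and sign-oriented so that it
    correlates positively with the mean standardized module profile.
    ``explained_variance`` is the leading eigenvalue share of the module's
    gene–gene correlation matrix.
    """
    genes = list(genes)
    if not genes:
        raise ValidationError(f"module {module!r} is empty")
    if matrix.transform_state != io.LOG2P1:
        raise StateError("eigengene requires a log2(FPKM+1) matrix")
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise ValidationError(f"genes absent from matrix: {', '.join(missing)}")
    z = standardize_genes(matrix.values.loc[genes])
    x = z.to_numpy(dtype=float)
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    e = vt[0]
    mean_profile = x.mean(axis=0)
    if float(e @ mean_profile) < 0:
        e = -e
    e = e / np.std(e, ddof=1)
    ev = float(s[0] ** 2 / np.sum(s ** 2))
    return Eigengene(module, pd.Series(e, index=matrix.values.columns, name=module), ev)


def module_eigengenes(matrix: ExpressionMatrix, assignment: ModuleAssignment) -> EigengeneSet:
    out = EigengeneSet()
    for m in assignment.module_names:
        out.eigengenes[m] = module_eigengene(matrix, assignment.genes_in(m), m)
    return out


# ---------------------------------------------------------------------------
# Traits and module-trait correlation
# ---------------------------------------------------------------------------

@dataclass
class TraitDesign:
    """Binary sample-indicator matrix (samples × traits)."""

    indicators: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.indicators.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("trait indicators must be 0/1")
        const = [t for t in self.indicators.columns
                 if self.indicators[t].nunique() < 2]
        if const:
            raise ValidationError(
                f"trait(s) with no contrast (all 0 or all 1): {', '.join(const)}"
            )

    @property
    def trait_names(self) -> list[str]:
        return list(self.indicators.columns)


def build_trait_design(
    metadata: SampleMetadata,
    samples: Sequence[str] | None = None,
    include_psc: bool = True,
    per_sample: bool = False,
) -> TraitDesign:
    """Per-group 0/1 indicators, plus a combined PSC (hiPSC ∪ hESC) trait.

    ``per_sample`` switches to one-hot per-sample indicators instead.
    """
    metadata.require_two_groups()
    ids = list(samples) if samples is not None else metadata.sample_ids
    t = metadata.table.loc[ids]
    if per_sample:
        ind = pd.DataFrame(np.eye(len(ids), dtype=int), index=ids, columns=ids)
    else:
        ind = pd.get_dummies(t["group"]).astype(int)
        ind = ind[sorted(ind.columns)]
        if include_psc:
            ind[PSC_TRAIT] = t["pluripotent"].astype(int)
    ind.index = pd.Index(ids, name="sample_id")
    return TraitDesign(ind)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the exact t-transform.

    t = r·√(n−2)/√(1−r²) with n−2 degrees of freedom; |r| = 1 maps to the
    smallest representable positive double.
    """
    if n < 3:
        raise ValidationError("p-value needs n >= 3")
    if abs(r) >= 1.0:
        return MIN_P
    df = n - 2
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    return float(max(2.0 * stdtr(df, -abs(t)), MIN_P))


def module_trait_correlation(
    eigengenes: EigengeneSet, design: TraitDesign, bonferroni: bool = False
) -> pd.DataFrame:
    """Pearson r and two-sided p for every (module eigengene, trait) pair.

    Raw p-values by default; ``bonferroni`` multiplies them by the number of
    (module, trait) tests, capped at 1.
    """
    rows = []
    for eg in eigengenes:
        e = eg.values.loc[design.indicators.index].to_numpy(dtype=float)
        n = e.size
        if n < 3:
            raise ValidationError("module-trait correlation needs >= 3 samples")
        for trait in design.trait_names:
            y = design.indicators[trait].to_numpy(dtype=float)
            r = float(np.corrcoef(e, y)[0, 1])
            rows.append(
                {"module": eg.module, "trait": trait, "r": r,
                 "p": correlation_pvalue(r, n)}
            )
    out = pd.DataFrame(rows, columns=["module", "trait", "r", "p"])
    if bonferroni and len(out):
        out["p"] = np.minimum(out["p"] * len(out), 1.0)
    return out


def select_top_trait_modules(
    result: pd.DataFrame, trait: str = PSC_TRAIT, k: int = 3, alpha: float = 0.05
) -> list[str]:
    """Top-k modules for a trait: p <= alpha, ranked by descending r.

    Ties break by smaller p, then module name.  Returns fewer than k (and
    warns) when not enough modules reach significance.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    sub = result[(result["trait"] == trait) & (result["p"] <= alpha)]
    ranked = sub.sort_values(["r", "p", "module"], ascending=[False, True, True])
    top = list(ranked["module"].head(k))
    if not top:
        logger.warning("no module passed alpha=%g for trait %r", alpha, trait)
    return top


# ---------------------------------------------------------------------------
# Module membership (kME)
# ---------------------------------------------------------------------------

def gene_membership_kme(
    matrix: ExpressionMatrix,
    eigengene: Eigengene,
    gene_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """kME: correlation of each gene's log2(FPKM+1) profile with the eigengene.

    Zero-variance genes are reported with ``undefined=True`` rather than
    dropped.
    """
    if matrix.transform_state != io.LOG2P1:
        raise StateError("kME requires a log2(FPKM+1) matrix")
    genes = list(gene_subset) if gene_subset is not None else matrix.gene_ids
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise ValidationError(f"genes absent from matrix: {', '.join(missing)}")
    x = matrix.values.loc[genes].to_numpy(dtype=float)
    e = eigengene.values.loc[matrix.sample_ids].to_numpy(dtype=float)
    sd = x.std(axis=1)
    ok = sd > 0
    kme = np.full(len(genes), np.nan)
    if ok.any():
        xc = x[ok] - x[ok].mean(axis=1, keepdims=True)
        ec = e - e.mean()
        kme[ok] = (xc @ ec) / (np.linalg.norm(xc, axis=1) * np.linalg.norm(ec))
    return pd.DataFrame(
        {"kme": np.clip(kme, -1.0, 1.0), "undefined": ~ok},
        index=pd.Index(genes, name="gene_id"),
    )


# ---------------------------------------------------------------------------
# One-call network construction
# ---------------------------------------------------------------------------

@dataclass
class NetworkResult:
    correlation: pd.DataFrame
    adjacency: AdjacencyMatrix
    tom: TomMatrix
    assignment: ModuleAssignment
    eigengenes: EigengeneSet
    module_trait: pd.DataFrame


def build_network(
    log_matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    beta: float = DEFAULT_BETA,
    network_type: str = "signed",
    cut_height: float = DEFAULT_CUT_HEIGHT,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    gene_cap: int = DEFAULT_GENE_CAP,
    per_sample_traits: bool = False,
) -> NetworkResult:
    """Run correlation → adjacency → TOM → modules → eigengenes → trait table."""
    metadata.validate_against(log_matrix)
    m = drop_constant_genes(log_matrix)
    m = cap_genes_by_variance(m, gene_cap)
    cor = pairwise_correlation(m)
    adj = soft_threshold_adjacency(cor, beta, network_type)
    tom = topological_overlap(adj)
    assignment = detect_modules(tom, cut_height, min_module_size)
    eigengenes = module_eigengenes(m, assignment)
    design = build_trait_design(metadata, samples=m.sample_ids, per_sample=per_sample_traits)
    if assignment.module_names:
        mt = module_trait_correlation(eigengenes, design)
    else:
        mt = pd.DataFrame(columns=["module", "trait", "r", "p"])
    return NetworkResult(cor, adj, tom, assignment, eigengenes, mt)
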
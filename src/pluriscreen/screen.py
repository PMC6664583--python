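"""The membership screen: PGM eigengene, kME cutoff, annotation filters, contrast.

The screen anchors on an a-priori pluripotency gene set (the PGM): its
eigengene summarises the pluripotency programme, and every gene from the top
PSC-correlated modules is scored by kME against it.  Noncoding genes with
kME strictly above the threshold (default 0.8) are candidates; pseudogenes
and literature-annotated (excluded) genes are flagged and removed from the
final shortlist but never silently dropped from the table.  Candidates are
ranked by kME or by their PSC-vs-somatic expression contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import io
from .io import (
    ExpressionMatrix,
    GeneAnnotation,
    GeneSet,
    SampleMetadata,
    StateError,
    ValidationError,
)
from .network import Eigengene, ModuleAssignment, gene_membership_kme, module_eigengene

logger = logging.getLogger("pluriscreen")

DEFAULT_TAU = 0.8


@dataclass
class ScreenConfig:
    """Membership-screen parameters.

    ``tau`` is the strict kME cutoff ("above 0.8"); ``restrict_to_noncoding``
    limits the final shortlist to noncoding biotypes; ``exclude`` lists
    known-function genes to flag; ``ranking_key`` orders the table.
    """

    tau: float = DEFAULT_TAU
    top_k_modules: int = 3
    restrict_to_noncoding: bool = True
    exclude: tuple[str, ...] = ()
    ranking_key: str = "kme"  # or "psc_fold_change"
    screen_all_noncoding: bool = False  # ignore module assignment, score all noncoding genes

    def __post_init__(self) -> None:
        if not (0.0 < self.tau <= 1.0):
            # tau = 1 is allowed and passes nothing (strict inequality)
            raise ValidationError("tau must lie in (0, 1]")
        if self.top_k_modules < 1:
            raise ValidationError("top_k_modules must be >= 1")
        if self.ranking_key not in ("kme", "psc_fold_change"):
            raise ValidationError(f"unknown ranking key {self.ranking_key!r}")


def pgm_eigengene(matrix: ExpressionMatrix, pgm: GeneSet) -> Eigengene:
    """Eigengene of the a-priori pluripotency gene set.

    Requires at least two PGM genes present in the matrix; missing members
    are logged (and listed in the error when too few remain).
    """
    present = [g for g in pgm.gene_ids if g in matrix.values.index]
    missing = [g for g in pgm.gene_ids if g not in matrix.values.index]
    if missing:
        logger.warning("PGM genes absent from matrix: %s", ", ".join(missing))
    if len(present) < 2:
        raise ValidationError(
            f"need >= 2 PGM genes in the matrix, found {len(present)}; "
            f"missing: {', '.join(missing)}"
        )
    return module_eigengene(matrix, present, pgm.name)


def expression_contrast(
    matrix: ExpressionMatrix, metadata: SampleMetadata, genes: Sequence[str]
) -> pd.DataFrame:
    """Mean raw FPKM in PSC and somatic samples and their log2 fold change.

    Fold change uses a pseudocount of 1: log2((mean_PSC + 1)/(mean_somatic + 1)).
    """
    if matrix.transform_state != io.RAW_FPKM:
        raise StateError("expression contrast works on raw FPKM values")
    metadata.validate_against(matrix)
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise ValidationError(f"genes absent from matrix: {', '.join(missing)}")
    flags = metadata.pluripotent.loc[matrix.sample_ids]
    psc_cols = list(flags.index[flags])
    som_cols = list(flags.index[~flags])
    if not psc_cols or not som_cols:
        raise ValidationError("need both PSC and somatic samples for the contrast")
    sub = matrix.values.loc[list(genes)]
    psc_mean = sub[psc_cols].mean(axis=1)
    som_mean = sub[som_cols].mean(axis=1)
    return pd.DataFrame(
        {
            "mean_fpkm_psc": psc_mean,
            "mean_fpkm_somatic": som_mean,
            "log2_fold_change": np.log2((psc_mean + 1.0) / (som_mean + 1.0)),
        }
    )


def screen_candidates(
    log_matrix: ExpressionMatrix,
    raw_matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    annotation: GeneAnnotation,
    assignment: ModuleAssignment,
    top_modules: Sequence[str],
    e_pgm: Eigengene,
    config: ScreenConfig = ScreenConfig(),
) -> pd.DataFrame:
    """Score every gene of the top modules by kME against the PGM eigengene.

    Returns the candidate table: kME, expression contrast, and the flags
    ``passed_threshold`` (kME strictly > tau), ``noncoding``, ``pseudogene``
    and ``excluded_known``.  Coding and excluded genes stay in the table,
    marked — the shortlist applies the filters.
    """
    unknown = [m for m in top_modules if m not in assignment.module_names]
    if unknown:
        raise ValidationError(f"module(s) not in assignment: {', '.join(unknown)}")
    if config.screen_all_noncoding:
        anno_all = annotation.for_genes(log_matrix.gene_ids)
        universe = list(anno_all.index[anno_all["biotype"] == io.NONCODING])
    else:
        universe = [g for m in top_modules for g in assignment.genes_in(m)]
    if not universe:
        logger.warning("candidate universe is empty for modules %s", list(top_modules))
        return _empty_table()
    anno = annotation.for_genes(universe)
    kme = gene_membership_kme(log_matrix, e_pgm, universe)
    contrast = expression_contrast(raw_matrix, metadata, universe)
    table = pd.DataFrame(
        {
            "symbol": anno["symbol"],
            "module": assignment.labels.reindex(universe, fill_value="grey"),
            "kme": kme["kme"],
            "kme_undefined": kme["undefined"],
            "mean_fpkm_psc": contrast["mean_fpkm_psc"],
            "mean_fpkm_somatic": contrast["mean_fpkm_somatic"],
            "log2_fold_change": contrast["log2_fold_change"],
            "passed_threshold": kme["kme"] > config.tau,
            "noncoding": anno["biotype"] == io.NONCODING,
            "pseudogene": anno["biotype"] == io.PSEUDOGENE,
            "excluded_known": anno["excluded"] | anno.index.isin(config.exclude),
        },
        index=pd.Index(universe, name="gene_id"),
    )
    table.loc[table["kme_undefined"], "passed_threshold"] = False
    key = "kme" if config.ranking_key == "kme" else "log2_fold_change"
    return table.sort_values(key, ascending=False, kind="stable")


def _empty_table() -> pd.DataFrame:
    cols = [
        "symbol", "module", "kme", "kme_undefined", "mean_fpkm_psc",
        "mean_fpkm_somatic", "log2_fold_change", "passed_threshold",
        "noncoding", "pseudogene", "excluded_known",
    ]
    return pd.DataFrame(columns=cols, index=pd.Index([], name="gene_id"))


def shortlist_uncharacterized(
    table: pd.DataFrame, restrict_to_noncoding: bool = True
) -> list[str]:
    """Final shortlist: passing, (non)coding filter, no pseudogenes, not excluded.

    Order follows the table's ranking; may be empty.
    """
    if table.empty:
        return []
    keep = table["passed_threshold"] & ~table["pseudogene"] & ~table["excluded_known"]
    if restrict_to_noncoding:
        keep &= table["noncoding"]
    return list(table.index[keep])


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    sample_tree: "object"  # cluster.Dendrogram
    network: "object"  # network.NetworkResult
    top_modules: list[str]
    pgm_eigengene: Eigengene
    candidates: pd.DataFrame
    shortlist: list[str]


def run_full_screen(
    raw_matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    annotation: GeneAnnotation,
    pgm: GeneSet,
    fpkm_min: float = 0.1,
    filter_policy: str = "max_ge",
    beta: float | None = None,
    network_type: str = "signed",
    cut_height: float | None = None,
    min_module_size: int | None = None,
    gene_cap: int | None = None,
    config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """FPKM filter → log2 → sample dendrogram → network → membership screen."""
    from . import cluster as _cluster
    from . import network as _network

    metadata.validate_against(raw_matrix)
    filtered = _cluster.filter_by_fpkm(raw_matrix, fpkm_min, filter_policy)
    logm = _cluster.log_transform(filtered)
    tree = _cluster.cluster_samples(logm)
    net = _network.build_network(
        logm,
        metadata,
        beta=_network.DEFAULT_BETA if beta is None else beta,
        network_type=network_type,
        cut_height=_network.DEFAULT_CUT_HEIGHT if cut_height is None else cut_height,
        min_module_size=(
            _network.DEFAULT_MIN_MODULE_SIZE if min_module_size is None else min_module_size
        ),
        gene_cap=_network.DEFAULT_GENE_CAP if gene_cap is None else gene_cap,
    )
    top = _network.select_top_trait_modules(
        net.module_trait, trait=_network.PSC_TRAIT, k=config.top_k_modules
    )
    e_pgm = pgm_eigengene(logm, pgm)
    table = screen_candidates(
        logm, filtered, metadata, annotation, net.assignment, top, e_pgm, config
    )
    short = shortlist_uncharacterized(table, config.restrict_to_noncoding)
    return ScreenResult(tree, net, top, e_pgm, table, short)
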
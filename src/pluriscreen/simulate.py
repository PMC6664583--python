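"""Synthetic FPKM data with the latent structure the co-expression screen assumes.

The generator emulates a compendium of pluripotent stem cell (PSC) and
somatic-tissue bulk RNA-seq profiles:

* a latent *pluripotency factor*, high in every hiPSC/hESC sample and low in
  somatic samples (two levels plus per-sample jitter, standardized to unit
  variance over samples);
* one latent *tissue factor* per somatic tissue, highest in that tissue's own
  samples, intermediate in other somatic tissues and lowest in PSCs —
  differentiation programs are absent in PSCs and partially shared between
  somatic tissues, which is what makes somatic samples cohere into one
  branch of the sample dendrogram as they do in real compendia;
* planted gene modules: a coding pluripotency module (the PGM analogue),
  noncoding true candidates on the pluripotency factor, weakly loading
  noncoding decoys, one 60-gene module per tissue, and unstructured
  background genes.

Signal is additive on the log2 scale — ``baseline + loading · factor +
Normal(0, σ)`` — and exponentiated to FPKM, giving log-normal marginals that
match the heavy right tail of real FPKM without modelling counts.  Because a
factor has unit empirical variance, the correlation between a planted gene
and its factor converges to λ/√(λ² + σ²) as the sample count grows.

A single :class:`numpy.random.Generator` seeded from ``config.seed`` drives
everything, so the full fixture is reproducible from one integer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io
from .ddct import QpcrPlate
from .io import (
    ExpressionMatrix,
    GeneAnnotation,
    GeneSet,
    SampleMetadata,
    ValidationError,
    config_hash,
    make_gene_annotation,
    make_sample_metadata,
)

PLURIPOTENCY_MODULE = "pluripotency"
DECOY_LABEL = "decoy"
BACKGROUND_LABEL = "background"


@dataclass
class SimulationConfig:
    """Study-shape and noise parameters for the synthetic compendium.

    Defaults mirror the screened compendium's composition: 21 hiPSC + 15 hESC
    samples sharing the pluripotency factor and 19 somatic samples over three
    tissues, a 32-gene pluripotency module, 12 planted noncoding candidates
    and 50 weak decoys, three 60-gene tissue modules and 300 background
    genes.  Loadings λ and the log2-scale noise sd σ set the population
    gene–factor correlation λ/√(λ²+σ²): 0.87 for the λ=0.9 candidates, 0.51
    for the λ=0.3 decoys, bracketing the screen's 0.8 membership cutoff.
    """

    n_hipsc: int = 21
    n_hesc: int = 15
    somatic_groups: tuple[tuple[str, int], ...] = (("liver", 7), ("heart", 6), ("brain", 6))
    n_pgm_genes: int = 32
    pgm_loading: float = 0.9
    n_true_candidates: int = 12
    candidate_loading: float = 0.9  # λ_true
    n_decoy_noncoding: int = 50
    decoy_loading: float = 0.3  # λ_decoy
    n_tissue_modules: int = 3
    genes_per_tissue_module: int = 60
    tissue_loading: float = 0.9
    n_background_genes: int = 300
    noncoding_background_every: int = 5  # every k-th background gene is noncoding
    noise_sd: float = 0.5  # σ, log2 scale
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    factor_jitter_sd: float = 0.15
    tissue_mid_level: float = 0.4  # tissue factor level in *other* somatic tissues
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_hipsc, self.n_hesc, self.n_pgm_genes, self.n_true_candidates,
            self.n_decoy_noncoding, self.n_tissue_modules, self.genes_per_tissue_module,
            self.n_background_genes,
        ] + [n for _, n in self.somatic_groups]
        if any(c < 0 for c in counts):
            raise ValidationError("all counts must be >= 0")
        if not (self.decoy_loading < self.candidate_loading <= 1.0):
            raise ValidationError("require λ_decoy < λ_true <= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_samples < 3:
            raise ValidationError("need >= 3 samples in total")
        if self.n_genes == 0:
            raise ValidationError("config generates zero genes")
        if self.n_tissue_modules > len(self.somatic_groups):
            raise ValidationError("more tissue modules than somatic groups")

    @property
    def n_samples(self) -> int:
        return self.n_hipsc + self.n_hesc + sum(n for _, n in self.somatic_groups)

    @property
    def n_genes(self) -> int:
        return (
            self.n_pgm_genes + self.n_true_candidates + self.n_decoy_noncoding
            + self.n_tissue_modules * self.genes_per_tissue_module
            + self.n_background_genes
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "somatic_groups" in data:
            data["somatic_groups"] = tuple((str(n), int(c)) for n, c in data["somatic_groups"])
        return cls(**data)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the matrix for recovery tests."""

    factor_values: pd.DataFrame  # samples × factors (pluripotency, tissue_*)
    module_membership: pd.Series  # gene_id -> planted label
    true_candidates: tuple[str, ...]
    config: SimulationConfig

    def membership_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "module": self.module_membership,
                "true_candidate": self.module_membership.index.isin(self.true_candidates),
            }
        )


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, GeneAnnotation, SyntheticTruth]:
    """Generate (expression, metadata, annotation, truth), deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    groups = [("hiPSC", config.n_hipsc), ("hESC", config.n_hesc), *config.somatic_groups]
    group_labels = np.concatenate([[g] * c for g, c in groups if c > 0])
    sample_ids = []
    for g, c in groups:
        sample_ids.extend(f"{g}_{i + 1:02d}" for i in range(c))
    is_psc = np.isin(group_labels, ["hiPSC", "hESC"])

    # latent factors, standardized to unit empirical variance over samples
    f_pluri = np.where(is_psc, 1.0, 0.0) + rng.normal(0.0, config.factor_jitter_sd, n)
    factors = {"pluripotency": _standardize(f_pluri)}
    tissue_names = [name for name, _ in config.somatic_groups[: config.n_tissue_modules]]
    for name in tissue_names:
        raw = np.where(
            group_labels == name, 1.0, np.where(~is_psc, config.tissue_mid_level, 0.0)
        ) + rng.normal(0.0, config.factor_jitter_sd, n)
        factors[f"tissue_{name}"] = _standardize(raw)

    gene_ids: list[str] = []
    biotypes: list[str] = []
    membership: list[str] = []
    rows: list[np.ndarray] = []

    def plant(prefix: str, count: int, loading: float, factor: np.ndarray | None,
              biotype: str, label: str) -> list[str]:
        ids = [f"{prefix}{i + 1:03d}" for i in range(count)]
        baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, count)
        signal = baseline[:, None] + rng.normal(0.0, config.noise_sd, (count, n))
        if factor is not None:
            signal += loading * factor[None, :]
        gene_ids.extend(ids)
        biotypes.extend([biotype] * count)
        membership.extend([label] * count)
        rows.append(signal)
        return ids

    plant("PGM", config.n_pgm_genes, config.pgm_loading,
          factors["pluripotency"], io.CODING, PLURIPOTENCY_MODULE)
    true_candidates = plant("LNC-CAND", config.n_true_candidates, config.candidate_loading,
                            factors["pluripotency"], io.NONCODING, PLURIPOTENCY_MODULE)
    plant("LNC-DECOY", config.n_decoy_noncoding, config.decoy_loading,
          factors["pluripotency"], io.NONCODING, DECOY_LABEL)
    for name in tissue_names:
        plant(f"TIS-{name.upper()}-", config.genes_per_tissue_module, config.tissue_loading,
              factors[f"tissue_{name}"], io.CODING, f"tissue_{name}")
    bg = plant("BG", config.n_background_genes, 0.0, None, io.CODING, BACKGROUND_LABEL)
    # sprinkle noncoding biotypes into the background for realism
    if config.noncoding_background_every > 0:
        for k, g in enumerate(bg):
            if (k + 1) % config.noncoding_background_every == 0:
                biotypes[gene_ids.index(g)] = io.NONCODING

    fpkm = 2.0 ** np.vstack(rows) if rows else np.empty((0, n))
    matrix = ExpressionMatrix(
        pd.DataFrame(fpkm, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        io.RAW_FPKM,
    )
    metadata = make_sample_metadata(sample_ids, group_labels, source=["synthetic"] * n)
    annotation = make_gene_annotation(gene_ids, biotypes=biotypes)
    truth = SyntheticTruth(
        factor_values=pd.DataFrame(factors, index=pd.Index(sample_ids, name="sample_id")),
        module_membership=pd.Series(membership, index=pd.Index(gene_ids, name="gene_id"),
                                    name="module"),
        true_candidates=tuple(true_candidates),
        config=config,
    )
    return matrix, metadata, annotation, truth


def pgm_gene_set(truth: SyntheticTruth) -> GeneSet:
    """The planted pluripotency-module coding genes as a gene set (PGM analogue)."""
    ids = [g for g in truth.module_membership.index
           if g.startswith("PGM")]
    return GeneSet("PGM", tuple(ids))


def write_dataset(
    out_dir: str | Path,
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    annotation: GeneAnnotation,
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Write expression/metadata/annotation/PGM/truth files into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"config_hash={config_hash(truth.config)}"
    paths = {
        "expression": out / "expression.tsv",
        "metadata": out / "metadata.tsv",
        "annotation": out / "annotation.tsv",
        "pgm": out / "pgm.txt",
        "truth": out / "truth.tsv",
        "factors": out / "factors.tsv",
    }
    io.write_expression_matrix(paths["expression"], matrix, tag)
    io.write_sample_metadata(paths["metadata"], metadata, tag)
    io.write_gene_annotation(paths["annotation"], annotation, tag)
    io.write_gene_set(paths["pgm"], pgm_gene_set(truth), tag)
    io.write_table(paths["truth"], truth.membership_frame(), tag)
    io.write_table(paths["factors"], truth.factor_values, tag)
    return paths


# ---------------------------------------------------------------------------
# qPCR plate fixtures
# ---------------------------------------------------------------------------

def generate_qpcr_plate(
    ct_means: Mapping[tuple[str, str], float],
    replicates: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
    reference_gene: str = "GAPDH",
    calibrator: str = "NC",
) -> QpcrPlate:
    """Draw replicate Ct values Normal(mean, sd) for each (gene, condition) well.

    ``ct_means`` maps (gene, condition) to the configured mean Ct.  With
    ``noise_sd`` = 0 every replicate equals its configured mean, so a plate
    configured at a given ΔΔCt reproduces 2^(−ΔΔCt) downstream exactly.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for (gene, condition), mean in ct_means.items():
        for r in range(replicates):
            records.append(
                {
                    "gene": gene,
                    "condition": condition,
                    "replicate": r + 1,
                    "ct": float(mean + rng.normal(0.0, noise_sd)),
                }
            )
    return QpcrPlate(pd.DataFrame(records), reference_gene=reference_gene,
                     calibrator=calibrator)
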
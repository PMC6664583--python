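"""Reading, writing and validation of expression matrices and companion tables.

All tables are plain TSV (tab delimiter, '.' decimal point, no locale
handling) to stay bit-exact with GEO-style matrices.  Lines starting with
``#`` are treated as comments on input; every writer emits one comment line
recording the package version and, when available, a configuration hash so
reruns can be compared byte for byte.

Missing values are not supported: every expression cell must be a finite,
non-negative number.  Validation is total — malformed input raises a typed
error naming the offending rows/cells, never a silent coercion.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__version__ = "0.1.0"

logger = logging.getLogger("pluriscreen")

RAW_FPKM = "raw_fpkm"
LOG2P1 = "log2p1"

#: group labels treated as pluripotent stem cells unless overridden
DEFAULT_PLURIPOTENT_GROUPS = ("hiPSC", "hESC")

CODING = "coding"
NONCODING = "noncoding"
PSEUDOGENE = "pseudogene"
BIOTYPES = (CODING, NONCODING, PSEUDOGENE)


class ValidationError(ValueError):
    """Input violates a structural invariant (shape, sign, type, coverage)."""


class DuplicateIdError(ValidationError):
    """An identifier column contains duplicates."""

    def __init__(self, kind: str, duplicates: Sequence[str]):
        self.duplicates = list(duplicates)
        super().__init__(f"duplicate {kind} ids: {', '.join(map(str, self.duplicates))}")


class StateError(ValidationError):
    """Operation applied to a matrix in the wrong transform state."""


def config_hash(obj: object) -> str:
    """Short deterministic hash of a configuration object's repr."""
    return hashlib.sha1(repr(obj).encode()).hexdigest()[:12]


def _header_comment(extra: str = "") -> str:
    tag = f"# pluriscreen v{__version__}"
    if extra:
        tag += f" {extra}"
    return tag + "\n"


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene × sample FPKM table.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns.
    ``transform_state`` tracks whether values are raw FPKM (non-negative) or
    log2(FPKM + 1); operations downstream enforce the state they require.
    """

    values: pd.DataFrame
    transform_state: str = RAW_FPKM

    def __post_init__(self) -> None:
        if self.transform_state not in (RAW_FPKM, LOG2P1):
            raise ValidationError(f"unknown transform_state {self.transform_state!r}")
        v = self.values
        if v.shape[0] == 0 or v.shape[1] == 0:
            raise ValidationError("expression matrix is empty")
        dup_g = v.index[v.index.duplicated()].unique()
        if len(dup_g):
            raise DuplicateIdError("gene", dup_g)
        dup_s = v.columns[v.columns.duplicated()].unique()
        if len(dup_s):
            raise DuplicateIdError("sample", dup_s)
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        bad = ~np.isfinite(arr)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite value at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        if self.transform_state == RAW_FPKM and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative FPKM at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def read_expression_matrix(path: str | Path, orientation: str = "genes_in_rows") -> ExpressionMatrix:
    """Read a TSV expression matrix (header = sample ids, first column = gene ids).

    Raises :class:`ValidationError` with cell coordinates for non-numeric or
    negative entries and :class:`DuplicateIdError` for repeated ids.
    """
    if orientation != "genes_in_rows":
        raise ValidationError(f"unsupported orientation {orientation!r}")
    raw = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValidationError(f"{path}: empty expression matrix")

    def _parse(cell):
        # Python float() is correctly rounded, so write -> read is bit-exact
        try:
            return float(cell)
        except (TypeError, ValueError):
            return np.nan

    num = raw.map(_parse)
    bad = num.isna().to_numpy() & raw.notna().to_numpy() | raw.isna().to_numpy()
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: non-numeric or missing value at gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r}"
        )
    num.index = num.index.astype(str)
    num.columns = num.columns.astype(str)
    num.index.name = "gene_id"
    return ExpressionMatrix(num, RAW_FPKM)


def write_expression_matrix(path: str | Path, matrix: ExpressionMatrix, extra: str = "") -> None:
    """Write the matrix as TSV with a version/config comment header.

    Values are written with Python repr precision so read ∘ write is the
    identity to full float precision.
    """
    with open(path, "w") as fh:
        fh.write(_header_comment(extra))
        matrix.values.to_csv(fh, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

#: "pluripotent" is accepted on input but recomputed from the group column
KNOWN_METADATA_COLUMNS = {"sample_id", "group", "source", "pluripotent"}


@dataclass
class SampleMetadata:
    """Per-sample group labels with a derived pluripotency indicator."""

    table: pd.DataFrame  # index sample_id; columns: group, pluripotent, source

    def __post_init__(self) -> None:
        t = self.table
        dup = t.index[t.index.duplicated()].unique()
        if len(dup):
            raise DuplicateIdError("sample", dup)
        empty = t.index[t["group"].isna() | (t["group"].astype(str).str.strip() == "")]
        if len(empty):
            raise ValidationError(f"empty group for sample(s): {', '.join(map(str, empty))}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    @property
    def pluripotent(self) -> pd.Series:
        return self.table["pluripotent"]

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Hard error if any matrix sample lacks metadata."""
        missing = [s for s in matrix.sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {', '.join(missing)}")

    def require_two_groups(self) -> None:
        if self.groups.nunique() < 2:
            raise ValidationError(
                "trait analysis requires >= 2 distinct sample groups, "
                f"found only {self.groups.unique().tolist()}"
            )


def make_sample_metadata(
    sample_ids: Sequence[str],
    groups: Sequence[str],
    source: Sequence[str] | None = None,
    pluripotent_groups: Iterable[str] = DEFAULT_PLURIPOTENT_GROUPS,
) -> SampleMetadata:
    pset = set(pluripotent_groups)
    t = pd.DataFrame(
        {
            "group": list(groups),
            "pluripotent": [g in pset for g in groups],
            "source": list(source) if source is not None else [""] * len(sample_ids),
        },
        index=pd.Index([str(s) for s in sample_ids], name="sample_id"),
    )
    return SampleMetadata(t)


def read_sample_metadata(
    path: str | Path,
    pluripotent_groups: Iterable[str] = DEFAULT_PLURIPOTENT_GROUPS,
) -> SampleMetadata:
    t = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "group"}
    missing = required - set(t.columns)
    if missing:
        raise ValidationError(f"{path}: missing metadata column(s) {sorted(missing)}")
    unknown = set(t.columns) - KNOWN_METADATA_COLUMNS
    if unknown:
        warnings.warn(f"{path}: ignoring unknown metadata column(s) {sorted(unknown)}")
    return make_sample_metadata(
        t["sample_id"],
        t["group"].fillna(""),
        t["source"] if "source" in t.columns else None,
        pluripotent_groups,
    )


def write_sample_metadata(path: str | Path, metadata: SampleMetadata, extra: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(extra))
        metadata.table.to_csv(fh, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Gene biotype and exclusion flags; unannotated genes default to coding.

    The coding default is deliberate: the candidate screen selects noncoding
    genes, so a gene missing from the annotation can never slip through the
    noncoding filter by accident.
    """

    table: pd.DataFrame  # index gene_id; columns: symbol, biotype, excluded

    def __post_init__(self) -> None:
        dup = self.table.index[self.table.index.duplicated()].unique()
        if len(dup):
            raise DuplicateIdError("gene", dup)
        bad = set(self.table["biotype"]) - set(BIOTYPES)
        if bad:
            raise ValidationError(f"unknown biotype(s) {sorted(bad)}; expected {BIOTYPES}")

    def for_genes(self, gene_ids: Sequence[str]) -> pd.DataFrame:
        """Annotation rows aligned to gene_ids, with defaults filled in."""
        out = pd.DataFrame(
            {"symbol": list(gene_ids), "biotype": CODING, "excluded": False},
            index=pd.Index(gene_ids, name="gene_id"),
        )
        present = [g for g in gene_ids if g in self.table.index]
        out.loc[present, ["symbol", "biotype", "excluded"]] = self.table.loc[
            present, ["symbol", "biotype", "excluded"]
        ]
        out["excluded"] = out["excluded"].astype(bool)
        return out


def make_gene_annotation(
    gene_ids: Sequence[str],
    symbols: Sequence[str] | None = None,
    biotypes: Sequence[str] | None = None,
    excluded: Sequence[bool] | None = None,
) -> GeneAnnotation:
    n = len(gene_ids)
    t = pd.DataFrame(
        {
            "symbol": list(symbols) if symbols is not None else list(gene_ids),
            "biotype": list(biotypes) if biotypes is not None else [CODING] * n,
            "excluded": list(excluded) if excluded is not None else [False] * n,
        },
        index=pd.Index([str(g) for g in gene_ids], name="gene_id"),
    )
    return GeneAnnotation(t)


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    t = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "gene_id" not in t.columns or "biotype" not in t.columns:
        raise ValidationError(f"{path}: annotation needs gene_id and biotype columns")
    excl = t["excluded"].map({"True": True, "False": False, "1": True, "0": False}) \
        if "excluded" in t.columns else pd.Series(False, index=t.index)
    if "excluded" in t.columns and excl.isna().any():
        raise ValidationError(f"{path}: excluded column must be boolean")
    return make_gene_annotation(
        t["gene_id"],
        t["symbol"] if "symbol" in t.columns else None,
        t["biotype"],
        excl.tolist(),
    )


def write_gene_annotation(path: str | Path, annotation: GeneAnnotation, extra: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(extra))
        annotation.table.to_csv(fh, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    """Named, duplicate-free list of gene ids (e.g. the pluripotency module)."""

    name: str
    gene_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.gene_ids) == 0:
            raise ValidationError(f"gene set {self.name!r} is empty")
        seen: set[str] = set()
        dups = [g for g in self.gene_ids if g in seen or seen.add(g)]
        if dups:
            raise DuplicateIdError("gene set", sorted(set(dups)))

    def __len__(self) -> int:
        return len(self.gene_ids)


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """One gene id per line; blank lines and '#' comments ignored.

    Duplicates are dropped (keeping first occurrence) with a warning; a file
    with no ids at all is a hard error.
    """
    ids: list[str] = []
    seen: set[str] = set()
    n_dup = 0
    for line in Path(path).read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if not token:
            continue
        if token in seen:
            n_dup += 1
            continue
        seen.add(token)
        ids.append(token)
    if not ids:
        raise ValidationError(f"{path}: gene set empty after parsing")
    if n_dup:
        warnings.warn(f"{path}: dropped {n_dup} duplicate gene id(s)")
    return GeneSet(name or Path(path).stem, tuple(ids))


def write_gene_set(path: str | Path, gene_set: GeneSet, extra: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(extra))
        fh.write("\n".join(gene_set.gene_ids) + "\n")


def write_table(path: str | Path, table: pd.DataFrame, extra: str = "", index: bool = True) -> None:
    """Generic TSV writer used for pipeline outputs (comment header included)."""
    with open(path, "w") as fh:
        fh.write(_header_comment(extra))
        table.to_csv(fh, sep="\t", index=index)
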
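"""Expression-matrix and gene-set I/O, gene filtering, symbol harmonization,
and batch adjustment.

The in-memory container is :class:`ExpressionMatrix`: a non-negative,
linear-scale genes x samples table (pandas DataFrame) plus per-sample
metadata (batch, condition, optional collection time in hours). Orientation
is fixed as genes in rows everywhere to avoid silent-transpose bugs.

Batch adjustment is a location (optionally location/scale) standardization
on the log(x+1) scale: per gene, each batch is recentred on the grand mean
(and rescaled to the pooled SD), then back-transformed. This removes exactly
the kind of multiplicative platform offset that dominates cross-cohort
expression compendia, is idempotent, and is fully verifiable on synthetic
data; empirical-Bayes shrinkage of batch parameters is deliberately not
applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("batch", "condition", "time_h")

#: symbol aliases collapsed onto a canonical (HGNC-style) name
SYMBOL_ALIASES = {
    "BMAL1": "ARNTL",
    "MOP3": "ARNTL",
    "BMAL2": "ARNTL2",
    "REV-ERBA": "NR1D1",
    "REVERBA": "NR1D1",
    "REV-ERBB": "NR1D2",
    "REVERBB": "NR1D2",
    "DEC1": "BHLHE40",
    "DEC2": "BHLHE41",
    "E4BP4": "NFIL3",
}


class FormatError(ValueError):
    """Raised when an input file violates the expected text format."""


@dataclass
class ExpressionMatrix:
    """Non-negative linear-scale expression, genes x samples, with metadata.

    ``values``: DataFrame indexed by gene symbol, columns are sample ids.
    ``metadata``: DataFrame indexed by sample id; columns ``batch``,
    ``condition`` and optionally ``time_h``. Metadata always covers every
    sample (defaults are filled in on construction).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        vals = self.values.to_numpy(dtype=float, copy=False)
        if vals.size and not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise FormatError(
                f"non-finite expression value at gene {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        if vals.size and vals.min() < 0:
            bad = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative expression value at gene {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        if self.values.index.has_duplicates:
            raise FormatError("duplicate gene symbols; collapse duplicates before constructing")
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=self.values.columns)
        self.metadata = self.metadata.reindex(self.values.columns)
        if "batch" not in self.metadata:
            self.metadata["batch"] = "batch0"
        if "condition" not in self.metadata:
            self.metadata["condition"] = "unknown"
        self.metadata["batch"] = self.metadata["batch"].fillna("batch0")
        self.metadata.index.name = "sample"

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self):
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        keep = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[keep].copy(), self.metadata.copy())

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.metadata.copy())


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple

    def __post_init__(self):
        if not self.members:
            raise FormatError(f"gene set {self.name!r} has no members")


@dataclass
class GeneSetCollection:
    sets: list

    def __post_init__(self):
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            raise FormatError("duplicate gene-set names in collection")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self):
        return len(self.sets)


class ParseReport(NamedTuple):
    n_genes: int
    n_samples: int
    duplicates_collapsed: tuple


def read_expression_tsv(path, metadata_path=None):
    """Read a genes x samples TSV (first column ``gene``) into an
    ExpressionMatrix.

    Duplicate gene rows are collapsed by mean (recorded in the parse
    report and logged). Returns ``(matrix, ParseReport)``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                gene = df.index[np.flatnonzero(bad)[0]]
                raise FormatError(
                    f"non-numeric expression value at gene {gene!r}, sample {col!r} in {path}"
                )
            df[col] = coerced
    if df.isna().to_numpy().any():
        loc = np.argwhere(df.isna().to_numpy())[0]
        raise FormatError(
            f"missing (NaN) expression value at gene {df.index[loc[0]]!r}, "
            f"sample {df.columns[loc[1]]!r} in {path}"
        )
    dupes = tuple(sorted(set(df.index[df.index.duplicated()])))
    if dupes:
        logger.warning("collapsing %d duplicated gene symbol(s) by mean: %s",
                       len(dupes), ", ".join(dupes[:10]))
        df = df.groupby(level=0, sort=False).mean()
    metadata = None
    if metadata_path is not None:
        metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
        metadata.index = metadata.index.astype(str)
    matrix = ExpressionMatrix(df, metadata)
    return matrix, ParseReport(df.shape[0], df.shape[1], dupes)


def write_expression_tsv(matrix: ExpressionMatrix, path, metadata_path=None) -> None:
    """Write an ExpressionMatrix as TSV (first column ``gene``); optionally
    write the sample metadata table alongside."""
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
    if metadata_path is not None:
        md = matrix.metadata.copy()
        md.index.name = "sample"
        md.to_csv(metadata_path, sep="\t")


class FilterResult(NamedTuple):
    matrix: ExpressionMatrix
    removed: tuple


def filter_genes(matrix: ExpressionMatrix, min_mean_expr: float = 1.0,
                 min_fraction_nonzero: float = 0.2) -> FilterResult:
    """Drop genes with mean expression below ``min_mean_expr`` or a nonzero
    fraction below ``min_fraction_nonzero``.

    With both thresholds at 0 this is the identity. Raises if nothing
    survives.
    """
    if min_mean_expr < 0 or min_fraction_nonzero < 0:
        raise ValueError("filter thresholds must be non-negative")
    vals = matrix.values
    means = vals.mean(axis=1)
    frac_nonzero = (vals > 0).mean(axis=1)
    keep = (means >= min_mean_expr) & (frac_nonzero >= min_fraction_nonzero)
    if not keep.any():
        raise ValueError(
            "gene filtering removed every gene; lower min_mean_expr "
            f"(={min_mean_expr}) or min_fraction_nonzero (={min_fraction_nonzero})"
        )
    removed = tuple(vals.index[~keep])
    out = ExpressionMatrix(vals.loc[keep].copy(), matrix.metadata.copy())
    return FilterResult(out, removed)


def batch_adjust(matrix: ExpressionMatrix, batch_labels=None,
                 mode: str = "location") -> ExpressionMatrix:
    """Remove per-gene batch offsets on the log(x+1) scale.

    mode="location": per gene, subtract each batch's mean log-expression and
    restore the grand mean. mode="location_scale": additionally divide by
    the batch SD and restore the pooled (RMS over batches) SD; every batch
    then needs >= 2 samples. A single batch is a no-op. Back-transform clips
    at zero (exact for the values the forward transform can produce).
    """
    if mode not in ("location", "location_scale"):
        raise ValueError(f"unknown batch adjustment mode {mode!r}")
    if batch_labels is None:
        batch_labels = matrix.metadata["batch"]
    batch_labels = pd.Series(batch_labels, index=matrix.samples).astype(str)
    groups = batch_labels.unique()
    if len(groups) < 2:
        return matrix.copy()
    log = np.log1p(matrix.values.to_numpy(dtype=float))
    grand_mean = log.mean(axis=1, keepdims=True)
    adjusted = np.empty_like(log)
    batch_sds = []
    masks = []
    for g in groups:
        mask = (batch_labels == g).to_numpy()
        masks.append(mask)
        sub = log[:, mask]
        if mode == "location_scale" and mask.sum() < 2:
            raise ValueError(f"batch {g!r} has a single sample; location_scale needs >= 2")
        mu = sub.mean(axis=1, keepdims=True)
        if mode == "location":
            adjusted[:, mask] = sub - mu + grand_mean
        else:
            sd = sub.std(axis=1, ddof=1, keepdims=True)
            sd_safe = np.where(sd > 0, sd, 1.0)
            adjusted[:, mask] = (sub - mu) / sd_safe
            batch_sds.append(np.where(sd > 0, sd, 0.0))
    if mode == "location_scale":
        pooled = np.sqrt(np.mean(np.concatenate(batch_sds, axis=1) ** 2, axis=1, keepdims=True))
        for mask in masks:
            adjusted[:, mask] = adjusted[:, mask] * pooled + grand_mean
    out = np.expm1(adjusted)
    out = np.maximum(out, 0.0)
    values = pd.DataFrame(out, index=matrix.genes, columns=matrix.samples)
    return ExpressionMatrix(values, matrix.metadata.copy())


def harmonize_symbols(matrix: ExpressionMatrix, species: str = "human") -> ExpressionMatrix:
    """Upper-case gene symbols and apply the clock-gene alias table so mouse
    (`Bmal1`) and human (`ARNTL`/`BMAL1`) rows address the same gene.

    Rows colliding after harmonization are collapsed by mean with a logged
    warning. ``species`` is accepted for interface symmetry; the mapping is
    case-insensitive and identical for human and mouse symbols.
    """
    if species not in ("human", "mouse"):
        raise ValueError("species must be 'human' or 'mouse'")
    upper = [str(g).upper() for g in matrix.genes]
    canonical = [SYMBOL_ALIASES.get(g, g) for g in upper]
    vals = matrix.values.copy()
    vals.index = pd.Index(canonical, name="gene")
    if vals.index.has_duplicates:
        dupes = sorted(set(vals.index[vals.index.duplicated()]))
        logger.warning("harmonization collapsed %d colliding symbol(s) by mean: %s",
                       len(dupes), ", ".join(dupes[:10]))
        vals = vals.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(vals, matrix.metadata.copy())


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT gene-set file: name <tab> description <tab> members...

    Member symbols are upper-cased; empty trailing fields are dropped.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno} has fewer than 3 tab-separated fields")
            name, desc = fields[0], fields[1]
            members = tuple(m.strip().upper() for m in fields[2:] if m.strip())
            if not members:
                raise FormatError(f"{path}: line {lineno} ({name!r}) has no members")
            sets.append(GeneSet(name, desc, members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")
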
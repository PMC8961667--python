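"""Reading expression tables and the standard pre-processing steps.

The container type is :class:`ExpressionMatrix`: a gene x sample matrix of
log2-scale expression with a dataset id, platform tag and optional sample
group labels.  Loading covers plain gene/probe x sample TSV tables and the
GEO series-matrix text dialect; pre-processing covers probe-to-gene
collapsing (mean over probes), log2 transformation and counts-to-TPM
conversion for RNA-seq.

Conventions: gene symbols are case-normalised to upper case; gene order is
lexicographic after probe collapsing so downstream scores are byte-for-byte
reproducible; missing microarray values are imputed with the per-gene row
mean when under 20 % of a row is missing, otherwise the gene is dropped.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .signatures import read_gmt  # noqa: F401  (re-exported: GMT loading lives with signatures)

__all__ = [
    "ExpressionMatrix",
    "read_expression_table",
    "resolve_missing",
    "collapse_probes",
    "log2_normalize",
    "counts_to_tpm",
    "write_expression_tsv",
    "read_expression_matrix",
    "read_gmt",
]

PLATFORMS = ("microarray", "rnaseq_bulk", "rnaseq_singlecell")

#: heuristic: series-matrix values with max below this are taken as already log2
LOGGED_MAX = 30.0

#: per-gene missingness above this fraction drops the gene instead of imputing
MAX_MISSING_FRACTION = 0.2


@dataclass
class ExpressionMatrix:
    """Gene x sample log2 expression for one dataset.

    ``values`` is a DataFrame indexed by unique upper-case gene symbols with
    unique sample ids as columns; all entries are finite (missing values are
    resolved at load time) and at least two samples are required.
    """

    values: pd.DataFrame
    dataset_id: str
    platform: str = "microarray"
    sample_groups: dict[str, str] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"platform must be one of {PLATFORMS}, got {self.platform!r}")
        df = self.values
        if not isinstance(df, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (genes x samples)")
        df = df.copy()
        df.index = [str(g).strip().upper() for g in df.index]
        df.columns = [str(s) for s in df.columns]
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if df.shape[1] < 2:
            raise ValueError("an expression matrix needs at least 2 samples")
        arr = df.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite; resolve missing values first")
        df = pd.DataFrame(arr, index=df.index, columns=df.columns)
        self.values = df
        if self.sample_groups is not None:
            unknown = set(self.sample_groups) - set(df.columns)
            if unknown:
                raise ValueError(f"sample_groups refer to unknown samples: {sorted(unknown)[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Samples x genes orientation (the estimator-facing layout)."""
        return self.values.T


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _parse_table(lines: list[str], path: str | Path) -> pd.DataFrame:
    rows = [line.rstrip("\n").split("\t") for line in lines if line.strip()]
    if not rows:
        raise ValueError(f"{path}: no table content found")
    header = [cell.strip().strip('"') for cell in rows[0]]
    sample_ids = header[1:]
    if not sample_ids:
        raise ValueError(f"{path}: header has no sample columns")
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample ids {dups[:5]}")
    feature_ids: list[str] = []
    data: list[list[float]] = []
    for row in rows[1:]:
        cells = [cell.strip().strip('"') for cell in row]
        if len(cells) != len(header):
            raise ValueError(
                f"{path}: row {cells[0]!r} has {len(cells) - 1} values for "
                f"{len(sample_ids)} samples"
            )
        feature_ids.append(cells[0])
        values: list[float] = []
        for sample, cell in zip(sample_ids, cells[1:]):
            if cell == "" or cell.upper() in ("NA", "NAN", "NULL"):
                values.append(np.nan)
                continue
            try:
                values.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at row {cells[0]!r}, "
                    f"column {sample!r}"
                ) from None
        data.append(values)
    if not data:
        raise ValueError(f"{path}: table has a header but no data rows")
    return pd.DataFrame(data, index=feature_ids, columns=sample_ids, dtype=float)


def read_expression_table(path: str | Path, dialect: str = "tsv_genes_by_samples") -> pd.DataFrame:
    """Read a raw probe- or gene-level table; file order is preserved.

    ``dialect`` is ``"tsv_genes_by_samples"`` (first column feature ids,
    header row sample ids, comment lines starting with ``#`` skipped) or
    ``"series_matrix"`` (GEO series-matrix text: only the block between
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end`` is read).
    Missing cells come back as NaN, to be resolved by :func:`resolve_missing`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    if dialect == "tsv_genes_by_samples":
        lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    elif dialect == "series_matrix":
        lines = []
        inside = False
        for ln in text.splitlines():
            marker = ln.strip().strip('"')
            if marker.startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if marker.startswith("!series_matrix_table_end"):
                inside = False
                continue
            if inside:
                lines.append(ln)
        if not lines:
            raise ValueError(f"{path}: no series_matrix_table_begin/end block found")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _parse_table(lines, path)


def resolve_missing(frame: pd.DataFrame, max_missing: float = MAX_MISSING_FRACTION) -> pd.DataFrame:
    """Impute per-gene row means for rows under ``max_missing`` missing, drop the rest."""
    frac = frame.isna().mean(axis=1)
    keep = frame.loc[frac < max_missing].copy()
    n_dropped = int((frac >= max_missing).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} gene(s) with >= {max_missing:.0%} missing values")
    if keep.isna().any().any():
        means = keep.mean(axis=1)
        keep = keep.apply(lambda row: row.fillna(means[row.name]), axis=1)
    return keep


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------

def collapse_probes(
    probe_matrix: pd.DataFrame,
    annotation: Mapping[str, str],
    dataset_id: str = "dataset",
    platform: str = "microarray",
    sample_groups: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Collapse probe-level rows to gene level by the mean over probes.

    ``annotation`` maps probe id -> gene symbol (many probes may share a
    gene).  Probes without a mapping are dropped; genes come out in
    lexicographic order.  Gene-level input passed with an identity annotation
    is returned unchanged (idempotence).
    """
    mapping = {str(p): str(g).strip().upper() for p, g in annotation.items() if str(g).strip()}
    present = [p for p in probe_matrix.index if str(p) in mapping]
    if not present:
        raise ValueError("no probe in the matrix has a gene annotation")
    frame = resolve_missing(probe_matrix.loc[present])
    genes = pd.Index([mapping[str(p)] for p in frame.index], name="gene")
    collapsed = frame.groupby(genes, sort=True).mean()
    return ExpressionMatrix(
        collapsed,
        dataset_id=dataset_id,
        platform=platform,
        sample_groups=sample_groups,
        provenance={"probe_collapse": "mean", "n_probes": int(len(present))},
    )


def log2_normalize(matrix: ExpressionMatrix | pd.DataFrame, offset: float = 1.0, **kwargs) -> ExpressionMatrix:
    """Apply ``log2(value + offset)``; input must be non-negative linear scale.

    Series matrices that are already log scale (max value under
    ``LOGGED_MAX``) should not be passed here; :func:`read_expression_matrix`
    applies that heuristic and records it in provenance.
    """
    if isinstance(matrix, ExpressionMatrix):
        frame, meta = matrix.values, matrix
    else:
        frame, meta = matrix, None
    arr = frame.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative values: input looks already log-scaled; skip log2_normalize")
    if offset <= 0 and (arr == 0).any():
        raise ValueError("offset must be positive when zeros are present")
    out = pd.DataFrame(np.log2(arr + offset), index=frame.index, columns=frame.columns)
    prov = dict(meta.provenance) if meta is not None else {}
    prov.update({"log2": True, "log2_offset": float(offset)})
    return ExpressionMatrix(
        out,
        dataset_id=meta.dataset_id if meta is not None else kwargs.pop("dataset_id", "dataset"),
        platform=meta.platform if meta is not None else kwargs.pop("platform", "microarray"),
        sample_groups=meta.sample_groups if meta is not None else kwargs.pop("sample_groups", None),
        provenance=prov,
    )


def counts_to_tpm(
    counts: pd.DataFrame,
    gene_lengths: Mapping[str, float],
    dataset_id: str = "dataset",
    platform: str = "rnaseq_bulk",
    log2_offset: float = 1.0,
    sample_groups: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Convert raw counts to log2(TPM + offset).

    TPM divides each count by its gene length in bases, then scales every
    sample to one million: pre-log columns sum to 1e6 exactly (to relative
    1e-9).  The transform is invariant to scaling a sample's counts by any
    positive constant (library-size invariance).
    """
    counts = counts.copy()
    counts.index = [str(g).strip().upper() for g in counts.index]
    lengths = pd.Series({str(g).strip().upper(): float(l) for g, l in gene_lengths.items()})
    missing = [g for g in counts.index if g not in lengths.index]
    if missing:
        raise ValueError(f"no gene length for: {missing[:5]}")
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"non-positive gene length for: {bad[:5]}")
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    rate = arr / lengths.to_numpy()[:, None]
    colsum = rate.sum(axis=0)
    if (colsum == 0).any():
        bad = counts.columns[colsum == 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad[:5]}")
    tpm = rate / colsum[None, :] * 1e6
    out = pd.DataFrame(np.log2(tpm + log2_offset), index=counts.index, columns=counts.columns)
    return ExpressionMatrix(
        out,
        dataset_id=dataset_id,
        platform=platform,
        sample_groups=sample_groups,
        provenance={"tpm": True, "log2": True, "log2_offset": float(log2_offset)},
    )


# ---------------------------------------------------------------------------
# Canonical TSV round-trip
# ---------------------------------------------------------------------------

def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the canonical gene x sample TSV with a one-line provenance header."""
    meta = {
        "dataset_id": matrix.dataset_id,
        "platform": matrix.platform,
        "sample_groups": matrix.sample_groups,
        "provenance": matrix.provenance,
    }
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as handle:
        handle.write("# emtmet " + json.dumps(meta, sort_keys=True) + "\n")
        handle.write("gene\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.values.to_numpy()):
            handle.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a canonical TSV written by :func:`write_expression_tsv`.

    Values round-trip bit-exactly (they are written with ``repr``).  Plain
    TSVs without the provenance header are accepted too; already-logged
    detection (max < LOGGED_MAX) is recorded in provenance.
    """
    path = Path(path)
    meta: dict = {}
    first = ""
    with open(path, "rt", encoding="utf-8") as handle:
        first = handle.readline()
    if first.startswith("# emtmet "):
        meta = json.loads(first[len("# emtmet "):])
    frame = read_expression_table(path, dialect="tsv_genes_by_samples")
    frame = resolve_missing(frame)
    prov = dict(meta.get("provenance") or {})
    if "log2" not in prov:
        prov["assumed_logged"] = bool(frame.to_numpy().max() < LOGGED_MAX)
    return ExpressionMatrix(
        frame,
        dataset_id=meta.get("dataset_id", path.stem),
        platform=meta.get("platform", "microarray"),
        sample_groups=meta.get("sample_groups"),
        provenance=prov,
    )
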
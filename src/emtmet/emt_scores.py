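"""The five per-sample EMT metrics and the panel that assembles them.

Functions here are thin wrappers over the estimators in
:mod:`emtmet.scorers`; each takes an :class:`~emtmet.io.ExpressionMatrix`
(or a samples x genes DataFrame) and returns a pandas Series of per-sample
scores.  :func:`score_emt_panel` computes all five metrics -- 76GS, KS,
hallmark-EMT ssGSEA, and singscore over the KS epithelial and mesenchymal
lists -- isolating failures so that, e.g., a matrix without CDH1 still gets
the other four columns.

Sign conventions: 76GS and the epithelial singscore rise toward the
epithelial end of the spectrum; KS, the hallmark-EMT enrichment and the
mesenchymal singscore rise toward the mesenchymal end.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .io import ExpressionMatrix
from .scorers import (
    GS76Scorer,
    InsufficientCoverageError,
    KSScorer,
    SingscoreScorer,
    SsgseaScorer,
    _as_sample_frame,
)
from .signatures import GeneSignature, SignatureRegistry, coverage, load_registry
from .tables import ScoreTable

__all__ = [
    "score_76gs",
    "score_ks",
    "score_ssgsea",
    "score_singscore",
    "score_emt_panel",
    "EMT_METRICS",
]

#: panel column order
EMT_METRICS = (
    "gs76",
    "ks",
    "hallmark_emt_ssgsea",
    "epithelial_singscore",
    "mesenchymal_singscore",
)


def score_76gs(matrix, signature: GeneSignature, anchor: str = "CDH1") -> pd.Series:
    """CDH1-correlation-weighted sum over the 76-gene list, cohort-centered to mean 0."""
    frame = _as_sample_frame(matrix)
    scorer = GS76Scorer(signature=signature, anchor=anchor).fit(frame)
    return scorer.score_samples(frame).rename("gs76")


def score_ks(matrix, epithelial: GeneSignature, mesenchymal: GeneSignature) -> pd.Series:
    """Signed two-sample KS score in [-1, 1]; positive = mesenchymal."""
    frame = _as_sample_frame(matrix)
    scorer = KSScorer(epithelial=epithelial, mesenchymal=mesenchymal).fit(frame)
    return scorer.score_samples(frame).rename("ks")


def score_ssgsea(
    matrix,
    signature: GeneSignature,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.Series:
    """ssGSEA enrichment of ``signature``; normalised by the within-dataset ES range."""
    frame = _as_sample_frame(matrix)
    scorer = SsgseaScorer(signature=signature, alpha=alpha, normalize=normalize).fit(frame)
    return scorer.score_samples(frame)


def score_singscore(matrix, signature: GeneSignature) -> pd.Series:
    """Singscore (normalised mean rank, in [-1, 1]) of ``signature``."""
    frame = _as_sample_frame(matrix)
    scorer = SingscoreScorer(signature=signature).fit(frame)
    return scorer.score_samples(frame)


def _attempt(columns: dict, metadata: dict, name: str, fn, signature, matrix) -> None:
    try:
        columns[name] = fn()
        cov = coverage(signature, matrix.gene_ids) if signature is not None else None
        metadata[name] = {
            "signature": signature.name if signature is not None else None,
            "coverage": cov.fraction if cov is not None else None,
        }
    except (InsufficientCoverageError, ValueError) as exc:
        warnings.warn(f"metric {name!r} not computed: {exc}")
        metadata[name] = {"missing": str(exc)}


def score_emt_panel(
    matrix: ExpressionMatrix,
    registry: SignatureRegistry | None = None,
    sample_type: str = "cellline",
    alpha: float = 0.25,
) -> ScoreTable:
    """Compute the five-metric EMT panel for one dataset.

    ``sample_type`` picks the cell-line (218-gene) or tumor (315-gene) KS
    epithelial/mesenchymal split; the same two lists feed the two singscore
    metrics.  Failures of individual metrics (absent anchor gene, poor
    signature coverage) are recorded in the table metadata instead of
    aborting the panel.
    """
    registry = registry if registry is not None else load_registry()
    epi, mes = registry.ks_pair(sample_type)

    columns: dict[str, pd.Series] = {}
    metadata: dict = {"sample_type": sample_type, "ssgsea_alpha": alpha}
    _attempt(columns, metadata, "gs76",
             lambda: score_76gs(matrix, registry.gs76), registry.gs76, matrix)
    _attempt(columns, metadata, "ks",
             lambda: score_ks(matrix, epi, mes), mes, matrix)
    _attempt(columns, metadata, "hallmark_emt_ssgsea",
             lambda: score_ssgsea(matrix, registry.hallmark_emt, alpha=alpha),
             registry.hallmark_emt, matrix)
    _attempt(columns, metadata, "epithelial_singscore",
             lambda: score_singscore(matrix, epi), epi, matrix)
    _attempt(columns, metadata, "mesenchymal_singscore",
             lambda: score_singscore(matrix, mes), mes, matrix)

    frame = pd.DataFrame(
        {name: columns[name] for name in EMT_METRICS if name in columns},
        index=pd.Index(matrix.sample_ids, name="sample"),
    )
    return ScoreTable(matrix.dataset_id, frame, metadata, matrix.sample_groups)
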
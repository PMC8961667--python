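"""Metabolic pathway activity scores and their panel.

Glycolysis and oxidative phosphorylation use ssGSEA over the hallmark sets;
AMPK and HIF1-alpha activity are proxied by singscore over their downstream
target-gene lists (33 and 23 genes); the FAO score is the weighted mean of
per-gene z-scores over the 14 fatty-acid-oxidation enzyme genes, with unit
default weights and a pluggable coefficient vector.
"""

from __future__ import annotations

import pandas as pd

from .emt_scores import _attempt, score_singscore, score_ssgsea
from .io import ExpressionMatrix
from .scorers import FAOScorer, _as_sample_frame
from .signatures import GeneSignature, SignatureRegistry, load_registry
from .tables import ScoreTable

__all__ = ["score_fao", "score_metabolic_panel", "METABOLIC_METRICS"]

METABOLIC_METRICS = (
    "glycolysis_ssgsea",
    "oxphos_ssgsea",
    "ampk_singscore",
    "hif1_singscore",
    "fao_score",
)


def score_fao(
    matrix,
    fao_genes: GeneSignature,
    weights: dict[str, float] | None = None,
) -> pd.Series:
    """Weighted mean z-score over the FAO enzyme genes.

    With the default unit weights the cohort mean is zero by construction;
    external coefficients (from the published FAO equation) can be supplied
    per gene.
    """
    frame = _as_sample_frame(matrix)
    scorer = FAOScorer(signature=fao_genes, weights=weights).fit(frame)
    return scorer.score_samples(frame).rename("fao_score")


def score_metabolic_panel(
    matrix: ExpressionMatrix,
    registry: SignatureRegistry | None = None,
    alpha: float = 0.25,
    fao_weights: dict[str, float] | None = None,
) -> ScoreTable:
    """Compute the five-metric metabolic panel for one dataset.

    Individual metric failures (e.g. a signature absent from the matrix)
    leave the other columns intact and are recorded in the table metadata.
    """
    registry = registry if registry is not None else load_registry()

    columns: dict[str, pd.Series] = {}
    metadata: dict = {"ssgsea_alpha": alpha}
    _attempt(
        columns, metadata, "glycolysis_ssgsea",
        lambda: score_ssgsea(matrix, registry.hallmark_glycolysis, alpha=alpha)
        .rename("glycolysis_ssgsea"),
        registry.hallmark_glycolysis, matrix)
    _attempt(
        columns, metadata, "oxphos_ssgsea",
        lambda: score_ssgsea(matrix, registry.hallmark_oxphos, alpha=alpha)
        .rename("oxphos_ssgsea"),
        registry.hallmark_oxphos, matrix)
    _attempt(
        columns, metadata, "ampk_singscore",
        lambda: score_singscore(matrix, registry.ampk_targets).rename("ampk_singscore"),
        registry.ampk_targets, matrix)
    _attempt(
        columns, metadata, "hif1_singscore",
        lambda: score_singscore(matrix, registry.hif1_targets).rename("hif1_singscore"),
        registry.hif1_targets, matrix)
    _attempt(
        columns, metadata, "fao_score",
        lambda: score_fao(matrix, registry.fao_enzymes, weights=fao_weights),
        registry.fao_enzymes, matrix)

    frame = pd.DataFrame(
        {name: columns[name] for name in METABOLIC_METRICS if name in columns},
        index=pd.Index(matrix.sample_ids, name="sample"),
    )
    return ScoreTable(matrix.dataset_id, frame, metadata, matrix.sample_groups)
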
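"""End-to-end orchestration: score a cohort, correlate, summarise.

Given a manifest of expression tables, the pipeline scores every dataset
with the EMT and metabolic panels, computes classified pairwise correlations
for a configurable pair list, and writes the cohort summaries (concordance,
Venn agreement patterns, axis counts, modality quadrants) as deterministic
TSV files.  Per-dataset failures are isolated into a failures table; the run
aborts only if no dataset scores at all.  Floating-point cells print at nine
significant digits so identical reruns are byte-identical.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import meta
from .emt_scores import score_emt_panel
from .io import read_expression_matrix
from .metabolic_scores import score_metabolic_panel
from .signatures import load_registry, registry_from_config
from .tables import ScoreTable

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_VENN_SIGNS", "DEFAULT_PAIRS"]

log = logging.getLogger("emtmet")

#: the four representative EMT metric pairs and their expected directions
DEFAULT_VENN_SIGNS: dict[tuple[str, str], str] = {
    ("ks", "hallmark_emt_ssgsea"): "+",
    ("gs76", "ks"): "-",
    ("gs76", "epithelial_singscore"): "+",
    ("gs76", "hallmark_emt_ssgsea"): "-",
}

#: metabolic-axis-vs-EMT pairs examined per dataset
DEFAULT_AXIS_PAIRS: tuple[tuple[str, str], ...] = (
    ("glycolysis_ssgsea", "hallmark_emt_ssgsea"),
    ("oxphos_ssgsea", "hallmark_emt_ssgsea"),
    ("fao_score", "hallmark_emt_ssgsea"),
    ("ampk_singscore", "epithelial_singscore"),
    ("hif1_singscore", "mesenchymal_singscore"),
)

DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    tuple(DEFAULT_VENN_SIGNS) + DEFAULT_AXIS_PAIRS
)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and outputs of one pipeline run."""

    manifest: Path
    out_dir: Path
    registry_dir: Path | None = None
    r_threshold: float = meta.R_THRESHOLD
    p_threshold: float = meta.P_THRESHOLD
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    venn_signs: dict[tuple[str, str], str] = field(
        default_factory=lambda: dict(DEFAULT_VENN_SIGNS)
    )

    def __post_init__(self) -> None:
        self.manifest = Path(self.manifest)
        self.out_dir = Path(self.out_dir)
        if not self.manifest.exists():
            raise FileNotFoundError(self.manifest)
        if not 0 < self.r_threshold < 1:
            raise ValueError("r_threshold must be in (0, 1)")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")


def read_manifest(path: Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"dataset_id", "path"}
    if not required <= set(frame.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    if frame.empty:
        raise ValueError("manifest lists no datasets")
    if frame["dataset_id"].duplicated().any():
        raise ValueError("duplicate dataset ids in manifest")
    if "sample_type" not in frame.columns:
        frame["sample_type"] = "cellline"
    return frame


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.9g")


def score_dataset(matrix, registry, sample_type: str = "cellline") -> ScoreTable:
    """Joint EMT + metabolic score table for one dataset."""
    emt = score_emt_panel(matrix, registry, sample_type=sample_type)
    met = score_metabolic_panel(matrix, registry)
    return emt.join(met)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run score -> correlate -> summarise; returns a summary dict of outputs."""
    out = config.out_dir
    scores_dir = out / "scores"
    scores_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    if config.registry_dir is not None and Path(config.registry_dir).is_file():
        registry = registry_from_config(config.registry_dir)
    else:
        registry = load_registry(config.registry_dir)
    manifest = read_manifest(config.manifest)
    base = config.manifest.parent

    tables: list[ScoreTable] = []
    failures: list[dict] = []
    for row in manifest.itertuples(index=False):
        started = time.perf_counter()
        try:
            path = Path(row.path)
            if not path.is_absolute():
                path = base / path
            matrix = read_expression_matrix(path)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = score_dataset(matrix, registry, sample_type=row.sample_type)
            if not table.metrics:
                raise ValueError("no metric could be computed")
            table.write(scores_dir / f"{row.dataset_id}.scores.tsv")
            tables.append(table)
            log.info(
                "scored %s: %d samples, %d metrics (%.2fs)",
                row.dataset_id, len(table.sample_ids), len(table.metrics),
                time.perf_counter() - started,
            )
        except Exception as exc:  # noqa: BLE001 - fault isolation per dataset
            failures.append({"dataset_id": row.dataset_id, "error": str(exc)})
            log.warning("failed %s: %s", row.dataset_id, exc)

    _write_tsv(pd.DataFrame(failures, columns=["dataset_id", "error"]), out / "failures.tsv")
    if not tables:
        log.removeHandler(handler)
        handler.close()
        raise RuntimeError("no dataset could be processed")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = meta.correlate_cohort(
            tables, config.pairs, config.r_threshold, config.p_threshold
        )
    _write_tsv(meta.records_frame(records), out / "correlations.tsv")

    by_pair: dict[tuple[str, str], list] = {}
    for record in records:
        by_pair.setdefault(record.pair, []).append(record)
    conc_rows = []
    for pair in config.pairs:
        if pair not in by_pair:
            continue
        summary = meta.concordance(by_pair[pair])
        conc_rows.append({
            "metric_a": summary.metric_a, "metric_b": summary.metric_b,
            "n_total": summary.n_total, "n_pos": summary.n_pos,
            "n_neg": summary.n_neg, "n_ns": summary.n_ns,
            "probability": summary.probability, "direction": summary.direction,
            "weighted_probability": summary.weighted_probability,
            "tie": summary.tie,
        })
    _write_tsv(pd.DataFrame(conc_rows), out / "concordance.tsv")

    venn = None
    if all(pair in by_pair for pair in config.venn_signs):
        venn = meta.venn_consistency(records, config.venn_signs)
        venn_rows = [
            {"pattern": "".join(map(str, bits)), "count": count}
            for bits, count in sorted(venn["patterns"].items())
        ]
        _write_tsv(pd.DataFrame(venn_rows), out / "patterns.tsv")

    emt_metric = "hallmark_emt_ssgsea"
    axes = ["glycolysis_ssgsea", "oxphos_ssgsea", "fao_score"]
    axis_records = [
        r for r in records if r.metric_b == emt_metric and r.metric_a in axes
    ]
    axis_counts = meta.axis_count_fractions(axis_records, axes, emt_metric)
    _write_tsv(
        pd.DataFrame({
            "n_significant_axes": list(range(len(axes) + 1)),
            "count": axis_counts["counts"],
            "fraction": axis_counts["fractions"],
        }),
        out / "axis_counts.tsv",
    )

    quad_rows = []
    for axis_a, axis_b in (("glycolysis_ssgsea", "oxphos_ssgsea"),
                           ("oxphos_ssgsea", "fao_score"),
                           ("glycolysis_ssgsea", "fao_score")):
        ra = [r for r in records if r.metric_a == axis_a and r.metric_b == emt_metric]
        rb = [r for r in records if r.metric_a == axis_b and r.metric_b == emt_metric]
        if not ra or not rb:
            continue
        quad = meta.modality_quadrants(ra, rb, axis_a, axis_b)
        for quadrant in meta.QUADRANTS:
            quad_rows.append({
                "axis_a": axis_a, "axis_b": axis_b, "quadrant": quadrant,
                "count": quad["counts"][quadrant],
                "percentage": quad["percentages"][quadrant],
                "n_assigned": quad["n_assigned"], "n_total": quad["n_total"],
            })
    _write_tsv(pd.DataFrame(quad_rows), out / "quadrants.tsv")

    log.info(
        "pipeline complete: %d scored, %d failed, %d correlation records",
        len(tables), len(failures), len(records),
    )
    log.removeHandler(handler)
    handler.close()
    return {
        "n_scored": len(tables),
        "n_failed": len(failures),
        "n_records": len(records),
        "venn": venn,
        "axis_counts": axis_counts,
        "out_dir": str(out),
    }
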
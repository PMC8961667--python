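"""Cohort-level meta-analysis over per-dataset score tables.

For each dataset and metric pair a Pearson correlation is computed and
classified on the volcano-plot rule (significant when p < 0.05 and
|r| > 0.3, the thresholds used throughout the analysis).  Cohort summaries
then quantify how reproducible each association is across datasets:

* concordance -- the majority-direction fraction among significantly
  correlated datasets, optionally weighted by the significant fraction of
  the whole cohort;
* Venn consistency -- per-dataset agreement patterns against expected signs
  for k chosen metric pairs;
* axis-count fractions -- how many of the three metabolic axes correlate
  significantly with the EMT score per dataset;
* modality quadrants -- the joint sign pattern of two metabolic axes'
  EMT correlations;
* group comparison -- Student's t-test between labelled sample groups
  (e.g. treatment time points in a single-cell course).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import ScoreTable

__all__ = [
    "CorrelationRecord",
    "ConcordanceSummary",
    "ModalityAssignment",
    "GroupComparison",
    "correlate",
    "classify",
    "correlate_cohort",
    "concordance",
    "venn_consistency",
    "axis_count_fractions",
    "modality_quadrants",
    "compare_groups",
    "R_THRESHOLD",
    "P_THRESHOLD",
]

#: volcano-plot boundaries: correlation magnitude and p-value cut-offs
R_THRESHOLD = 0.3
P_THRESHOLD = 0.05

QUADRANTS = ("both_pos", "both_neg", "a_pos_b_neg", "a_neg_b_pos")


@dataclass(frozen=True)
class CorrelationRecord:
    """One (dataset, metric pair) Pearson correlation with its volcano class."""

    dataset_id: str
    metric_a: str
    metric_b: str
    r: float
    p: float
    n: int
    klass: str = "NS"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"r out of range: {self.r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p out of range: {self.p}")
        if self.n < 3:
            raise ValueError("a correlation record needs n >= 3")
        if self.klass not in ("POS", "NEG", "NS"):
            raise ValueError(f"unknown class {self.klass!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.metric_a, self.metric_b)


@dataclass(frozen=True)
class ConcordanceSummary:
    """Direction consistency of one metric pair across a cohort of datasets."""

    metric_a: str
    metric_b: str
    n_total: int
    n_pos: int
    n_neg: int
    n_ns: int
    probability: float | None
    direction: str | None
    weighted_probability: float | None
    tie: bool = False

    def __post_init__(self) -> None:
        if self.n_pos + self.n_neg + self.n_ns != self.n_total:
            raise ValueError("POS + NEG + NS must equal the cohort size")


@dataclass(frozen=True)
class ModalityAssignment:
    """Joint sign pattern of two axis-EMT correlations within one dataset."""

    dataset_id: str
    axis_a: str
    axis_b: str
    quadrant: str

    def __post_init__(self) -> None:
        if self.quadrant not in QUADRANTS:
            raise ValueError(f"unknown quadrant {self.quadrant!r}")


@dataclass(frozen=True)
class GroupComparison:
    """Two-group Student's t-test on one metric."""

    metric: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    difference: float
    t: float
    p: float
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------
# Correlation and classification
# ---------------------------------------------------------------------------

def correlate(
    scores: ScoreTable,
    metric_a: str,
    metric_b: str,
    r_threshold: float = R_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> CorrelationRecord | None:
    """Pearson r and two-sided p (t-distribution, n-2 df) for one metric pair.

    Uses pairwise-complete samples.  Returns ``None`` with a warning when
    fewer than 3 complete pairs exist or either metric has zero variance.
    """
    sub = scores.scores[[metric_a, metric_b]].dropna()
    n = len(sub)
    if n < 3:
        warnings.warn(
            f"{scores.dataset_id}: {metric_a} vs {metric_b}: only {n} complete "
            "pair(s); correlation skipped"
        )
        return None
    a = sub[metric_a].to_numpy(dtype=float)
    b = sub[metric_b].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn(
            f"{scores.dataset_id}: {metric_a} vs {metric_b}: zero variance; "
            "correlation skipped"
        )
        return None
    result = stats.pearsonr(a, b)
    record = CorrelationRecord(
        scores.dataset_id, metric_a, metric_b,
        float(np.clip(result.statistic, -1.0, 1.0)), float(result.pvalue), n,
    )
    return classify(record, r_threshold, p_threshold)


def classify(
    record: CorrelationRecord,
    r_threshold: float = R_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> CorrelationRecord:
    """Volcano classification: POS / NEG when p and |r| clear the cut-offs, else NS."""
    if record.p < p_threshold and record.r > r_threshold:
        klass = "POS"
    elif record.p < p_threshold and record.r < -r_threshold:
        klass = "NEG"
    else:
        klass = "NS"
    return CorrelationRecord(
        record.dataset_id, record.metric_a, record.metric_b,
        record.r, record.p, record.n, klass,
    )


def correlate_cohort(
    tables: Iterable[ScoreTable],
    pairs: Sequence[tuple[str, str]],
    r_threshold: float = R_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    fdr: bool = False,
) -> list[CorrelationRecord]:
    """Classified correlation records for every dataset and metric pair.

    ``fdr=True`` applies Benjamini-Hochberg adjustment to the p-values of
    each metric pair across the cohort's datasets before classification
    (off by default: the analysis convention applies no correction).
    """
    records: list[CorrelationRecord] = []
    for table in tables:
        for metric_a, metric_b in pairs:
            if metric_a not in table.metrics or metric_b not in table.metrics:
                warnings.warn(
                    f"{table.dataset_id}: pair ({metric_a}, {metric_b}) not scored"
                )
                continue
            record = correlate(table, metric_a, metric_b, r_threshold, p_threshold)
            if record is not None:
                records.append(record)
    if fdr and records:
        from statsmodels.stats.multitest import multipletests

        adjusted: list[CorrelationRecord] = []
        for pair in {r.pair for r in records}:
            subset = [r for r in records if r.pair == pair]
            q = multipletests([r.p for r in subset], method="fdr_bh")[1]
            adjusted.extend(
                classify(
                    CorrelationRecord(r.dataset_id, r.metric_a, r.metric_b,
                                      r.r, float(qi), r.n),
                    r_threshold, p_threshold,
                )
                for r, qi in zip(subset, q)
            )
        records = sorted(adjusted, key=lambda r: (r.dataset_id, r.pair))
    return records


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def concordance(
    records: Sequence[CorrelationRecord],
    significant_only_denominator: bool = True,
) -> ConcordanceSummary:
    """Majority-direction probability for one metric pair across a cohort.

    probability = max(n_pos, n_neg) / (n_pos + n_neg); the weighted variant
    multiplies by the significant fraction (n_pos + n_neg) / n_total, so it
    equals max(n_pos, n_neg) / n_total.  Both are undefined (None) when no
    dataset is significant.  Direction ties break toward positive with the
    ``tie`` flag set.  ``significant_only_denominator=False`` divides the
    plain probability by n_total instead (the alternative reading of the
    denominator).
    """
    records = list(records)
    if not records:
        raise ValueError("concordance of an empty cohort is undefined")
    pairs = {r.pair for r in records}
    if len(pairs) != 1:
        raise ValueError(f"records mix metric pairs: {sorted(pairs)}")
    metric_a, metric_b = records[0].pair
    n_total = len(records)
    n_pos = sum(r.klass == "POS" for r in records)
    n_neg = sum(r.klass == "NEG" for r in records)
    n_ns = n_total - n_pos - n_neg
    n_sig = n_pos + n_neg
    if n_sig == 0:
        return ConcordanceSummary(
            metric_a, metric_b, n_total, n_pos, n_neg, n_ns,
            probability=None, direction=None, weighted_probability=None,
        )
    tie = n_pos == n_neg
    direction = "positive" if n_pos >= n_neg else "negative"
    denominator = n_sig if significant_only_denominator else n_total
    probability = max(n_pos, n_neg) / denominator
    weighted = probability * n_sig / n_total
    return ConcordanceSummary(
        metric_a, metric_b, n_total, n_pos, n_neg, n_ns,
        probability=probability, direction=direction,
        weighted_probability=weighted, tie=tie,
    )


# ---------------------------------------------------------------------------
# Venn consistency
# ---------------------------------------------------------------------------

def venn_consistency(
    records: Sequence[CorrelationRecord],
    expected_signs: Mapping[tuple[str, str], str],
) -> dict:
    """Agreement-pattern counts over k metric pairs with expected directions.

    ``expected_signs`` maps each pair to "+" or "-".  For every dataset with
    all k pairs present, a k-bit vector marks which pairs match the expected
    sign (POS for "+", NEG for "-"); the result counts datasets per pattern
    (keys are tuples of 0/1 in the pair order of ``expected_signs``).
    Datasets missing any pair are excluded and counted separately.  Pattern
    counts always sum to the number of included datasets.
    """
    pair_order = list(expected_signs)
    for pair, sign in expected_signs.items():
        if sign not in ("+", "-"):
            raise ValueError(f"expected sign for {pair} must be '+' or '-', got {sign!r}")
    known_pairs = {r.pair for r in records}
    unknown = [p for p in pair_order if p not in known_pairs]
    if unknown:
        raise ValueError(f"no records for expected pair(s): {unknown}")

    by_dataset: dict[str, dict[tuple[str, str], str]] = {}
    for record in records:
        if record.pair in expected_signs:
            by_dataset.setdefault(record.dataset_id, {})[record.pair] = record.klass

    patterns: dict[tuple[int, ...], int] = {
        bits: 0 for bits in itertools.product((0, 1), repeat=len(pair_order))
    }
    excluded = 0
    for dataset_id, klasses in sorted(by_dataset.items()):
        if any(pair not in klasses for pair in pair_order):
            excluded += 1
            continue
        bits = tuple(
            int(klasses[pair] == ("POS" if expected_signs[pair] == "+" else "NEG"))
            for pair in pair_order
        )
        patterns[bits] += 1
    return {
        "pairs": pair_order,
        "patterns": patterns,
        "n_included": sum(patterns.values()),
        "n_excluded": excluded,
    }


# ---------------------------------------------------------------------------
# Axis counts and modality quadrants
# ---------------------------------------------------------------------------

def axis_count_fractions(
    records: Sequence[CorrelationRecord],
    axes: Sequence[str],
    emt_metric: str = "hallmark_emt_ssgsea",
) -> dict:
    """Fraction of datasets with 0..k axes significantly EMT-associated.

    ``records`` hold the axis-vs-EMT correlations; a dataset enters the
    denominator only when all ``axes`` were attempted for it.  The returned
    fractions sum to 1 over those complete datasets.
    """
    axes = list(axes)
    by_dataset: dict[str, dict[str, str]] = {}
    for record in records:
        axis = record.metric_a if record.metric_b == emt_metric else (
            record.metric_b if record.metric_a == emt_metric else None
        )
        if axis in axes:
            by_dataset.setdefault(record.dataset_id, {})[axis] = record.klass
    counts = np.zeros(len(axes) + 1, dtype=int)
    incomplete = 0
    for dataset_id, klasses in sorted(by_dataset.items()):
        if any(axis not in klasses for axis in axes):
            incomplete += 1
            continue
        n_sig = sum(klasses[axis] != "NS" for axis in axes)
        counts[n_sig] += 1
    total = int(counts.sum())
    fractions = counts / total if total else counts.astype(float)
    return {
        "axes": axes,
        "counts": counts.tolist(),
        "fractions": fractions.tolist(),
        "n_datasets": total,
        "n_incomplete": incomplete,
    }


def modality_quadrants(
    records_a: Sequence[CorrelationRecord],
    records_b: Sequence[CorrelationRecord],
    axis_a: str,
    axis_b: str,
) -> dict:
    """Quadrant assignment from the signs of two axis-EMT correlations.

    A dataset is assigned only when both its axis-EMT correlations are
    significant; quadrant percentages are over assigned datasets, so
    assigned + unassigned = total datasets seen.
    """
    klass_a = {r.dataset_id: r.klass for r in records_a}
    klass_b = {r.dataset_id: r.klass for r in records_b}
    datasets = sorted(set(klass_a) | set(klass_b))
    assignments: list[ModalityAssignment] = []
    for dataset_id in datasets:
        ka = klass_a.get(dataset_id, "NS")
        kb = klass_b.get(dataset_id, "NS")
        if ka == "NS" or kb == "NS":
            continue
        quadrant = {
            ("POS", "POS"): "both_pos",
            ("NEG", "NEG"): "both_neg",
            ("POS", "NEG"): "a_pos_b_neg",
            ("NEG", "POS"): "a_neg_b_pos",
        }[(ka, kb)]
        assignments.append(ModalityAssignment(dataset_id, axis_a, axis_b, quadrant))
    n_assigned = len(assignments)
    counts = {q: sum(a.quadrant == q for a in assignments) for q in QUADRANTS}
    percentages = {
        q: (100.0 * c / n_assigned if n_assigned else None) for q, c in counts.items()
    }
    return {
        "axis_a": axis_a,
        "axis_b": axis_b,
        "assignments": assignments,
        "counts": counts,
        "percentages": percentages,
        "n_assigned": n_assigned,
        "n_total": len(datasets),
    }


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def compare_groups(
    scores: ScoreTable,
    metric: str,
    group_a: str,
    group_b: str,
    welch: bool = False,
) -> GroupComparison:
    """Student's t-test (equal-variance by default) between two sample groups.

    Groups come from the table's ``sample_groups`` labels; each group needs
    at least 2 samples with the metric present.  ``welch=True`` switches to
    the unequal-variance test.
    """
    if scores.sample_groups is None:
        raise ValueError("score table has no sample_groups")
    if metric not in scores.metrics:
        raise ValueError(f"metric {metric!r} not in table")
    series = scores.metric(metric).dropna()
    values: dict[str, np.ndarray] = {}
    for group in (group_a, group_b):
        members = [s for s, g in scores.sample_groups.items() if g == group and s in series.index]
        if len(members) < 2:
            raise ValueError(f"group {group!r} has {len(members)} scored sample(s); need >= 2")
        values[group] = series.loc[members].to_numpy(dtype=float)
    a, b = values[group_a], values[group_b]
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        metric=metric, group_a=group_a, group_b=group_b,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        difference=float(a.mean() - b.mean()),
        t=float(t), p=float(p), n_a=len(a), n_b=len(b),
    )


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def records_frame(records: Sequence[CorrelationRecord]) -> pd.DataFrame:
    """Correlation records as a tidy DataFrame (dataset, pair, r, p, n, class)."""
    return pd.DataFrame(
        [
            {
                "dataset_id": r.dataset_id, "metric_a": r.metric_a,
                "metric_b": r.metric_b, "r": r.r, "p": r.p, "n": r.n,
                "class": r.klass,
            }
            for r in records
        ]
    )
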
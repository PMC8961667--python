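"""Optional rendering: volcano and concordance bar plots.

Requires matplotlib (the ``plot`` extra); nothing else in the package
imports this module, and no analysis output depends on it.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .meta import ConcordanceSummary, CorrelationRecord, P_THRESHOLD, R_THRESHOLD


def volcano(
    records: Sequence[CorrelationRecord],
    ax=None,
    r_threshold: float = R_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
):
    """Pearson r vs -log10(p) across datasets for one metric pair.

    Vertical boundaries sit at +/- the correlation threshold and the
    horizontal one at the p cut-off; POS/NEG/NS records are coloured
    blue/red/grey.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    colors = {"POS": "tab:blue", "NEG": "tab:red", "NS": "0.6"}
    for klass in ("NS", "POS", "NEG"):
        sub = [r for r in records if r.klass == klass]
        if sub:
            ax.scatter(
                [r.r for r in sub],
                [-np.log10(max(r.p, 1e-300)) for r in sub],
                s=12, c=colors[klass], label=f"{klass} ({len(sub)})",
            )
    ax.axvline(+r_threshold, ls="--", lw=0.8, c="k")
    ax.axvline(-r_threshold, ls="--", lw=0.8, c="k")
    ax.axhline(-np.log10(p_threshold), ls="--", lw=0.8, c="k")
    ax.set_xlim(-1.05, 1.05)
    ax.set_xlabel("Pearson r")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    if records:
        ax.set_title(f"{records[0].metric_a} vs {records[0].metric_b}")
    ax.legend(frameon=False, fontsize=8)
    return ax


def concordance_bars(summaries: Sequence[ConcordanceSummary], ax=None, weighted: bool = False):
    """Concordance probabilities per metric pair, signed by direction."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    labels, values, colors = [], [], []
    for s in summaries:
        p = s.weighted_probability if weighted else s.probability
        if p is None:
            continue
        labels.append(f"{s.metric_a}\nvs {s.metric_b}")
        values.append(p if s.direction == "positive" else -p)
        colors.append("tab:blue" if s.direction == "positive" else "tab:red")
    ax.bar(range(len(values)), values, color=colors)
    ax.set_xticks(range(len(labels)), labels, fontsize=7, rotation=30, ha="right")
    ax.axhline(0, c="k", lw=0.8)
    ax.set_ylabel("weighted probability" if weighted else "probability")
    ax.set_ylim(-1.05, 1.05)
    return ax
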
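"""The sample x metric score table shared by the EMT and metabolic panels."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ScoreTable"]


@dataclass
class ScoreTable:
    """Per-sample scores for one dataset.

    ``scores`` is samples x metrics; a metric that could not be computed is
    absent from the frame, with the reason recorded in ``metadata`` under the
    metric name.  ``sample_groups`` (when the dataset has them, e.g. a
    treatment time course) are carried through for group comparisons.
    """

    dataset_id: str
    scores: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    sample_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.scores.columns.has_duplicates:
            raise ValueError("duplicate metric names")
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate sample ids")

    @property
    def metrics(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def metric(self, name: str) -> pd.Series:
        return self.scores[name]

    def join(self, other: "ScoreTable") -> "ScoreTable":
        """Combine two score tables for the same dataset and samples."""
        if other.dataset_id != self.dataset_id:
            raise ValueError("cannot join score tables from different datasets")
        clash = set(self.metrics) & set(other.metrics)
        if clash:
            raise ValueError(f"duplicate metrics on join: {sorted(clash)}")
        merged = self.scores.join(other.scores, how="inner")
        meta = {**self.metadata, **other.metadata}
        groups = self.sample_groups or other.sample_groups
        return ScoreTable(self.dataset_id, merged, meta, groups)

    # -- canonical TSV + JSON sidecar ------------------------------------

    def write(self, path: str | Path) -> None:
        """Write samples x metrics TSV; metadata goes to ``<path>.meta.json``."""
        path = Path(path)
        with open(path, "wt", encoding="utf-8") as handle:
            handle.write("sample\t" + "\t".join(self.metrics) + "\n")
            for sample, row in zip(self.sample_ids, self.scores.to_numpy()):
                cells = ["%.9g" % v if np.isfinite(v) else "NA" for v in row]
                handle.write(str(sample) + "\t" + "\t".join(cells) + "\n")
        sidecar = {
            "dataset_id": self.dataset_id,
            "metadata": self.metadata,
            "sample_groups": self.sample_groups,
        }
        with open(path.with_suffix(path.suffix + ".meta.json"), "wt", encoding="utf-8") as handle:
            json.dump(sidecar, handle, indent=2, sort_keys=True)
            handle.write("\n")

    @classmethod
    def read(cls, path: str | Path) -> "ScoreTable":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        sidecar_path = path.with_suffix(path.suffix + ".meta.json")
        meta: dict = {}
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text(encoding="utf-8"))
        return cls(
            dataset_id=meta.get("dataset_id", path.stem),
            scores=frame,
            metadata=meta.get("metadata", {}),
            sample_groups=meta.get("sample_groups"),
        )
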
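"""Synthetic expression cohorts with a known epithelial-mesenchymal axis.

The generator draws a latent EMT coordinate phi per sample and builds
log2-scale expression as ``baseline_g + c_g * phi_s + Normal(0, sigma)``:
epithelial-list genes carry coupling ``-emt_coupling`` (they fall as cells
become mesenchymal), mesenchymal and hallmark-EMT genes ``+emt_coupling``,
and each metabolic pathway's genes the signed coupling from the config
(default glycolysis +0.8, OXPHOS / FAO / AMPK -0.8, HIF1 +0.8, matching the
dominant directions the scoring pipeline should recover).  Background genes
are uncoupled noise.  Everything is deterministic under the seed, and the
ground truth (phi, couplings, gene membership) is returned alongside every
dataset so recovery statistics never need to re-inspect generator internals.

Cohorts draw per-dataset couplings from a stated mixture (or an explicit
per-dataset override list), emulating a multi-study compendium in which the
EMT-metabolism coupling direction varies by biological context.  The
time-course generator shifts the phi mean per group (day0 / day7 /
day3_withdrawal) to emulate TGF-beta EMT induction and withdrawal in
single cells, with optional dropout sparsity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, write_expression_tsv
from .signatures import SignatureRegistry, load_registry

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_dataset",
    "generate_cohort",
    "generate_timecourse",
    "write_truth",
    "DEFAULT_COUPLINGS",
]

#: default pathway couplings to the latent EMT axis (sign = direction of
#: association with a more mesenchymal state)
DEFAULT_COUPLINGS: dict[str, float] = {
    "glycolysis": 0.8,
    "oxphos": -0.8,
    "fao": -0.8,
    "ampk": -0.8,
    "hif1": 0.8,
}

#: generator gene groups -> registry slot supplying their symbols
_GROUP_SLOTS = {
    "epithelial": "ks_epithelial_cellline",
    "mesenchymal": "ks_mesenchymal_cellline",
    "gs76": "gs76",
    "hallmark_emt": "hallmark_emt",
    "glycolysis": "hallmark_glycolysis",
    "oxphos": "hallmark_oxphos",
    "ampk": "ampk_targets",
    "hif1": "hif1_targets",
    "fao": "fao_enzymes",
}


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic dataset.

    Defaults are the study conditions the recovery analyses use: 100
    samples, unit EMT coupling, noise sigma 0.5 on a latent axis uniform on
    [-1, 1], and the default metabolic couplings above.
    """

    n_samples: int = 100
    seed: int = 0
    dataset_id: str = "synthetic"
    emt_axis_distribution: str = "uniform"
    emt_coupling: float = 1.0
    couplings: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COUPLINGS))
    noise_sigma: float = 0.5
    signature_sizes: dict[str, int] | None = None
    n_background: int = 200
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    platform: str = "microarray"
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.emt_axis_distribution not in ("uniform", "bimodal"):
            raise ValueError("emt_axis_distribution must be 'uniform' or 'bimodal'")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        allowed = set(DEFAULT_COUPLINGS) | {
            "epithelial", "mesenchymal", "gs76", "hallmark_emt",
        }
        unknown = set(self.couplings) - allowed
        if unknown:
            raise ValueError(f"unknown pathway coupling(s): {sorted(unknown)}")
        bad = {k: v for k, v in self.couplings.items() if not -1.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"couplings must lie in [-1, 1]: {bad}")
        if self.signature_sizes:
            unknown = set(self.signature_sizes) - set(_GROUP_SLOTS)
            if unknown:
                raise ValueError(f"unknown signature size key(s): {sorted(unknown)}")
            small = {k: v for k, v in self.signature_sizes.items() if v < 2}
            if small:
                raise ValueError(f"signature sizes must be >= 2: {small}")


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside a generated dataset."""

    dataset_id: str
    phi: pd.Series
    couplings: dict[str, float]
    membership: dict[str, str]

    def group_genes(self, group: str) -> list[str]:
        return [g for g, grp in self.membership.items() if grp == group]


def _group_genes(config: SyntheticConfig, registry: SignatureRegistry) -> dict[str, list[str]]:
    sizes = config.signature_sizes or {}
    groups: dict[str, list[str]] = {}
    seen: set[str] = set()
    for group, slot in _GROUP_SLOTS.items():
        genes = list(registry[slot].genes)
        if group == "gs76":
            # CDH1 anchors the 76GS list but is generated as an epithelial gene
            genes = [g for g in genes if g != "CDH1"]
        if group in sizes:
            genes = genes[: sizes[group]]
        overlap = seen & set(genes)
        if overlap:
            raise ValueError(
                f"signature groups must be disjoint; {group!r} shares {sorted(overlap)[:5]}"
            )
        seen |= set(genes)
        groups[group] = genes
    groups["background"] = [f"BGD{i:04d}" for i in range(1, config.n_background + 1)]
    return groups


def _draw_phi(rng: np.random.Generator, config: SyntheticConfig, n: int) -> np.ndarray:
    if config.emt_axis_distribution == "uniform":
        return rng.uniform(-1.0, 1.0, size=n)
    centre = rng.choice([-1.0, 1.0], size=n)
    return centre + rng.normal(0.0, 0.3, size=n)


def _effective_couplings(config: SyntheticConfig) -> dict[str, float]:
    c = config.emt_coupling
    eff = {
        "epithelial": -c,
        "mesenchymal": +c,
        "gs76": -c,
        "hallmark_emt": +c,
        "background": 0.0,
    }
    eff.update({k: float(v) for k, v in config.couplings.items()})
    for pathway in DEFAULT_COUPLINGS:
        eff.setdefault(pathway, 0.0)
    return eff


def _assemble(
    config: SyntheticConfig,
    registry: SignatureRegistry,
    phi: np.ndarray,
    sample_ids: list[str],
    rng: np.random.Generator,
    sample_groups: dict[str, str] | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    groups = _group_genes(config, registry)
    eff = _effective_couplings(config)
    gene_ids: list[str] = []
    coupling_per_gene: list[float] = []
    membership: dict[str, str] = {}
    for group, genes in groups.items():
        gene_ids.extend(genes)
        coupling_per_gene.extend([eff[group]] * len(genes))
        for g in genes:
            membership[g] = group
    c = np.array(coupling_per_gene)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=len(gene_ids))
    noise = rng.normal(0.0, config.noise_sigma, size=(len(gene_ids), len(sample_ids)))
    values = baseline[:, None] + c[:, None] * phi[None, :] + noise
    if config.dropout_rate > 0:
        dropped = rng.random(values.shape) < config.dropout_rate
        values = np.where(dropped, 0.0, values)
    frame = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    matrix = ExpressionMatrix(
        frame,
        dataset_id=config.dataset_id,
        platform=config.platform,
        sample_groups=sample_groups,
        provenance={"synthetic": True, "seed": int(config.seed), "log2": True},
    )
    truth = SyntheticTruth(
        dataset_id=config.dataset_id,
        phi=pd.Series(phi, index=sample_ids, name="phi"),
        couplings=eff,
        membership=membership,
    )
    return matrix, truth


def generate_dataset(
    config: SyntheticConfig,
    registry: SignatureRegistry | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate one dataset plus its ground truth, deterministically from the seed."""
    registry = registry if registry is not None else load_registry()
    rng = np.random.default_rng(config.seed)
    sample_ids = [f"S{i:04d}" for i in range(1, config.n_samples + 1)]
    phi = _draw_phi(rng, config, config.n_samples)
    return _assemble(config, registry, phi, sample_ids, rng)


def generate_cohort(
    n_datasets: int,
    seed: int = 0,
    base_config: SyntheticConfig | None = None,
    mixture: Sequence[tuple[float, dict]] | None = None,
    overrides_per_dataset: Sequence[dict] | None = None,
    registry: SignatureRegistry | None = None,
) -> list[tuple[ExpressionMatrix, SyntheticTruth]]:
    """Generate a multi-dataset cohort.

    ``mixture`` is a sequence of ``(weight, config_overrides)``; each dataset
    independently draws one component (weights need not be normalised), so a
    70/30 mixture of coupling patterns produces binomially distributed
    composition.  ``overrides_per_dataset`` instead fixes the override dict
    of every dataset exactly (length ``n_datasets``), for cohorts with an
    exact composition.  Overrides may set any config field;
    ``couplings`` overrides are merged entry-wise into the base couplings.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    if mixture is not None and overrides_per_dataset is not None:
        raise ValueError("give either mixture or overrides_per_dataset, not both")
    if overrides_per_dataset is not None and len(overrides_per_dataset) != n_datasets:
        raise ValueError("overrides_per_dataset must have one entry per dataset")
    base = base_config if base_config is not None else SyntheticConfig()
    registry = registry if registry is not None else load_registry()
    rng = np.random.default_rng(seed)

    if mixture is not None:
        weights = np.array([w for w, _ in mixture], dtype=float)
        if (weights < 0).any() or weights.sum() == 0:
            raise ValueError("mixture weights must be non-negative and not all zero")
        weights = weights / weights.sum()

    cohort: list[tuple[ExpressionMatrix, SyntheticTruth]] = []
    for i in range(n_datasets):
        child_seed = int(rng.integers(0, 2**31 - 1))
        overrides: dict = {}
        if mixture is not None:
            overrides = dict(mixture[int(rng.choice(len(mixture), p=weights))][1])
        elif overrides_per_dataset is not None:
            overrides = dict(overrides_per_dataset[i])
        couplings = dict(base.couplings)
        couplings.update(overrides.pop("couplings", {}))
        config = replace(
            base,
            seed=child_seed,
            dataset_id=f"D{i + 1:04d}",
            couplings=couplings,
            **overrides,
        )
        cohort.append(generate_dataset(config, registry))
    return cohort


def generate_timecourse(
    config: SyntheticConfig | None = None,
    shifts: Mapping[str, float] | None = None,
    n_cells_per_group: int = 200,
    phi_sd: float = 0.5,
    groups: Sequence[str] | None = None,
    registry: SignatureRegistry | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Single-cell treatment/withdrawal time course.

    ``shifts`` maps each group label to its latent-axis offset; the default
    emulates 7-day EMT induction followed by partial reversal on withdrawal:
    ``{"day0": 0.0, "day7": 1.0, "day3_withdrawal": 0.5}``.  Cells draw
    ``phi = shift + Normal(0, phi_sd)``.  When an explicit ``groups`` list is
    given, every shift key must belong to it.
    """
    config = config if config is not None else SyntheticConfig(platform="rnaseq_singlecell")
    if config.platform != "rnaseq_singlecell":
        config = replace(config, platform="rnaseq_singlecell")
    shifts = dict(shifts) if shifts is not None else {
        "day0": 0.0, "day7": 1.0, "day3_withdrawal": 0.5,
    }
    if groups is not None:
        unknown = set(shifts) - set(groups)
        if unknown:
            raise ValueError(f"shift(s) for unknown group(s): {sorted(unknown)}")
    if len(shifts) < 2:
        raise ValueError("a time course needs at least 2 groups")
    registry = registry if registry is not None else load_registry()
    rng = np.random.default_rng(config.seed)
    sample_ids: list[str] = []
    sample_groups: dict[str, str] = {}
    phi_parts: list[np.ndarray] = []
    for group, shift in shifts.items():
        ids = [f"{group}_C{i:04d}" for i in range(1, n_cells_per_group + 1)]
        sample_ids.extend(ids)
        sample_groups.update({s: group for s in ids})
        phi_parts.append(shift + rng.normal(0.0, phi_sd, size=n_cells_per_group))
    phi = np.concatenate(phi_parts)
    matrix, truth = _assemble(config, registry, phi, sample_ids, rng, sample_groups)
    return matrix, truth


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Write the ground-truth sidecar as JSON."""
    payload = {
        "dataset_id": truth.dataset_id,
        "phi": {s: float(v) for s, v in truth.phi.items()},
        "couplings": truth.couplings,
        "membership": truth.membership,
    }
    with open(path, "wt", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")


def write_cohort(
    cohort: Sequence[tuple[ExpressionMatrix, SyntheticTruth]],
    directory: str | Path,
) -> Path:
    """Write a cohort as canonical TSVs + truth sidecars + a manifest TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for matrix, truth in cohort:
        data_path = directory / f"{matrix.dataset_id}.tsv"
        write_expression_tsv(matrix, data_path)
        write_truth(truth, directory / f"{matrix.dataset_id}.truth.json")
        rows.append((matrix.dataset_id, data_path.name, matrix.platform, "cellline"))
    manifest = directory / "manifest.tsv"
    with open(manifest, "wt", encoding="utf-8") as handle:
        handle.write("dataset_id\tpath\tplatform\tsample_type\n")
        for row in rows:
            handle.write("\t".join(row) + "\n")
    return manifest
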
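"""Gene signatures, the bundled signature registry, and coverage checks.

A :class:`GeneSignature` is a named, ordered list of unique gene symbols with
an optional direction (epithelial / mesenchymal / up) and optional per-gene
weights.  The :class:`SignatureRegistry` bundles the nine signature slots the
scoring panels need: the hallmark EMT / glycolysis / OXPHOS sets, the KS
epithelial-mesenchymal pairs for cell-line and tumor samples, the 76-gene
epithelial scoring list, AMPK and HIF1-alpha target lists, and the FAO enzyme
list.

The GMT files shipped inside the package are synthetic placeholders (dummy
symbols with the published cardinalities; see ``data/signatures/README.txt``).
Real analyses should point :func:`load_registry` at a directory of genuine
GMT files; any slot can be overridden individually.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GeneSignature",
    "CoverageReport",
    "SignatureRegistry",
    "coverage",
    "load_registry",
    "registry_from_config",
    "read_gmt",
    "MIN_COVERAGE",
]

#: Minimum fraction of a signature's genes that must be present in a dataset
#: for the corresponding score to be computed; below this the score is
#: reported as missing with a warning.
MIN_COVERAGE = 0.5

_DIRECTIONS = ("up", "epithelial", "mesenchymal", "neutral")


def _normalize_symbol(gene: str) -> str:
    return gene.strip().upper()


@dataclass
class GeneSignature:
    """A named gene set with optional direction and weights.

    Parameters
    ----------
    name : str
        Signature name (GMT first field).
    genes : sequence of str
        Gene symbols; case-normalised to upper case, order preserved,
        duplicates rejected.
    direction : {"up", "epithelial", "mesenchymal", "neutral"}
        Biological direction of the set, used only for bookkeeping.
    weights : mapping gene -> float, optional
        Per-gene weights (used by externally supplied FAO coefficients);
        keys must be a subset of ``genes``.
    expected_size : int, optional
        Published size of the signature; a mismatch at load time emits a
        warning, never an error.
    """

    name: str
    genes: tuple[str, ...]
    direction: str = "neutral"
    weights: dict[str, float] | None = None
    expected_size: int | None = None
    description: str = ""

    def __post_init__(self) -> None:
        genes = tuple(_normalize_symbol(g) for g in self.genes)
        if len(set(genes)) != len(genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")
        if not genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if self.direction not in _DIRECTIONS:
            raise ValueError(
                f"direction must be one of {_DIRECTIONS}, got {self.direction!r}"
            )
        object.__setattr__(self, "genes", genes)
        if self.weights is not None:
            weights = {_normalize_symbol(k): float(v) for k, v in self.weights.items()}
            unknown = set(weights) - set(genes)
            if unknown:
                raise ValueError(
                    f"weights for genes not in signature {self.name!r}: {sorted(unknown)}"
                )
            self.weights = weights
        if self.expected_size is not None and len(genes) != self.expected_size:
            warnings.warn(
                f"signature {self.name!r} has {len(genes)} genes, "
                f"expected {self.expected_size}",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return _normalize_symbol(gene) in set(self.genes)


@dataclass(frozen=True)
class CoverageReport:
    """How much of a signature a dataset's gene universe covers."""

    signature: str
    n_found: int
    n_total: int
    missing: tuple[str, ...]

    @property
    def fraction(self) -> float:
        return self.n_found / self.n_total

    @property
    def sufficient(self) -> bool:
        return self.fraction >= MIN_COVERAGE


def coverage(signature: GeneSignature, gene_ids: Iterable[str]) -> CoverageReport:
    """Report the overlap between ``signature`` and a gene universe.

    ``gene_ids`` may be an iterable of symbols or anything exposing
    ``.gene_ids`` (e.g. an :class:`~emtmet.io.ExpressionMatrix`).
    """
    if hasattr(gene_ids, "gene_ids"):
        gene_ids = gene_ids.gene_ids
    universe = {_normalize_symbol(g) for g in gene_ids}
    missing = tuple(g for g in signature.genes if g not in universe)
    n_found = len(signature.genes) - len(missing)
    return CoverageReport(signature.name, n_found, len(signature.genes), missing)


# ---------------------------------------------------------------------------
# GMT reading
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, direction: str = "neutral") -> list[GeneSignature]:
    """Read a GMT v2 file: one signature per line, ``name<TAB>desc<TAB>genes...``.

    Duplicate genes within a line are de-duplicated with a warning; lines with
    fewer than three fields raise with the offending line number.  An empty
    file yields an empty list.
    """
    signatures: list[GeneSignature] = []
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need name, description "
                    f"and at least one gene ({len(fields)} fields found)"
                )
            name, desc, *genes = fields
            genes = [_normalize_symbol(g) for g in genes if g.strip()]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                warnings.warn(
                    f"{path}: line {lineno}: duplicate genes in {name!r} "
                    "de-duplicated",
                    stacklevel=2,
                )
            signatures.append(
                GeneSignature(name, tuple(unique), direction=direction, description=desc)
            )
    return signatures


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

#: slot -> (filename, number of GMT lines, expected sizes per line, directions)
_SLOT_FILES: dict[str, tuple[str, int, tuple[int | None, ...], tuple[str, ...]]] = {
    "hallmark_emt": ("hallmark_emt.synthetic.gmt", 1, (None,), ("mesenchymal",)),
    "hallmark_glycolysis": ("hallmark_glycolysis.synthetic.gmt", 1, (None,), ("up",)),
    "hallmark_oxphos": ("hallmark_oxphos.synthetic.gmt", 1, (None,), ("up",)),
    "ks_cellline": (
        "ks_cellline.synthetic.gmt", 2, (None, None), ("epithelial", "mesenchymal"),
    ),
    "ks_tumor": (
        "ks_tumor.synthetic.gmt", 2, (None, None), ("epithelial", "mesenchymal"),
    ),
    "gs76": ("gs76.synthetic.gmt", 1, (76,), ("epithelial",)),
    "ampk_targets": ("ampk_targets.synthetic.gmt", 1, (33,), ("up",)),
    "hif1_targets": ("hif1_targets.synthetic.gmt", 1, (23,), ("up",)),
    "fao_enzymes": ("fao_enzymes.synthetic.gmt", 1, (14,), ("up",)),
}

#: published combined sizes for the KS pairs (cell line 218, tumor 315)
_KS_PAIR_SIZES = {"ks_cellline": 218, "ks_tumor": 315}


@dataclass
class SignatureRegistry:
    """The nine signature slots used by the EMT and metabolic panels."""

    hallmark_emt: GeneSignature
    hallmark_glycolysis: GeneSignature
    hallmark_oxphos: GeneSignature
    ks_epithelial_cellline: GeneSignature
    ks_mesenchymal_cellline: GeneSignature
    ks_epithelial_tumor: GeneSignature
    ks_mesenchymal_tumor: GeneSignature
    gs76: GeneSignature
    ampk_targets: GeneSignature
    hif1_targets: GeneSignature
    fao_enzymes: GeneSignature
    source: str = "bundled-synthetic"
    extra: dict[str, GeneSignature] = field(default_factory=dict)

    def ks_pair(self, sample_type: str = "cellline") -> tuple[GeneSignature, GeneSignature]:
        """Return the (epithelial, mesenchymal) KS pair for a sample type."""
        if sample_type == "cellline":
            return self.ks_epithelial_cellline, self.ks_mesenchymal_cellline
        if sample_type == "tumor":
            return self.ks_epithelial_tumor, self.ks_mesenchymal_tumor
        raise ValueError(f"sample_type must be 'cellline' or 'tumor', got {sample_type!r}")

    def __getitem__(self, name: str) -> GeneSignature:
        if name in self.extra:
            return self.extra[name]
        try:
            sig = getattr(self, name)
        except AttributeError:
            raise KeyError(name) from None
        if not isinstance(sig, GeneSignature):
            raise KeyError(name)
        return sig


def _bundled_dir() -> Path:
    return Path(resources.files("emtmet").joinpath("data", "signatures"))


def load_registry(
    directory: str | Path | None = None,
    overrides: Mapping[str, str | Path] | None = None,
) -> SignatureRegistry:
    """Load the signature registry from ``directory`` (default: bundled files).

    ``overrides`` maps slot names (``hallmark_emt``, ``ks_cellline``, ...) to
    alternative GMT paths.  Size checks against the published cardinalities
    warn rather than fail; a missing file raises naming the slot.  Loading is
    deterministic and independent of directory listing order because slots are
    resolved by fixed file names.
    """
    base = Path(directory) if directory is not None else _bundled_dir()
    overrides = dict(overrides or {})

    loaded: dict[str, list[GeneSignature]] = {}
    for slot, (fname, n_lines, sizes, directions) in _SLOT_FILES.items():
        path = Path(overrides[slot]) if slot in overrides else base / fname
        if not path.exists() and slot not in overrides and directory is not None:
            # allow plain (non-.synthetic) file names in user directories
            alt = base / fname.replace(".synthetic", "")
            if alt.exists():
                path = alt
        if not path.exists():
            raise FileNotFoundError(
                f"registry slot {slot!r}: signature file {path} not found"
            )
        sigs = read_gmt(path)
        if len(sigs) != n_lines:
            raise ValueError(
                f"registry slot {slot!r}: expected {n_lines} signature line(s) "
                f"in {path}, found {len(sigs)}"
            )
        for sig, size, direction in zip(sigs, sizes, directions):
            sig.direction = direction
            if size is not None and len(sig) != size:
                warnings.warn(
                    f"registry slot {slot!r}: {sig.name} has {len(sig)} genes, "
                    f"published size is {size}",
                    stacklevel=2,
                )
        loaded[slot] = sigs

    for slot, total in _KS_PAIR_SIZES.items():
        combined = sum(len(s) for s in loaded[slot])
        if combined != total:
            warnings.warn(
                f"registry slot {slot!r}: combined E+M size {combined} differs "
                f"from published total {total}",
                stacklevel=2,
            )

    registry = SignatureRegistry(
        hallmark_emt=loaded["hallmark_emt"][0],
        hallmark_glycolysis=loaded["hallmark_glycolysis"][0],
        hallmark_oxphos=loaded["hallmark_oxphos"][0],
        ks_epithelial_cellline=loaded["ks_cellline"][0],
        ks_mesenchymal_cellline=loaded["ks_cellline"][1],
        ks_epithelial_tumor=loaded["ks_tumor"][0],
        ks_mesenchymal_tumor=loaded["ks_tumor"][1],
        gs76=loaded["gs76"][0],
        ampk_targets=loaded["ampk_targets"][0],
        hif1_targets=loaded["hif1_targets"][0],
        fao_enzymes=loaded["fao_enzymes"][0],
        source=str(base) if directory is not None else "bundled-synthetic",
    )
    return registry


def registry_from_config(path: str | Path) -> SignatureRegistry:
    """Load a registry from a YAML config: slot name -> GMT path.

    The optional ``directory`` key sets the base directory for unlisted
    slots (default: bundled files); relative override paths resolve
    against the config file's directory.
    """
    import yaml

    path = Path(path)
    with open(path, "rt", encoding="utf-8") as handle:
        config = yaml.safe_load(handle) or {}
    if not isinstance(config, dict):
        raise ValueError(f"{path}: registry config must be a mapping")
    directory = config.pop("directory", None)
    unknown = set(config) - set(_SLOT_FILES)
    if unknown:
        raise ValueError(f"{path}: unknown registry slot(s): {sorted(unknown)}")
    overrides = {
        slot: (path.parent / p if not Path(p).is_absolute() else Path(p))
        for slot, p in config.items()
    }
    return load_registry(directory, overrides=overrides)
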
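"""Per-sample signature scorers as scikit-learn estimators.

Every scorer follows the transformer contract: ``fit`` learns whatever
dataset-level state the method needs (76GS learns CDH1-correlation weights
and the centering mean, ssGSEA the enrichment-score range used for
normalisation, the FAO scorer per-gene z-score moments), ``transform``
returns an ``(n_samples, 1)`` array of scores, and fitted attributes carry a
trailing underscore.  ``X`` is samples x genes: a pandas DataFrame with gene
symbols as columns, or an :class:`~emtmet.io.ExpressionMatrix` (transposed
internally).

Scorers:

``GS76Scorer``
    Weighted sum of signature-gene expression; the weight of each gene is
    its Pearson correlation with CDH1 across the samples of the dataset, and
    scores are centered to cohort mean zero.  Higher = more epithelial.
``KSScorer``
    Signed two-sample Kolmogorov-Smirnov distance between a sample's
    mesenchymal-gene and epithelial-gene expression distributions, in
    [-1, 1]; positive = mesenchymal.
``SsgseaScorer``
    Single-sample gene-set enrichment: rank-weighted running-sum difference
    between the in-set and out-of-set empirical distribution functions; the
    normalised score divides by the ES range across the dataset's samples.
``SingscoreScorer``
    Normalised mean rank of the signature genes, mapped onto [-1, 1] using
    its analytic extremes.
``FAOScorer``
    Weighted mean of per-gene z-scores over the fatty-acid-oxidation enzyme
    genes (weights default to 1, external coefficient vectors pluggable).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .signatures import MIN_COVERAGE, GeneSignature

__all__ = [
    "GS76Scorer",
    "KSScorer",
    "SsgseaScorer",
    "SingscoreScorer",
    "FAOScorer",
    "InsufficientCoverageError",
]


class InsufficientCoverageError(ValueError):
    """Raised when too few of a signature's genes are present to score."""


def _as_sample_frame(X) -> pd.DataFrame:
    """Coerce input to a samples x genes DataFrame with upper-case gene columns."""
    if hasattr(X, "to_frame") and hasattr(X, "gene_ids"):  # ExpressionMatrix
        frame = X.to_frame()
    elif isinstance(X, pd.DataFrame):
        frame = X.copy()
        frame.columns = [str(c).strip().upper() for c in frame.columns]
    else:
        raise TypeError(
            "X must be a samples x genes DataFrame or an ExpressionMatrix, "
            f"got {type(X).__name__}"
        )
    arr = frame.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("X contains non-finite values")
    return frame


def _present_genes(signature: GeneSignature, columns, minimum: int = 1) -> list[str]:
    universe = set(columns)
    present = [g for g in signature.genes if g in universe]
    frac = len(present) / len(signature.genes)
    if frac < MIN_COVERAGE or len(present) < minimum:
        raise InsufficientCoverageError(
            f"signature {signature.name!r}: {len(present)}/{len(signature.genes)} "
            f"genes present (coverage {frac:.2f} < {MIN_COVERAGE} or fewer than "
            f"{minimum})"
        )
    if len(present) < len(signature.genes):
        warnings.warn(
            f"signature {signature.name!r}: scoring over the {len(present)} of "
            f"{len(signature.genes)} genes present",
            stacklevel=3,
        )
    return present


def _rank_rows(values: np.ndarray) -> np.ndarray:
    """Ascending average ranks per row (sample); shape preserved."""
    return np.apply_along_axis(rankdata, 1, values)


# ---------------------------------------------------------------------------
# 76GS
# ---------------------------------------------------------------------------

class GS76Scorer(TransformerMixin, BaseEstimator):
    """CDH1-anchored weighted-sum EMT score (higher = more epithelial).

    ``fit`` derives per-gene weights as the Pearson correlation of each
    signature gene with the anchor gene (CDH1) across the fitted dataset's
    samples, and records the cohort mean of the raw weighted sums so that
    ``transform`` on the same samples is centered to mean zero.

    Parameters
    ----------
    signature : GeneSignature
        The 76-gene list (scored over the subset present in the data).
    anchor : str, default "CDH1"
        Epithelial anchor gene; absent or zero-variance anchor is an error.

    Attributes
    ----------
    genes_ : list of str -- signature genes used (present in the data).
    weights_ : pandas.Series -- correlation weight per used gene.
    center_ : float -- cohort mean subtracted from raw scores.
    """

    def __init__(self, signature: GeneSignature, anchor: str = "CDH1"):
        self.signature = signature
        self.anchor = anchor

    def fit(self, X, y=None):
        frame = _as_sample_frame(X)
        if frame.shape[0] < 3:
            raise ValueError("76GS needs at least 3 samples to estimate correlations")
        anchor = self.anchor.strip().upper()
        if anchor not in frame.columns:
            raise ValueError(f"anchor gene {anchor!r} absent from the matrix")
        a = frame[anchor].to_numpy(dtype=float)
        if np.std(a) == 0:
            raise ValueError(f"anchor gene {anchor!r} has zero variance")
        genes = _present_genes(self.signature, frame.columns, minimum=1)
        sub = frame[genes].to_numpy(dtype=float)
        a_c = a - a.mean()
        sub_c = sub - sub.mean(axis=0)
        denom = np.sqrt((sub_c**2).sum(axis=0)) * np.sqrt((a_c**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            weights = (sub_c * a_c[:, None]).sum(axis=0) / denom
        flat = ~np.isfinite(weights)
        if flat.any():
            warnings.warn(
                f"{int(flat.sum())} signature gene(s) with zero variance get weight 0"
            )
            weights = np.where(flat, 0.0, weights)
        self.genes_ = list(genes)
        self.weights_ = pd.Series(weights, index=genes, name="weight")
        self.center_ = float((sub @ weights).mean())
        self.n_features_in_ = frame.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        frame = _as_sample_frame(X)
        missing = [g for g in self.genes_ if g not in frame.columns]
        if missing:
            raise ValueError(f"fitted genes absent from X: {missing[:5]}")
        raw = frame[self.genes_].to_numpy(dtype=float) @ self.weights_.to_numpy()
        return (raw - self.center_).reshape(-1, 1)

    def score_samples(self, X) -> pd.Series:
        frame = _as_sample_frame(X)
        return pd.Series(self.transform(frame)[:, 0], index=frame.index, name="gs76")


# ---------------------------------------------------------------------------
# KS
# ---------------------------------------------------------------------------

def signed_ks_statistic(epithelial: np.ndarray, mesenchymal: np.ndarray) -> float:
    """Signed two-sample KS distance between M- and E-gene expression values.

    Returns +D when the mesenchymal distribution is stochastically larger
    (the one-sided statistic favouring M > E dominates), -D otherwise; an
    exact tie of the two one-sided statistics returns 0.  |D| <= 1.
    """
    e = np.sort(np.asarray(epithelial, dtype=float))
    m = np.sort(np.asarray(mesenchymal, dtype=float))
    pool = np.concatenate([e, m])
    f_e = np.searchsorted(e, pool, side="right") / e.size
    f_m = np.searchsorted(m, pool, side="right") / m.size
    diff = f_e - f_m
    d_plus = float(diff.max())   # evidence that M is shifted up (F_M below F_E)
    d_minus = float((-diff).max())
    if d_plus > d_minus:
        return d_plus
    if d_minus > d_plus:
        return -d_minus
    return 0.0


class KSScorer(TransformerMixin, BaseEstimator):
    """Signed KS EMT score in [-1, 1]; positive = mesenchymal.

    Per sample, the empirical CDFs of the sample's expression over the
    epithelial and the mesenchymal gene list are compared; the score is the
    two-sample KS distance signed by which side is stochastically larger.
    Stateless apart from resolving which signature genes are present.
    """

    def __init__(self, epithelial: GeneSignature, mesenchymal: GeneSignature):
        self.epithelial = epithelial
        self.mesenchymal = mesenchymal

    def fit(self, X, y=None):
        frame = _as_sample_frame(X)
        self.genes_e_ = _present_genes(self.epithelial, frame.columns, minimum=2)
        self.genes_m_ = _present_genes(self.mesenchymal, frame.columns, minimum=2)
        overlap = set(self.genes_e_) & set(self.genes_m_)
        if overlap:
            raise ValueError(f"genes on both E and M lists: {sorted(overlap)[:5]}")
        self.n_features_in_ = frame.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        frame = _as_sample_frame(X)
        e = frame[self.genes_e_].to_numpy(dtype=float)
        m = frame[self.genes_m_].to_numpy(dtype=float)
        out = np.array(
            [signed_ks_statistic(e[i], m[i]) for i in range(frame.shape[0])]
        )
        return out.reshape(-1, 1)

    def score_samples(self, X) -> pd.Series:
        frame = _as_sample_frame(X)
        return pd.Series(self.transform(frame)[:, 0], index=frame.index, name="ks")


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

class SsgseaScorer(TransformerMixin, BaseEstimator):
    """Single-sample GSEA enrichment score with range normalisation.

    Per sample, genes are ranked by expression (ascending average ranks, so
    the top gene carries rank N).  Walking the list from the highest-ranked
    gene down, the enrichment score is the sum over positions of the
    difference between the in-set ECDF, weighted by rank**alpha, and the
    unweighted out-of-set ECDF.  The normalised score (NES) divides each
    sample's ES by the range (max - min) of ES across the samples seen at
    ``fit`` time; ``normalize=False`` returns raw ES.

    A monotone transform of one sample's expression leaves its ES unchanged
    (the statistic depends on ranks only).
    """

    def __init__(self, signature: GeneSignature, alpha: float = 0.25, normalize: bool = True):
        self.signature = signature
        self.alpha = alpha
        self.normalize = normalize

    def _raw_es(self, frame: pd.DataFrame) -> np.ndarray:
        genes = self.genes_
        n_genes = frame.shape[1]
        in_set = np.isin(np.array(frame.columns), np.array(genes))
        n_out = n_genes - int(in_set.sum())
        values = frame.to_numpy(dtype=float)
        ranks = _rank_rows(values)
        es = np.empty(frame.shape[0])
        for i in range(frame.shape[0]):
            # descending expression; stable sort keeps tied genes in column order
            order = np.argsort(-values[i], kind="stable")
            inset = in_set[order]
            w = np.where(inset, ranks[i, order] ** self.alpha, 0.0)
            p_in = np.cumsum(w) / w.sum()
            p_out = np.cumsum(~inset) / n_out
            es[i] = float((p_in - p_out).sum())
        return es

    def fit(self, X, y=None):
        frame = _as_sample_frame(X)
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        self.genes_ = _present_genes(self.signature, frame.columns, minimum=2)
        if len(self.genes_) >= frame.shape[1]:
            raise ValueError("signature covers every gene: empty out-of-set")
        if frame.shape[1] < 2 * len(self.genes_):
            warnings.warn(
                "gene universe is under twice the signature size; enrichment "
                "scores may be unstable"
            )
        es = self._raw_es(frame)
        self.es_min_ = float(es.min())
        self.es_max_ = float(es.max())
        self.n_features_in_ = frame.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        frame = _as_sample_frame(X)
        es = self._raw_es(frame)
        if not self.normalize:
            return es.reshape(-1, 1)
        span = self.es_max_ - self.es_min_
        if span == 0:
            warnings.warn(
                "ES range across fitted samples is zero (single sample or "
                "identical samples); returning unnormalised ES"
            )
            return es.reshape(-1, 1)
        return (es / span).reshape(-1, 1)

    def score_samples(self, X) -> pd.Series:
        frame = _as_sample_frame(X)
        name = f"{self.signature.name.lower()}_ssgsea"
        return pd.Series(self.transform(frame)[:, 0], index=frame.index, name=name)


# ---------------------------------------------------------------------------
# Singscore
# ---------------------------------------------------------------------------

class SingscoreScorer(TransformerMixin, BaseEstimator):
    """Rank-based single-sample signature score in [-1, 1].

    Per sample all genes are ranked ascending (average ranks for ties); the
    mean rank m of the signature genes is normalised by its analytic
    extremes -- (|S|+1)/2 when the signature genes are the lowest-expressed,
    N - (|S|-1)/2 when they are the highest -- onto [0, 1] and mapped
    linearly to [-1, 1].  A sample whose signature genes occupy the top |S|
    ranks scores exactly +1, the bottom |S| exactly -1.
    """

    def __init__(self, signature: GeneSignature):
        self.signature = signature

    def fit(self, X, y=None):
        frame = _as_sample_frame(X)
        self.genes_ = _present_genes(self.signature, frame.columns, minimum=2)
        if len(self.genes_) >= frame.shape[1]:
            raise ValueError(
                "signature covers every gene in the matrix: mean-rank "
                "normalisation is degenerate"
            )
        self.n_features_in_ = frame.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        frame = _as_sample_frame(X)
        n_genes = frame.shape[1]
        size = len(self.genes_)
        in_set = np.isin(np.array(frame.columns), np.array(self.genes_))
        ranks = _rank_rows(frame.to_numpy(dtype=float))
        mean_rank = ranks[:, in_set].mean(axis=1)
        lo = (size + 1) / 2.0
        hi = n_genes - (size - 1) / 2.0
        unit = (mean_rank - lo) / (hi - lo)
        return (2.0 * unit - 1.0).reshape(-1, 1)

    def score_samples(self, X) -> pd.Series:
        frame = _as_sample_frame(X)
        name = f"{self.signature.name.lower()}_singscore"
        return pd.Series(self.transform(frame)[:, 0], index=frame.index, name=name)


# ---------------------------------------------------------------------------
# FAO
# ---------------------------------------------------------------------------

class FAOScorer(TransformerMixin, BaseEstimator):
    """Fatty-acid-oxidation activity: weighted mean of per-gene z-scores.

    ``fit`` records each FAO gene's mean and standard deviation across the
    dataset's samples; ``transform`` z-scores the genes with those moments
    and averages them (weights default to 1; a published coefficient vector
    can be supplied via ``weights`` or on the signature itself).  With unit
    weights the cohort mean of the scores is zero by construction.
    """

    def __init__(self, signature: GeneSignature, weights: dict[str, float] | None = None):
        self.signature = signature
        self.weights = weights

    def fit(self, X, y=None):
        frame = _as_sample_frame(X)
        genes = _present_genes(self.signature, frame.columns, minimum=1)
        sub = frame[genes].to_numpy(dtype=float)
        std = sub.std(axis=0)
        usable = std > 0
        if not usable.any():
            raise ValueError("every FAO gene has zero variance across samples")
        if not usable.all():
            warnings.warn(
                f"{int((~usable).sum())} zero-variance FAO gene(s) excluded"
            )
        self.genes_ = [g for g, u in zip(genes, usable) if u]
        self.mean_ = pd.Series(sub.mean(axis=0)[usable], index=self.genes_)
        self.std_ = pd.Series(std[usable], index=self.genes_)
        wmap = self.weights if self.weights is not None else (self.signature.weights or {})
        w = np.array([float(wmap.get(g, 1.0)) for g in self.genes_])
        if w.sum() == 0:
            raise ValueError("FAO weights sum to zero")
        self.weights_ = pd.Series(w, index=self.genes_, name="weight")
        self.n_features_in_ = frame.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        frame = _as_sample_frame(X)
        missing = [g for g in self.genes_ if g not in frame.columns]
        if missing:
            raise ValueError(f"fitted genes absent from X: {missing[:5]}")
        z = (frame[self.genes_].to_numpy(dtype=float) - self.mean_.to_numpy()) / self.std_.to_numpy()
        w = self.weights_.to_numpy()
        return (z @ w / w.sum()).reshape(-1, 1)

    def score_samples(self, X) -> pd.Series:
        frame = _as_sample_frame(X)
        return pd.Series(self.transform(frame)[:, 0], index=frame.index, name="fao_score")
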
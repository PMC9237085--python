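"""Per-sample signature scoring.

Three scorers are provided as scikit-learn transformers operating on a
samples x genes DataFrame (gene symbols as columns, matched
case-insensitively):

* :class:`DirectionalScorer` — the correlation-to-directionality score: a
  sample's score is the Pearson correlation, across signature genes, between
  its (median-centered) expression and the +1/-1 direction vector. Scores
  lie in [-1, 1]; +1 means expression perfectly tracks the driver's
  regulatory program.
* :class:`GeneSetMeanScorer` — the arithmetic mean of a gene set's rows,
  the standard immune-cell infiltration score (e.g. a 60-gene TIL set).
* :class:`SsgseaScorer` — single-sample GSEA: a rank-based running-sum
  enrichment score, computed per sample independently of the rest of the
  cohort (up to the optional cohort-level max-min normalization).

:class:`Dichotomizer` splits scores into High (> cutpoint) vs Low
(<= cutpoint) groups; the boundary goes to Low.

Module-level functions (:func:`score_direction_correlation`,
:func:`score_mean`, :func:`score_ssgsea`, :func:`dichotomize`) are thin
wrappers accepting an :class:`~mycsig.io.ExpressionMatrix` and returning a
:class:`ScoreVector`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ScoringError
from .io import (
    SCALE_CENTERED,
    DirectionalSignature,
    ExpressionMatrix,
    GeneSet,
    normalize_symbol,
)

LOW_OVERLAP_WARNING = 10


@dataclass
class ScoreVector:
    """One numeric score per sample plus provenance metadata."""

    scores: pd.Series = field(repr=False)
    method: str = ""
    signature_name: str = ""
    n_genes_used: int = 0

    def __post_init__(self) -> None:
        self.scores = self.scores.astype(float)
        self.scores.index = self.scores.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def __len__(self) -> int:
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "score": self.scores,
                "method": self.method,
                "signature": self.signature_name,
                "n_genes_used": self.n_genes_used,
            }
        )


def _resolve_columns(X: pd.DataFrame, wanted: list[str]) -> list[str]:
    """Columns of X matching ``wanted`` symbols case-insensitively,
    in ``wanted`` order."""
    lookup: dict[str, str] = {}
    for col in X.columns:
        lookup.setdefault(normalize_symbol(col), col)
    return [lookup[normalize_symbol(g)] for g in wanted if normalize_symbol(g) in lookup]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    raise TypeError(
        "scorers require a samples x genes DataFrame with gene symbols as columns"
    )


class DirectionalScorer(TransformerMixin, BaseEstimator):
    """Correlation-to-directionality signature score.

    Parameters
    ----------
    signature : DirectionalSignature
        Genes with +1/-1 directions.
    min_overlap : int, default 3
        Minimum number of signature genes that must be present in the data;
        a warning is emitted below 10.

    Attributes
    ----------
    genes_ : list of str
        Matrix columns used (signature genes present in the data).
    directions_ : ndarray
        The +1/-1 vector aligned to ``genes_``.
    n_genes_used_ : int
    """

    def __init__(self, signature: DirectionalSignature, min_overlap: int = 3):
        self.signature = signature
        self.min_overlap = min_overlap

    def fit(self, X, y=None):
        X = _as_frame(X)
        self.n_features_in_ = X.shape[1]
        genes = _resolve_columns(X, self.signature.genes)
        if len(genes) < self.min_overlap:
            raise ScoringError(
                f"signature {self.signature.name!r}: only {len(genes)} of "
                f"{len(self.signature)} genes present; min_overlap={self.min_overlap}"
            )
        if len(genes) < LOW_OVERLAP_WARNING:
            warnings.warn(
                f"signature {self.signature.name!r}: low overlap "
                f"({len(genes)} genes)",
                stacklevel=2,
            )
        norm_dir = self.signature.normalized_entries()
        directions = np.array([norm_dir[normalize_symbol(g)] for g in genes], float)
        if len(set(directions)) < 2:
            raise ScoringError(
                f"signature {self.signature.name!r}: direction vector is constant "
                "over the overlapping genes; the correlation score is undefined"
            )
        self.genes_ = genes
        self.directions_ = directions
        self.n_genes_used_ = len(genes)
        return self

    def transform(self, X) -> np.ndarray:
        """Per-sample Pearson correlation with the direction vector,
        shape (n_samples, 1). Samples with zero expression variance (or
        fewer than min_overlap observed genes) score NaN with a warning."""
        X = _as_frame(X)
        vals = X[self.genes_].to_numpy(float)
        d = self.directions_
        dm = d - d.mean()
        sd = float(np.sqrt((dm**2).sum()))
        out = np.full(vals.shape[0], np.nan)
        obs = ~np.isnan(vals)
        complete = obs.all(axis=1)
        if complete.any():
            xv = vals[complete]
            xm = xv - xv.mean(axis=1, keepdims=True)
            sx = np.sqrt((xm**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (xm @ dm) / (sx * sd)
            r[sx == 0] = np.nan
            out[complete] = r
        for i in np.nonzero(~complete)[0]:
            mask = obs[i]
            if mask.sum() < max(self.min_overlap, 2):
                continue
            di = d[mask]
            if len(set(di)) < 2:
                continue
            xi = vals[i, mask]
            xm_i = xi - xi.mean()
            dm_i = di - di.mean()
            denom = np.sqrt((xm_i**2).sum() * (dm_i**2).sum())
            out[i] = (xm_i @ dm_i) / denom if denom > 0 else np.nan
        if np.isnan(out).any():
            warnings.warn(
                f"{int(np.isnan(out).sum())} sample(s) received a missing score "
                "(zero variance or insufficient observed genes)",
                stacklevel=2,
            )
        return out[:, None]

    def score_samples(self, X) -> pd.Series:
        X = _as_frame(X)
        return pd.Series(self.transform(X)[:, 0], index=X.index, name="score")


class GeneSetMeanScorer(TransformerMixin, BaseEstimator):
    """Mean expression of a gene set's members, per sample.

    Missing genes are dropped with a warning; missing values are ignored
    in the mean (the score uses the genes observed for that sample)."""

    def __init__(self, gene_set: GeneSet, min_overlap: int = 3):
        self.gene_set = gene_set
        self.min_overlap = min_overlap

    def fit(self, X, y=None):
        X = _as_frame(X)
        self.n_features_in_ = X.shape[1]
        genes = _resolve_columns(X, self.gene_set.genes)
        if len(genes) < self.min_overlap:
            raise ScoringError(
                f"gene set {self.gene_set.name!r}: only {len(genes)} of "
                f"{len(self.gene_set)} genes present; min_overlap={self.min_overlap}"
            )
        if len(genes) < len(self.gene_set):
            warnings.warn(
                f"gene set {self.gene_set.name!r}: {len(self.gene_set) - len(genes)} "
                "gene(s) absent from the matrix",
                stacklevel=2,
            )
        if len(genes) < LOW_OVERLAP_WARNING:
            warnings.warn(
                f"gene set {self.gene_set.name!r}: low overlap ({len(genes)} genes)",
                stacklevel=2,
            )
        self.genes_ = genes
        self.n_genes_used_ = len(genes)
        return self

    def transform(self, X) -> np.ndarray:
        X = _as_frame(X)
        vals = X[self.genes_].to_numpy(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(vals, axis=1)
        return means[:, None]

    def score_samples(self, X) -> pd.Series:
        X = _as_frame(X)
        return pd.Series(self.transform(X)[:, 0], index=X.index, name="score")


class SsgseaScorer(TransformerMixin, BaseEstimator):
    """Single-sample GSEA enrichment score.

    For each sample, all genes are ranked by expression (highest expression
    gets the largest rank value N; ties receive average ranks). Walking the
    gene list from the top rank downward, the enrichment score accumulates
    the gap between the weighted in-set and the uniform out-of-set empirical
    distributions::

        ES = sum_i [ P_in(i) - P_out(i) ]
        P_in(i)  = sum_{members at position <= i} rank^alpha / sum_{members} rank^alpha
        P_out(i) = #(non-members at position <= i) / (N - |set|)

    ``alpha`` (default 0.25) is the rank-weighting exponent. With
    ``normalize=True`` all samples' scores are divided by (max ES - min ES)
    across the cohort. The score depends only on within-sample ranks.
    """

    def __init__(self, gene_set: GeneSet, alpha: float = 0.25, normalize: bool = False):
        self.gene_set = gene_set
        self.alpha = alpha
        self.normalize = normalize

    def fit(self, X, y=None):
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        X = _as_frame(X)
        self.n_features_in_ = X.shape[1]
        members = self.gene_set.normalized()
        in_set = np.array(
            [normalize_symbol(c) in members for c in X.columns], dtype=bool
        )
        if in_set.sum() == 0:
            raise ScoringError(
                f"gene set {self.gene_set.name!r}: no genes present in the matrix"
            )
        if in_set.all():
            raise ScoringError(
                f"gene set {self.gene_set.name!r} covers every matrix gene; "
                "the out-of-set distribution is undefined"
            )
        self.in_set_mask_ = in_set
        self.n_genes_used_ = int(in_set.sum())
        return self

    def _es_one(self, x: np.ndarray, in_set: np.ndarray) -> float:
        n = x.size
        ranks = rankdata(x)  # average ties; largest expression -> rank n
        order = np.argsort(-ranks, kind="stable")  # top-ranked first
        member = in_set[order]
        w = np.where(member, ranks[order] ** self.alpha, 0.0)
        denom_in = w.sum()
        p_in = np.cumsum(w) / denom_in
        p_out = np.cumsum(~member) / (n - member.sum())
        return float((p_in - p_out).sum())

    def transform(self, X) -> np.ndarray:
        X = _as_frame(X)
        vals = X.to_numpy(float)
        if np.isnan(vals).any():
            raise ScoringError("ssGSEA requires complete expression values")
        es = np.array([self._es_one(row, self.in_set_mask_) for row in vals])
        if self.normalize:
            spread = es.max() - es.min()
            if spread == 0:
                raise ScoringError(
                    "cannot normalize ssGSEA scores: max - min across samples is 0"
                )
            es = es / spread
        return es[:, None]

    def score_samples(self, X) -> pd.Series:
        X = _as_frame(X)
        return pd.Series(self.transform(X)[:, 0], index=X.index, name="score")


class Dichotomizer(TransformerMixin, BaseEstimator):
    """Map scores to High (> cutpoint) / Low (<= cutpoint) labels."""

    def __init__(self, cutpoint: float = 0.0):
        self.cutpoint = cutpoint

    def fit(self, X, y=None):
        if not np.isfinite(self.cutpoint):
            raise ValueError("cutpoint must be finite")
        self.n_features_in_ = np.asarray(X).shape[1] if np.asarray(X).ndim == 2 else 1
        return self

    def transform(self, X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        labels = np.where(arr > self.cutpoint, "High", "Low").astype(object)
        labels[np.isnan(arr)] = None
        if (arr != arr).any():
            warnings.warn("missing score(s): sample(s) left unlabelled", stacklevel=2)
        return labels


# ---------------------------------------------------------------------------
# ExpressionMatrix-level wrappers
# ---------------------------------------------------------------------------

def score_direction_correlation(
    m: ExpressionMatrix,
    sig: DirectionalSignature,
    min_overlap: int = 3,
    require_centered: bool = True,
) -> ScoreVector:
    """Correlation-to-directionality score for every sample of ``m``.

    The matrix is expected on the log2-centered scale; pass
    ``require_centered=False`` to proceed on another scale with a warning.
    """
    if m.scale != SCALE_CENTERED:
        if require_centered:
            raise ScoringError(
                f"expected a log2-centered matrix, got scale={m.scale!r}; "
                "median-center first or pass require_centered=False"
            )
        warnings.warn(
            f"scoring a matrix with scale={m.scale!r}; the directional score "
            "assumes median-centered log2 expression",
            stacklevel=2,
        )
    scorer = DirectionalScorer(sig, min_overlap=min_overlap).fit(m.samples_by_genes())
    scores = scorer.score_samples(m.samples_by_genes())
    return ScoreVector(
        scores=scores,
        method="direction_correlation",
        signature_name=sig.name,
        n_genes_used=scorer.n_genes_used_,
    )


def score_mean(m: ExpressionMatrix, gs: GeneSet, min_overlap: int = 3) -> ScoreVector:
    """Mean of the gene set's rows per sample, on the matrix's current scale."""
    scorer = GeneSetMeanScorer(gs, min_overlap=min_overlap).fit(m.samples_by_genes())
    return ScoreVector(
        scores=scorer.score_samples(m.samples_by_genes()),
        method="mean",
        signature_name=gs.name,
        n_genes_used=scorer.n_genes_used_,
    )


def score_ssgsea(
    m: ExpressionMatrix,
    gs: GeneSet,
    alpha: float = 0.25,
    normalize: bool = False,
) -> ScoreVector:
    """ssGSEA enrichment score of ``gs`` for every sample of ``m``."""
    X = m.samples_by_genes()
    scorer = SsgseaScorer(gs, alpha=alpha, normalize=normalize).fit(X)
    return ScoreVector(
        scores=scorer.score_samples(X),
        method="ssgsea",
        signature_name=gs.name,
        n_genes_used=scorer.n_genes_used_,
    )


def dichotomize(scores: ScoreVector | pd.Series, cutpoint: float = 0.0) -> pd.Series:
    """High/Low labels from scores; High iff score > cutpoint.

    Samples with missing scores are excluded with a warning."""
    s = scores.scores if isinstance(scores, ScoreVector) else pd.Series(scores)
    if not np.isfinite(cutpoint) and not np.isneginf(cutpoint) and not np.isposinf(cutpoint):
        raise ValueError("cutpoint must not be NaN")
    missing = s.isna()
    if missing.any():
        warnings.warn(
            f"excluding {int(missing.sum())} sample(s) with missing scores from "
            "dichotomization",
            stacklevel=2,
        )
        s = s[~missing]
    labels = pd.Series(
        np.where(s > cutpoint, "High", "Low"), index=s.index, name="group"
    )
    return labels
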
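"""Chi-square gene ranking over quantized expression terms.

Each gene's expression range is split into ``t`` equal-width intervals
("terms"). A 2 x t contingency table A counts how many resistant and
sensitive samples fall in each term; the expected table under independence is
E[c, j] = n * P_term(j) * P_class(c), and the gene's score is the classical

    chi2 = sum_j sum_c (A[c, j] - E[c, j])^2 / E[c, j]

with empty-term cells (E = 0, which forces A = 0) contributing zero. High
scores mark genes whose discretized expression is informative about the
class. Selection keeps the top m' genes, optionally restricted to a candidate
list (e.g. pro-/anti-apoptotic genes) or drawn at random as a null baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import logger
from .errors import DomainError, SelectionError
from .io_formats import ExpressionMatrix, GeneList
from .labeling import CLASSES

DEFAULT_TERMS = 10


@dataclass(frozen=True)
class ChiSquareTable:
    """Observed/expected 2 x t count tables and the resulting chi2 score.

    Row 0 corresponds to the resistant class, row 1 to the sensitive class.
    """

    observed: np.ndarray
    expected: np.ndarray
    t: int
    score: float
    gene: str | None = None


@dataclass(frozen=True)
class FeatureSet:
    genes: tuple[str, ...]
    method: str
    scores: pd.Series | None = None


def quantize(values, t: int) -> np.ndarray:
    """Map each value to a term index in [1, t] by equal-width binning.

    The observed [min, max] range is split into ``t`` fixed-length intervals;
    the maximum value belongs to term ``t`` (closed last interval). A constant
    vector maps every sample to term 1.
    """
    if t < 2:
        raise DomainError(f"need at least 2 terms, got {t}")
    arr = np.asarray(values, dtype=float)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.ones(arr.shape, dtype=int)
    idx = np.floor((arr - lo) / (hi - lo) * t).astype(int)
    return np.clip(idx, 0, t - 1) + 1


def chi2_score(values, labels, t: int = DEFAULT_TERMS, gene: str | None = None) -> ChiSquareTable:
    """Chi-square independence score between quantized expression and class."""
    arr = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=object)
    if arr.shape != lab.shape:
        raise DomainError("values and labels must have equal length")
    for cls in CLASSES:
        if not (lab == cls).any():
            raise DomainError(f"labels contain no {cls} samples")
    terms = quantize(arr, t)
    n = arr.size
    observed = np.zeros((2, t))
    for c, cls in enumerate(CLASSES):
        counts = np.bincount(terms[lab == cls], minlength=t + 1)[1:]
        observed[c] = counts
    p_term = observed.sum(axis=0) / n
    p_class = observed.sum(axis=1) / n
    expected = n * np.outer(p_class, p_term)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    return ChiSquareTable(
        observed=observed, expected=expected, t=t, score=float(contrib.sum()), gene=gene
    )


def chi2_rank(features: pd.DataFrame, labels, t: int = DEFAULT_TERMS) -> pd.Series:
    """Chi-square score per gene on a samples x genes frame, descending.

    Ties are broken lexicographically by gene symbol for reproducibility.
    """
    scores = {
        gene: chi2_score(features[gene].to_numpy(), labels, t=t, gene=gene).score
        for gene in features.columns
    }
    ser = pd.Series(scores, name="chi2")
    order = sorted(ser.index, key=lambda g: (-ser[g], g))
    return ser.loc[order]


def select_top_genes(
    expr,
    labels,
    m_prime: int,
    t: int = DEFAULT_TERMS,
    candidates: GeneList | None = None,
) -> FeatureSet:
    """Select the top ``m_prime`` genes by chi-square score.

    ``expr`` may be an :class:`ExpressionMatrix` (labels aligned to its cell
    lines) or a samples x genes DataFrame (labels aligned to its rows). With a
    candidate :class:`GeneList`, ranking is restricted to candidates present
    in the matrix; fewer candidates than ``m_prime`` yields all of them with a
    warning.
    """
    if m_prime < 1:
        raise DomainError("m_prime must be >= 1")
    features = expr.samples() if isinstance(expr, ExpressionMatrix) else expr
    if candidates is not None:
        avail = [g for g in features.columns if g in candidates.symbols]
        if not avail:
            raise SelectionError(
                f"candidate list {candidates.name!r} shares no genes with the matrix"
            )
        features = features[avail]
        method = candidates.name
    else:
        method = "chi2"
    ranked = chi2_rank(features, labels, t=t)
    if m_prime >= len(ranked):
        if m_prime > len(ranked):
            logger.warning(
                "requested %d genes but only %d candidates available", m_prime, len(ranked)
            )
        chosen = ranked
    else:
        chosen = ranked.iloc[:m_prime]
    return FeatureSet(genes=tuple(chosen.index), method=method, scores=chosen)


def select_random_genes(expr, m_prime: int, seed: int) -> FeatureSet:
    """Uniform gene sample without replacement — the null feature selection."""
    genes = expr.genes if isinstance(expr, ExpressionMatrix) else list(expr.columns)
    if m_prime > len(genes):
        raise DomainError(f"m_prime={m_prime} exceeds the {len(genes)} available genes")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(np.asarray(genes, dtype=object), size=m_prime, replace=False)
    return FeatureSet(genes=tuple(chosen), method="random", scores=None)
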
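"""Single-sample gene-set enrichment scoring (ssGSEA).

For one sample, genes are ranked by expression (midranks for ties,
1 = lowest) and walked in order of decreasing rank.  The enrichment score
of a gene set G is the summed difference between the weighted in-set and
the uniform out-of-set cumulative distributions:

    ES(G) = sum_i [ P_hit(i) - P_miss(i) ]

    P_hit(i)  = sum_{g in G, pos(g) <= i} rank(g)^alpha / sum_{g in G} rank(g)^alpha
    P_miss(i) = |{g not in G : pos(g) <= i}| / (N - |G|)

i.e. the ssGSEA convention (sum of running differences), not the classic
GSEA extremum.  Weights are rank values raised to ``alpha`` — not raw
expression — which makes the score invariant under any strictly increasing
per-sample transform and hence portable across platforms and scales.

Tied ranks are handled blockwise: genes sharing a midrank form one block
and every gene in it contributes the end-of-block value of
``P_hit - P_miss``.  With no ties this is exactly the positional walk; with
ties it makes the score independent of the arbitrary within-tie order, and
an all-constant sample scores exactly 0 for every set.  Iteration order
within a block is lexicographic in the gene id so outputs are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import ExpressionMatrix, GeneSet, GeneSetCollection, ValidationError

__all__ = [
    "ScoreMatrix",
    "rank_transform",
    "enrichment_score",
    "score_collection",
]

DEFAULT_ALPHA = 0.25
DEFAULT_MIN_OVERLAP = 2


@dataclass(frozen=True)
class ScoreMatrix:
    """Gene sets × samples enrichment scores plus the scoring configuration."""

    scores: pd.DataFrame  # index = set names, columns = sample ids
    alpha: float
    normalized: bool
    dropped_sets: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValidationError("scores must be finite")

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


def rank_transform(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample midranks of expression (1 = lowest … N = highest)."""
    if matrix.n_genes < 2:
        raise ValidationError("rank transform needs at least 2 genes")
    ranks = rankdata(matrix.values, method="average", axis=0)
    return pd.DataFrame(ranks, index=matrix.gene_ids, columns=matrix.sample_ids)


def _es_from_ordered(
    sorted_ranks: np.ndarray, in_set: np.ndarray, alpha: float
) -> float:
    """ES given ranks sorted in decreasing order and an in-set mask.

    Tied-rank blocks contribute their end-of-block running-sum value once
    per member gene.
    """
    n = sorted_ranks.size
    n_hit = int(in_set.sum())
    weights = np.where(in_set, sorted_ranks.astype(float) ** alpha, 0.0)
    p_hit = np.cumsum(weights) / weights.sum()
    p_miss = np.cumsum(~in_set) / (n - n_hit)
    diff = p_hit - p_miss
    # block ends: last position of each run of equal rank values
    block_end = np.empty(n, dtype=int)
    ends = np.flatnonzero(np.diff(sorted_ranks) != 0)
    ends = np.append(ends, n - 1)
    start = 0
    for e in ends:
        block_end[start : e + 1] = e
        start = e + 1
    return float(diff[block_end].sum())


def _order_indices(ranks: np.ndarray, lex_order: np.ndarray) -> np.ndarray:
    """Indices sorting genes by decreasing rank, ties by gene-id order."""
    return np.lexsort((lex_order, -ranks))


def enrichment_score(
    ranks: pd.Series, gene_set: GeneSet, alpha: float = DEFAULT_ALPHA
) -> float:
    """ssGSEA enrichment score of one set against one sample's rank vector."""
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    gene_ids = np.asarray(ranks.index, dtype=object)
    rank_values = ranks.to_numpy(dtype=float)
    members = set(gene_set.members)
    in_set = np.array([g in members for g in gene_ids])
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValidationError(f"set {gene_set.name!r} not represented in the matrix")
    if n_hit == rank_values.size:
        raise ValidationError(
            f"set {gene_set.name!r} covers every gene: P_miss undefined"
        )
    lex_order = np.argsort(np.argsort(gene_ids))
    order = _order_indices(rank_values, lex_order)
    return _es_from_ordered(rank_values[order], in_set[order], alpha)


def score_collection(
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = True,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> ScoreMatrix:
    """Score every (set, sample) pair; optionally min–max normalize globally.

    Sets overlapping the matrix in fewer than ``min_overlap`` genes are
    dropped and listed in :attr:`ScoreMatrix.dropped_sets`.  Normalization
    divides the whole matrix once by its global (max − min); a constant raw
    matrix skips normalization with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    rank_df = rank_transform(matrix)
    gene_ids = np.asarray(rank_df.index, dtype=object)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    lex_order = np.argsort(np.argsort(gene_ids))
    rank_values = rank_df.to_numpy()

    kept: list[GeneSet] = []
    dropped: list[str] = []
    for s in collection:
        overlap = sum(1 for g in s.members if g in gene_pos)
        if overlap < min_overlap:
            dropped.append(s.name)
        else:
            kept.append(s)
    if not kept:
        raise ValidationError("all gene sets fell below the overlap threshold")
    if dropped:
        logger.warning("dropped %d set(s) below min_overlap: %s", len(dropped), dropped)

    masks = np.zeros((len(kept), len(gene_ids)), dtype=bool)
    for i, s in enumerate(kept):
        idx = [gene_pos[g] for g in s.members if g in gene_pos]
        masks[i, idx] = True
        if masks[i].all():
            raise ValidationError(
                f"set {s.name!r} covers every gene: P_miss undefined"
            )

    scores = np.empty((len(kept), matrix.n_samples))
    for j in range(matrix.n_samples):
        col = rank_values[:, j]
        order = _order_indices(col, lex_order)
        sorted_ranks = col[order]
        for i in range(len(kept)):
            scores[i, j] = _es_from_ordered(sorted_ranks, masks[i][order], alpha)

    normalized = False
    if normalize:
        rng = scores.max() - scores.min()
        if rng == 0:
            logger.warning("constant score matrix: normalization skipped")
        else:
            scores = scores / rng
            normalized = True

    df = pd.DataFrame(
        scores, index=[s.name for s in kept], columns=matrix.sample_ids
    )
    return ScoreMatrix(
        scores=df, alpha=alpha, normalized=normalized, dropped_sets=tuple(dropped)
    )
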
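"""Three-stage distillation of a stemness signature from candidate gene sets.

Stage 1 — discrimination: each candidate set is scored on a labeled
stem-vs-somatic panel and kept iff its ROC-AUC (probability that a stem
sample outscores a somatic one, ties counted half) is at least ``auc_min``
(default 0.95; the exclusion rule is "AUC < 95%", so the boundary is
inclusive).  No orientation flipping is performed: candidate stemness sets
are expected to score higher in stem cells.

Stage 2 — stability: survivors are scored on a large tumor cell-line panel
and kept iff the coefficient of variation of their scores across lines is
at most ``cv_max`` (default 0.1; exclusion is "CV > 0.1", boundary
inclusive).  Enrichment scores can be negative, which makes a raw CV
meaningless, so the whole score matrix is min–max rescaled to [0, 1] first;
sets whose rescaled mean is 0 have undefined CV and are excluded with a
flag.  The standard deviation uses the n−1 (sample) convention.

Stage 3 — consensus: genes present in at least ``min_membership`` (default
4) of the surviving sets form the final signature, sorted by descending
membership count then gene id.

A Pearson screen (:func:`correlation_screen`) selects individual genes
whose expression tracks a per-sample score (r > r_min and p < p_max, both
strict); no multiple-testing correction is applied to the decision, but
Benjamini–Hochberg q-values are reported for transparency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GeneSet, GeneSetCollection, PhenotypeLabels, ValidationError
from .ssgsea import ScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DistillationReport",
    "ConsensusSignature",
    "roc_auc",
    "filter_discriminative",
    "stability_cv",
    "consensus_signature",
    "correlation_screen",
    "distill",
]

DEFAULT_AUC_MIN = 0.95
DEFAULT_CV_MAX = 0.1
DEFAULT_MIN_MEMBERSHIP = 4


@dataclass(frozen=True)
class DistillationReport:
    """Per-set audit trail of the two filters plus the thresholds used."""

    rows: pd.DataFrame  # index = set names; auc, passed_auc, cv, cv_defined, passed_cv
    auc_min: float
    cv_max: float
    n_entered: int
    n_after_auc: int
    n_after_cv: int

    def __post_init__(self) -> None:
        if not (self.n_entered >= self.n_after_auc >= self.n_after_cv):
            raise ValidationError("stage counts must be non-increasing")


@dataclass(frozen=True)
class ConsensusSignature:
    """Genes present in >= min_membership of the retained sets."""

    genes: tuple[str, ...]
    membership_count: dict[str, int]
    min_membership: int
    source_set_names: tuple[str, ...]

    def __post_init__(self) -> None:
        for g in self.genes:
            if self.membership_count[g] < self.min_membership:
                raise ValidationError(
                    f"gene {g!r} below min_membership {self.min_membership}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def to_gene_set(self, name: str = "stemness_signature") -> GeneSet:
        return GeneSet(
            name=name,
            description=f"consensus of {len(self.source_set_names)} sets "
            f"(membership >= {self.min_membership})",
            members=self.genes,
        )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie), by the midrank formula.

    ``labels`` are 0/1 with 1 the positive (stem / tumor) class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present for ROC-AUC")
    ranks = stats.rankdata(scores, method="average")
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def filter_discriminative(
    score_matrix: ScoreMatrix,
    labels: PhenotypeLabels,
    auc_min: float = DEFAULT_AUC_MIN,
) -> tuple[list[str], pd.DataFrame]:
    """Retain sets whose stem-vs-somatic AUC is >= ``auc_min``."""
    y = labels.values_for(score_matrix.sample_ids)
    records = []
    for name in score_matrix.set_names:
        auc = roc_auc(score_matrix.scores.loc[name].to_numpy(), y)
        records.append({"set": name, "auc": auc, "passed_auc": auc >= auc_min})
    rows = pd.DataFrame(records).set_index("set")
    retained = list(rows.index[rows["passed_auc"]])
    return retained, rows


def stability_cv(
    score_matrix: ScoreMatrix, cv_max: float = DEFAULT_CV_MAX
) -> tuple[list[str], pd.DataFrame]:
    """Retain sets with coefficient of variation <= ``cv_max`` across a panel.

    The whole score matrix is min–max rescaled to [0, 1] before computing
    per-set CV = sd(n−1) / mean, so means are nonnegative; mean-zero sets
    have undefined CV and are excluded with ``cv_defined = False``.
    """
    values = score_matrix.scores.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValidationError("stability filter needs a panel of >= 2 samples")
    lo, hi = values.min(), values.max()
    rescaled = np.zeros_like(values) if hi == lo else (values - lo) / (hi - lo)
    records = []
    for i, name in enumerate(score_matrix.set_names):
        row = rescaled[i]
        mean = row.mean()
        if mean == 0:
            records.append(
                {"set": name, "cv": np.nan, "cv_defined": False, "passed_cv": False}
            )
            continue
        cv = row.std(ddof=1) / mean
        records.append(
            {"set": name, "cv": cv, "cv_defined": True, "passed_cv": cv <= cv_max}
        )
    rows = pd.DataFrame(records).set_index("set")
    retained = list(rows.index[rows["passed_cv"]])
    return retained, rows


def consensus_signature(
    retained: GeneSetCollection, min_membership: int = DEFAULT_MIN_MEMBERSHIP
) -> ConsensusSignature:
    """Genes appearing in >= ``min_membership`` of the retained sets."""
    if len(retained) == 0:
        raise ValidationError("no retained sets to build a consensus from")
    counts: dict[str, int] = {}
    for s in retained:
        for g in s.members:
            counts[g] = counts.get(g, 0) + 1
    genes = [g for g, c in counts.items() if c >= min_membership]
    genes.sort(key=lambda g: (-counts[g], g))
    if not genes:
        logger.warning(
            "consensus signature is empty at min_membership=%d", min_membership
        )
    return ConsensusSignature(
        genes=tuple(genes),
        membership_count={g: counts[g] for g in genes},
        min_membership=min_membership,
        source_set_names=tuple(retained.names),
    )


def correlation_screen(
    matrix,
    score: pd.Series,
    r_min: float = 0.4,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Pearson correlation against a per-sample score.

    Returns a frame (index = gene) with r, two-sided p (t transform with
    n−2 df), BH q-value, and a ``kept`` flag for r > r_min and p < p_max
    (both strict).  Zero-variance genes are excluded with a warning.
    """
    samples = list(score.index)
    if len(samples) < 3:
        raise ValidationError("correlation screen needs >= 3 samples")
    X = matrix.data[samples].to_numpy(dtype=float)
    y = score.to_numpy(dtype=float)
    n = len(samples)
    xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    valid = (sx > 0) & (sy > 0)
    n_invalid = int((~valid).sum())
    if n_invalid:
        logger.warning(
            "excluded %d zero-variance gene(s) from the correlation screen",
            n_invalid,
        )
    r = np.full(X.shape[0], np.nan)
    r[valid] = (xc[valid] @ yc) / (sx[valid] * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    out = pd.DataFrame(
        {"r": r, "p": p}, index=matrix.gene_ids
    ).loc[np.asarray(matrix.gene_ids)[valid]]
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["kept"] = (out["r"] > r_min) & (out["p"] < p_max)
    return out


def distill(
    stem_scores: ScoreMatrix,
    labels: PhenotypeLabels,
    panel_scores: ScoreMatrix,
    collection: GeneSetCollection,
    auc_min: float = DEFAULT_AUC_MIN,
    cv_max: float = DEFAULT_CV_MAX,
    min_membership: int = DEFAULT_MIN_MEMBERSHIP,
) -> tuple[DistillationReport, ConsensusSignature]:
    """Run the full funnel: AUC filter → CV filter → consensus signature.

    ``panel_scores`` must contain at least the stage-1 survivors; only
    survivors are assessed for stability.
    """
    retained_auc, auc_rows = filter_discriminative(stem_scores, labels, auc_min)
    missing = [n for n in retained_auc if n not in panel_scores.set_names]
    if missing:
        raise ValidationError(f"panel scores missing stage-1 survivors: {missing}")
    survivors = ScoreMatrix(
        scores=panel_scores.scores.loc[retained_auc],
        alpha=panel_scores.alpha,
        normalized=panel_scores.normalized,
    )
    retained_cv, cv_rows = stability_cv(survivors, cv_max)
    rows = auc_rows.join(cv_rows, how="left")
    rows["cv_defined"] = rows["cv_defined"].astype(object).where(rows["cv_defined"].notna(), False)
    rows["passed_cv"] = rows["passed_cv"].astype(object).where(rows["passed_cv"].notna(), False)
    report = DistillationReport(
        rows=rows,
        auc_min=auc_min,
        cv_max=cv_max,
        n_entered=len(stem_scores.set_names),
        n_after_auc=len(retained_auc),
        n_after_cv=len(retained_cv),
    )
    signature = consensus_signature(collection.subset(retained_cv), min_membership)
    return report, signature
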
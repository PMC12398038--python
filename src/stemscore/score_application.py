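"""Apply a stemness signature to a cohort and run the validation analytics.

Covers: per-sample signature scoring (ssGSEA of the signature as a single
set), high/low dichotomization at the median (ties to low), group contrasts
(Welch t for two groups, one-way ANOVA for three or more), diagnostic ROC,
Kaplan–Meier curves with the log-rank test, and Cox proportional-hazards
regression (Efron tie handling).

Survival machinery is backed by lifelines; the ROC polyline by
scikit-learn; the AUC is the in-package midrank statistic.  The Cox score
test at β = 0 is implemented here directly (it is the analytic bridge to
the log-rank statistic for a binary covariate without ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .core_io import (
    ExpressionMatrix,
    GeneSetCollection,
    PhenotypeLabels,
    SurvivalTable,
    ValidationError,
)
from .distillation import ConsensusSignature, roc_auc
from .ssgsea import DEFAULT_ALPHA, DEFAULT_MIN_OVERLAP, score_collection

logger = logging.getLogger(__name__)

__all__ = [
    "CohortScores",
    "KMEstimate",
    "CoxFit",
    "RocResult",
    "score_samples",
    "dichotomize",
    "group_difference",
    "diagnostic_roc",
    "km_logrank",
    "cox_ph",
    "cox_score_test",
]


@dataclass(frozen=True)
class CohortScores:
    """Per-sample signature scores, optionally split into high/low groups."""

    scores: pd.Series  # index = sample ids
    group: pd.Series | None = None  # values "high"/"low"
    split_value: float | None = None
    split_method: str | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival estimate for one group."""

    group: str
    times: np.ndarray  # event/censor time grid of the step function
    survival: np.ndarray  # S(t), right-continuous, starts at 1
    at_risk: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class CoxFit:
    """Cox PH fit summary: per-covariate effects plus fit diagnostics."""

    summary: pd.DataFrame  # index = covariate; coef, hr, ci_low, ci_high, z, p
    log_likelihood: float
    converged: bool
    ties: str
    n: int
    n_events: int


@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def score_samples(
    matrix: ExpressionMatrix,
    signature: ConsensusSignature,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = False,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> CohortScores:
    """ssGSEA score of the consensus signature (as one set) per sample."""
    collection = GeneSetCollection((signature.to_gene_set(),))
    sm = score_collection(
        matrix, collection, alpha=alpha, normalize=normalize, min_overlap=min_overlap
    )
    return CohortScores(scores=sm.scores.iloc[0].copy())


def dichotomize(scores: CohortScores, method: str = "median") -> CohortScores:
    """Split into high (score > median) and low (score <= median) groups."""
    if method != "median":
        raise ValueError(f"unknown split method {method!r}")
    values = scores.scores
    if len(values) < 2:
        raise ValidationError("dichotomization needs >= 2 samples")
    if values.nunique() == 1:
        raise ValidationError("degenerate split: all scores identical")
    split = float(values.median())
    group = pd.Series(
        np.where(values.to_numpy() > split, "high", "low"), index=values.index
    )
    return CohortScores(
        scores=values, group=group, split_value=split, split_method=method
    )


def group_difference(
    values: pd.Series, groups: pd.Series
) -> tuple[float, float]:
    """Welch t (2 groups) or one-way ANOVA F (>= 3 groups), two-sided p."""
    aligned = groups.loc[values.index]
    arrays = [
        values[aligned == g].to_numpy(dtype=float) for g in pd.unique(aligned)
    ]
    if len(arrays) < 2:
        raise ValidationError("need >= 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValidationError("every group needs >= 2 members")
    if len(arrays) == 2:
        res = stats.ttest_ind(arrays[0], arrays[1], equal_var=False)
    else:
        res = stats.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def diagnostic_roc(scores: pd.Series, labels: PhenotypeLabels) -> RocResult:
    """Full (FPR, TPR) polyline over score thresholds, plus midrank AUC."""
    y = labels.values_for(list(scores.index))
    s = scores.to_numpy(dtype=float)
    fpr, tpr, thresholds = _sk_roc_curve(y, s)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=roc_auc(s, y))


def _km_one_group(name: str, time: np.ndarray, event: np.ndarray) -> KMEstimate:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    survival = sf.iloc[:, 0].to_numpy(dtype=float)
    # drop the t=0 anchor row lifelines prepends (S starts at 1 implicitly)
    if times.size and times[0] == 0 and 0 not in time:
        times, survival = times[1:], survival[1:]
        at_risk = kmf.event_table["at_risk"].iloc[1:].to_numpy(dtype=float)
    else:
        at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)
    return KMEstimate(
        group=name,
        times=times,
        survival=survival,
        at_risk=at_risk,
        censor_times=np.sort(time[event == 0]),
    )


def km_logrank(
    survival: SurvivalTable, groups: pd.Series
) -> tuple[dict[str, KMEstimate], float, float]:
    """Kaplan–Meier estimate per group and the 2-group log-rank test.

    The log-rank statistic is the classic sum of (observed − expected)
    events with hypergeometric variance across event times, df = 1.
    """
    df = survival.data
    g = groups.loc[df.index]
    levels = list(pd.unique(g))
    if len(levels) != 2:
        raise ValidationError("log-rank comparison needs exactly 2 groups")
    if int(df["event"].sum()) < 1:
        raise ValidationError("no events observed")
    estimates = {}
    for level in levels:
        mask = (g == level).to_numpy()
        if mask.sum() == 0:
            raise ValidationError(f"group {level!r} has zero subjects")
        estimates[str(level)] = _km_one_group(
            str(level),
            df["time"].to_numpy(dtype=float)[mask],
            df["event"].to_numpy(dtype=int)[mask],
        )
    res = multivariate_logrank_test(
        df["time"].to_numpy(dtype=float),
        g.to_numpy(),
        df["event"].to_numpy(dtype=int),
    )
    return estimates, float(res.test_statistic), float(res.p_value)


def cox_ph(
    survival: SurvivalTable,
    covariates: list[str] | None = None,
    ties: str = "efron",
) -> CoxFit:
    """Cox proportional-hazards fit by maximum partial likelihood.

    ``ties`` is ``"efron"`` (default) or ``"breslow"``.  Non-convergence or
    a monotone likelihood (perfect separation) yields ``converged=False``
    with no effect estimates rather than an exception.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    covariates = covariates or survival.covariate_names
    if not covariates:
        raise ValidationError("no covariates to fit")
    df = survival.data[["time", "event", *covariates]].astype(float)
    if int(df["event"].sum()) < 1:
        raise ValidationError("no events observed")
    cph = CoxPHFitter()
    n, n_events = len(df), int(df["event"].sum())
    try:
        with np.errstate(all="ignore"):
            cph.fit(
                df,
                duration_col="time",
                event_col="event",
                show_progress=False,
                fit_options={"step_size": 0.95},
            )
    except Exception as exc:  # lifelines ConvergenceError and kin
        logger.warning("Cox fit did not converge: %s", exc)
        empty = pd.DataFrame(
            columns=["coef", "hr", "ci_low", "ci_high", "se", "z", "p"]
        )
        return CoxFit(
            summary=empty,
            log_likelihood=float("nan"),
            converged=False,
            ties=ties,
            n=n,
            n_events=n_events,
        )
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_low": np.exp(s["coef lower 95%"]),
            "ci_high": np.exp(s["coef upper 95%"]),
            "se": s["se(coef)"],
            "z": s["z"],
            "p": s["p"],
        }
    )
    return CoxFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        converged=True,
        ties=ties,
        n=n,
        n_events=n_events,
    )


def cox_score_test(
    time: np.ndarray, event: np.ndarray, x: np.ndarray
) -> tuple[float, float]:
    """Cox partial-likelihood score test of β = 0 for a single covariate.

    U(0) = Σ_events (x_i − mean over risk set); I(0) = Σ_events risk-set
    variance of x.  The statistic U²/I is chi-square with 1 df and, for a
    binary covariate without tied event times, equals the log-rank
    statistic exactly.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    u = 0.0
    info = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        xr = x[at_risk]
        n_r = xr.size
        mean_r = xr.mean()
        var_r = ((xr - mean_r) ** 2).sum() / n_r
        d = int(((time == t) & (event == 1)).sum())
        u += (x[(time == t) & (event == 1)] - mean_r).sum()
        info += d * var_r
    if info == 0:
        raise ValidationError("degenerate covariate: zero information")
    stat = u * u / info
    return float(stat), float(stats.chi2.sf(stat, df=1))
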
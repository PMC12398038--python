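"""Synthetic data with the statistical structure the pipeline assumes.

Three emulated data layers, all derived from one :class:`SimulationDesign`:

* a labeled **stem vs somatic expression panel** in which the genes of
  "planted" stemness sets are coordinately up-shifted in stem samples
  (log-normal baseline, additive shift of ``delta`` standard deviations on
  the log scale — ranks downstream make the marginal shape nearly
  irrelevant, log-normal is chosen for realistic skew);
* a large **tumor cell-line panel** on which planted sets score stably (a
  fixed shift on every line) while "unstable" decoy sets receive an
  independent per-line shift of high variance, so their enrichment scores
  fluctuate and fail the coefficient-of-variation filter;
* a **tumor/normal cohort** whose survival hazard and clinical stage
  depend on a latent per-sample stemness trait ``z`` (tumors
  ``z ~ N(separation, 1)``, normals ``z ~ N(0, 1)``): survival times are
  exponential with rate ``lam * exp(beta * z_std)`` under independent
  uniform censoring, and advanced-stage/metastasis probabilities are
  logistic in the score quartile.

Gene-set truth structure: a core pool of signature genes is shared among
the planted sets (each core gene belongs to 4–6 of them, so the consensus
rule at membership >= 4 recovers exactly the core pool); every planted set
additionally carries private filler genes, and decoy sets draw from genes
outside the core, all pools pairwise disjoint.

Determinism: one global seed expands into fixed per-component substreams
(``SeedSequence(seed, spawn_key=(k,))``), so identical design + seed give
bitwise-identical outputs and adding a component never perturbs earlier
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .core_io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    PhenotypeLabels,
    SurvivalTable,
    ValidationError,
)

__all__ = [
    "SimulationDesign",
    "GeneSetTruth",
    "StemSomaticData",
    "CellLinePanel",
    "TumorCohort",
    "gen_stem_somatic",
    "gen_cellline_panel",
    "gen_tumor_cohort",
    "gen_contingency",
]

# fixed substream indices: adding components must not shift earlier draws
_SUB_GENESETS = 0
_SUB_STEM = 1
_SUB_PANEL = 2
_SUB_COHORT = 3
_SUB_CONTINGENCY = 4


def _rng(seed: int, component: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(component,)))
    )


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of the synthetic study; defaults are the reference design."""

    seed: int = 0
    n_genes: int = 2000
    sigma: float = 1.0  # log-scale noise sd
    delta: float = 2.0  # planted-set mean shift, in units of sigma
    # stem/somatic discrimination panel
    n_stem: int = 20
    n_somatic: int = 20
    # gene-set truth structure
    n_planted: int = 6  # discriminative + stable
    n_unstable: int = 3  # discriminative but unstable on the cell-line panel
    n_null: int = 6  # non-discriminative decoys
    core_signature_size: int = 120
    core_membership_range: tuple[int, int] = (4, 6)  # sets per core gene
    private_per_set: int = 20
    decoy_set_size: int = 60
    # cell-line panel
    n_lines: int = 200
    stable_shift: float = 2.0  # fixed shift of stable sets, sigma units
    unstable_shift_sd: float = 3.0  # per-line shift sd of unstable sets
    # tumor/normal cohort
    n_tumor: int = 500
    n_normal: int = 100
    separation: float = 2.5  # latent stemness mean shift of tumors, in latent SD
    beta: float = 0.7  # log-hazard per unit standardized score
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.3
    clinical_odds_mult: float = 2.0  # advanced-stage odds multiplier per quartile

    def __post_init__(self) -> None:
        counts = (
            self.n_genes, self.n_stem, self.n_somatic, self.n_planted,
            self.core_signature_size, self.n_lines, self.n_tumor, self.n_normal,
        )
        if any(c <= 0 for c in counts):
            raise ValidationError("all design counts must be positive")
        if self.sigma <= 0 or self.delta < 0 or self.baseline_hazard <= 0:
            raise ValidationError("sigma, baseline hazard must be > 0; delta >= 0")
        if not (0 <= self.censoring_rate < 1):
            raise ValidationError("censoring rate must be in [0, 1)")
        lo, hi = self.core_membership_range
        if not (1 <= lo <= hi <= self.n_planted):
            raise ValidationError("core membership range must fit in n_planted")
        needed = (
            self.core_signature_size
            + self.n_planted * self.private_per_set
            + (self.n_unstable + self.n_null) * self.decoy_set_size
        )
        if needed > self.n_genes:
            raise ValidationError(
                f"gene universe too small: need {needed}, have {self.n_genes}"
            )

    @property
    def design_auc(self) -> float:
        """Closed-form tumor-vs-normal AUC of the latent stemness trait."""
        return float(norm.cdf(self.separation / np.sqrt(2.0)))

    def manifest(self) -> dict:
        d = asdict(self)
        d["design_auc"] = self.design_auc
        return d


@dataclass(frozen=True)
class GeneSetTruth:
    """Which synthetic sets are planted/unstable/null, and the true signature."""

    planted: tuple[str, ...]
    unstable: tuple[str, ...]
    null: tuple[str, ...]
    signature_genes: tuple[str, ...]  # the core pool (membership >= 4 by design)


@dataclass(frozen=True)
class StemSomaticData:
    expression: ExpressionMatrix
    labels: PhenotypeLabels
    collection: GeneSetCollection
    truth: GeneSetTruth


@dataclass(frozen=True)
class CellLinePanel:
    expression: ExpressionMatrix
    stability: dict[str, bool]  # set name -> True if stable by construction
    collection: GeneSetCollection
    truth: GeneSetTruth


@dataclass(frozen=True)
class TumorCohort:
    expression: ExpressionMatrix
    labels: PhenotypeLabels  # 1 = tumor
    survival: SurvivalTable  # tumors only; covariates: stemness_z, age_z
    clinical: ClinicalTable  # tumors only
    truth_z: pd.Series  # latent stemness per sample (all samples)
    collection: GeneSetCollection
    gene_set_truth: GeneSetTruth


def _gene_universe(design: SimulationDesign) -> list[str]:
    width = len(str(design.n_genes))
    return [f"G{i:0{width}d}" for i in range(1, design.n_genes + 1)]


def build_gene_sets(
    design: SimulationDesign,
) -> tuple[GeneSetCollection, GeneSetTruth]:
    """Construct the candidate collection and its truth labels.

    Deterministic given the design (uses the gene-set substream only).
    """
    rng = _rng(design.seed, _SUB_GENESETS)
    genes = np.array(_gene_universe(design), dtype=object)
    perm = rng.permutation(design.n_genes)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = genes[perm[cursor : cursor + k]]
        cursor += k
        return out

    core = take(design.core_signature_size)
    lo, hi = design.core_membership_range
    planted_members: list[list[str]] = [[] for _ in range(design.n_planted)]
    for g in core:
        k = int(rng.integers(lo, hi + 1))
        for idx in rng.choice(design.n_planted, size=k, replace=False):
            planted_members[idx].append(str(g))
    sets: list[GeneSet] = []
    planted_names, unstable_names, null_names = [], [], []
    n_total = design.n_planted + design.n_unstable + design.n_null
    width = len(str(n_total))
    i_set = 0
    for members in planted_members:
        i_set += 1
        name = f"GS{i_set:0{width}d}"
        planted_names.append(name)
        full = list(members) + [str(g) for g in take(design.private_per_set)]
        sets.append(GeneSet(name=name, description="synthetic", members=tuple(sorted(full))))
    for _ in range(design.n_unstable):
        i_set += 1
        name = f"GS{i_set:0{width}d}"
        unstable_names.append(name)
        sets.append(GeneSet(
            name=name, description="synthetic",
            members=tuple(sorted(str(g) for g in take(design.decoy_set_size))),
        ))
    for _ in range(design.n_null):
        i_set += 1
        name = f"GS{i_set:0{width}d}"
        null_names.append(name)
        sets.append(GeneSet(
            name=name, description="synthetic",
            members=tuple(sorted(str(g) for g in take(design.decoy_set_size))),
        ))
    truth = GeneSetTruth(
        planted=tuple(planted_names),
        unstable=tuple(unstable_names),
        null=tuple(null_names),
        signature_genes=tuple(sorted(str(g) for g in core)),
    )
    return GeneSetCollection(tuple(sets)), truth


def _member_mask(genes: list[str], members: set[str]) -> np.ndarray:
    return np.array([g in members for g in genes])


def gen_stem_somatic(design: SimulationDesign) -> StemSomaticData:
    """Labeled stem/somatic panel with planted coordinate up-shifts."""
    collection, truth = build_gene_sets(design)
    if not truth.planted:
        raise ValidationError("design has no planted sets")
    rng = _rng(design.seed, _SUB_STEM)
    genes = _gene_universe(design)
    n = design.n_stem + design.n_somatic
    log_expr = rng.normal(0.0, design.sigma, size=(design.n_genes, n))
    shifted_genes: set[str] = set()
    for name in truth.planted + truth.unstable:  # discriminative sets
        shifted_genes |= set(collection[name].members)
    mask = _member_mask(genes, shifted_genes)
    log_expr[np.ix_(mask, np.arange(design.n_stem))] += design.delta * design.sigma
    samples = [f"stem{i:03d}" for i in range(1, design.n_stem + 1)] + [
        f"soma{i:03d}" for i in range(1, design.n_somatic + 1)
    ]
    matrix = ExpressionMatrix(
        pd.DataFrame(np.exp(log_expr), index=genes, columns=samples)
    )
    labels = PhenotypeLabels(
        pd.Series([1] * design.n_stem + [0] * design.n_somatic, index=samples),
        positive_name="stem",
        negative_name="somatic",
    )
    return StemSomaticData(matrix, labels, collection, truth)


def gen_cellline_panel(design: SimulationDesign) -> CellLinePanel:
    """Cell-line panel: stable sets shift every line, unstable per line."""
    collection, truth = build_gene_sets(design)
    rng = _rng(design.seed, _SUB_PANEL)
    genes = _gene_universe(design)
    log_expr = rng.normal(0.0, design.sigma, size=(design.n_genes, design.n_lines))
    stable_genes: set[str] = set()
    for name in truth.planted:
        stable_genes |= set(collection[name].members)
    log_expr[_member_mask(genes, stable_genes), :] += (
        design.stable_shift * design.sigma
    )
    for name in truth.unstable:
        mask = _member_mask(genes, set(collection[name].members))
        per_line = rng.normal(
            design.stable_shift * design.sigma,
            design.unstable_shift_sd * design.sigma,
            size=design.n_lines,
        )
        log_expr[mask, :] += per_line[None, :]
    lines = [f"line{i:04d}" for i in range(1, design.n_lines + 1)]
    matrix = ExpressionMatrix(
        pd.DataFrame(np.exp(log_expr), index=genes, columns=lines)
    )
    stability = {name: True for name in truth.planted}
    stability.update({name: False for name in truth.unstable + truth.null})
    return CellLinePanel(matrix, stability, collection, truth)


def _censor_horizon(design: SimulationDesign) -> float:
    """Uniform-censoring horizon c giving the target censoring fraction.

    With C ~ U(0, c) and T approximately exponential with effective rate
    lam_eff = lam * E[exp(beta * z)] = lam * exp(beta^2 / 2), the censored
    fraction is (1 - exp(-lam_eff * c)) / (lam_eff * c), solved for c.
    """
    rate = design.censoring_rate
    lam_eff = design.baseline_hazard * float(np.exp(design.beta**2 / 2.0))

    def frac(c: float) -> float:
        return (1.0 - np.exp(-lam_eff * c)) / (lam_eff * c) - rate

    return float(brentq(frac, 1e-9, 1e9))


def gen_tumor_cohort(design: SimulationDesign) -> TumorCohort:
    """Tumor/normal cohort with survival and clinical links to stemness."""
    collection, truth = build_gene_sets(design)
    rng = _rng(design.seed, _SUB_COHORT)
    genes = _gene_universe(design)
    n = design.n_tumor + design.n_normal
    z = np.concatenate([
        rng.normal(design.separation, 1.0, size=design.n_tumor),
        rng.normal(0.0, 1.0, size=design.n_normal),
    ])
    log_expr = rng.normal(0.0, design.sigma, size=(design.n_genes, n))
    sig_mask = _member_mask(genes, set(truth.signature_genes))
    # per-sample shift proportional to the latent trait; tumors average delta*sigma
    scale = design.delta * design.sigma / max(design.separation, 1e-12)
    log_expr[sig_mask, :] += scale * z[None, :]
    samples = [f"tumor{i:04d}" for i in range(1, design.n_tumor + 1)] + [
        f"normal{i:04d}" for i in range(1, design.n_normal + 1)
    ]
    matrix = ExpressionMatrix(
        pd.DataFrame(np.exp(log_expr), index=genes, columns=samples)
    )
    labels = PhenotypeLabels(
        pd.Series([1] * design.n_tumor + [0] * design.n_normal, index=samples),
        positive_name="tumor",
        negative_name="normal",
    )

    # --- survival (tumors only), exponential hazard in standardized z ---
    zt = z[: design.n_tumor]
    z_std = (zt - zt.mean()) / zt.std(ddof=0)
    rate = design.baseline_hazard * np.exp(design.beta * z_std)
    t_event = rng.exponential(1.0 / rate)
    if design.censoring_rate > 0:
        c_time = rng.uniform(0.0, _censor_horizon(design), size=design.n_tumor)
        time = np.minimum(t_event, c_time)
        event = (t_event <= c_time).astype(int)
    else:
        time, event = t_event, np.ones(design.n_tumor, dtype=int)
    time = np.maximum(time, 1e-9)  # strictly positive
    age_z = rng.normal(0.0, 1.0, size=design.n_tumor)  # hazard-independent
    survival = SurvivalTable(
        pd.DataFrame(
            {"time": time, "event": event, "stemness_z": z_std, "age_z": age_z},
            index=samples[: design.n_tumor],
        )
    )

    # --- clinical categories (tumors only), logistic in score quartile ---
    quart = pd.qcut(z_std, 4, labels=False, duplicates="drop")
    quart = np.asarray(quart, dtype=int)

    def logistic_draw(base_odds: float, mult: float) -> np.ndarray:
        odds = base_odds * mult**quart
        p = odds / (1.0 + odds)
        return rng.uniform(size=design.n_tumor) < p

    adv = logistic_draw(0.35, design.clinical_odds_mult)
    met = logistic_draw(0.40, design.clinical_odds_mult)
    male = rng.uniform(size=design.n_tumor) < 0.5
    older = rng.uniform(size=design.n_tumor) < 0.85
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "stage": np.where(adv, "III+IV", "I+II"),
                "distant_metastasis": np.where(met, "M1", "M0"),
                "gender": np.where(male, "Male", "Female"),
                "age_group": np.where(older, ">=50", "<50"),
            },
            index=samples[: design.n_tumor],
        )
    )
    return TumorCohort(
        expression=matrix,
        labels=labels,
        survival=survival,
        clinical=clinical,
        truth_z=pd.Series(z, index=samples),
        collection=collection,
        gene_set_truth=truth,
    )


def gen_contingency(
    n: int,
    odds_ratio: float,
    marker_rate: float = 0.5,
    clinical_base_rate: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired binary marker/clinical samples with a designed odds ratio.

    The marker is Bernoulli(``marker_rate``); given marker level, the
    clinical odds are ``clinical_base_rate`` odds times ``odds_ratio`` for
    marker-high samples.  Returns a frame with 'marker' (low/high) and
    'clinical' (level1/level2) columns indexed by sample id.
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    if odds_ratio <= 0:
        raise ValidationError("odds ratio must be positive")
    rng = _rng(seed, _SUB_CONTINGENCY)
    marker_high = rng.uniform(size=n) < marker_rate
    base_odds = clinical_base_rate / (1.0 - clinical_base_rate)
    odds = np.where(marker_high, base_odds * odds_ratio, base_odds)
    p = odds / (1.0 + odds)
    clinical_pos = rng.uniform(size=n) < p
    return pd.DataFrame(
        {
            "marker": np.where(marker_high, "high", "low"),
            "clinical": np.where(clinical_pos, "level2", "level1"),
        },
        index=[f"s{i:05d}" for i in range(1, n + 1)],
    )
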
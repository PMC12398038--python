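"""Signature distillation: AUC filter, CV filter, consensus, Pearson screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stemscore as ss
from stemscore.core_io import GeneSet, GeneSetCollection, PhenotypeLabels, ValidationError
from stemscore.distillation import (
    consensus_signature,
    correlation_screen,
    filter_discriminative,
    roc_auc,
    stability_cv,
)
from stemscore.ssgsea import ScoreMatrix

from _oracles import pairwise_auc, pearson_by_formula


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([1.0] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_mixed_case_matches_pair_enumeration(self):
        # pos {3,1,2}, neg {2,0}: 4.5 concordant of 6 pairs
        scores = [3, 1, 2, 2, 0]
        labels = [1, 1, 1, 0, 0]
        assert roc_auc(scores, labels) == pytest.approx(4.5 / 6)
        assert roc_auc(scores, labels) == pytest.approx(
            pairwise_auc([3, 1, 2], [2, 0])
        )

    def test_one_class_empty_is_error(self):
        with pytest.raises(ValidationError):
            roc_auc([1.0, 2.0], [1, 1])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_label_flip_complement_is_exact(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = rng.integers(0, 8, size=n).astype(float)
        labels = np.zeros(n, dtype=int)
        labels[: int(rng.integers(1, n))] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) + roc_auc(scores, 1 - labels) == 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_exhaustive_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 5, size=int(rng.integers(1, 8))).astype(float)
        neg = rng.integers(0, 5, size=int(rng.integers(1, 8))).astype(float)
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * len(pos) + [0] * len(neg))
        assert roc_auc(scores, labels) == pytest.approx(pairwise_auc(pos, neg))


def _score_matrix(rows: dict[str, list[float]], samples: list[str]) -> ScoreMatrix:
    return ScoreMatrix(
        scores=pd.DataFrame(rows, index=samples).T,
        alpha=0.25,
        normalized=False,
    )


class TestDiscriminativeFilter:
    def test_boundary_auc_is_retained(self):
        # 20 samples, one discordant pair out of 100 -> AUC exactly 0.95 stays
        pos = list(range(10))
        neg = [-1] * 9 + [9.5]  # beats 5 of the positives... construct exactly
        # simpler: engineered scores with AUC 0.95: pos ranks above all but
        # 5 half-ties
        scores = {"S": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 0, 0, 0, 0, 0, 0, 0, 0, 0, 5.0]}
        samples = [f"x{i}" for i in range(20)]
        labels = PhenotypeLabels(
            pd.Series([1] * 10 + [0] * 10, index=samples)
        )
        sm = _score_matrix(scores, samples)
        auc = roc_auc(np.array(scores["S"][:10] + scores["S"][10:]),
                      np.array([1] * 10 + [0] * 10))
        retained, rows = filter_discriminative(sm, labels, auc_min=auc)
        assert rows.loc["S", "auc"] == pytest.approx(auc)
        assert retained == ["S"]

    def test_planted_retained_nulls_rejected(self, stem_scores, stem_data):
        retained, rows = filter_discriminative(stem_scores, stem_data.labels)
        truth = stem_data.truth
        discriminative = set(truth.planted) | set(truth.unstable)
        assert discriminative <= set(retained)
        null_rejected = [n for n in truth.null if n not in retained]
        assert len(null_rejected) >= 0.95 * len(truth.null)

    def test_flipped_labels_select_complementary_sets(self, stem_scores, stem_data):
        flipped = PhenotypeLabels(1 - stem_data.labels.labels)
        _, rows = filter_discriminative(stem_scores, flipped)
        _, orig = filter_discriminative(stem_scores, stem_data.labels)
        assert np.allclose(rows["auc"] + orig["auc"], 1.0)


class TestStabilityCv:
    def test_constant_positive_scores_have_zero_cv(self):
        sm = _score_matrix({"S": [3.0, 3.0, 3.0], "T": [0.0, 1.0, 3.0]},
                           ["l1", "l2", "l3"])
        retained, rows = stability_cv(sm, cv_max=0.1)
        assert rows.loc["S", "cv"] == 0.0
        assert "S" in retained

    def test_cv_formula_on_rescaled_values(self):
        # after global min-max rescale, {0, ..., 1} spread: check sd/mean by hand
        sm = _score_matrix({"A": [0.9, 1.0, 1.1], "B": [0.0, 2.0, 1.0]},
                           ["l1", "l2", "l3"])
        _, rows = stability_cv(sm, cv_max=0.1)
        values = np.array([[0.9, 1.0, 1.1], [0.0, 2.0, 1.0]])
        rescaled = (values - values.min()) / (values.max() - values.min())
        for name, row in zip(["A", "B"], rescaled):
            assert rows.loc[name, "cv"] == pytest.approx(
                row.std(ddof=1) / row.mean()
            )

    def test_boundary_cv_exactly_point_one_retained(self):
        # dyadic values so the rescaled cv is exactly the double 0.1:
        # {0.5625, 0.625, 0.6875} -> sd 0.0625, mean 0.625
        rows_in = {
            "S": [0.5625, 0.625, 0.6875],
            "LO": [0.0, 0.0, 0.0],
            "HI": [1.0, 1.0, 1.0],  # pins the global rescale to the identity
        }
        sm = _score_matrix(rows_in, ["l1", "l2", "l3"])
        _, rows = stability_cv(sm, cv_max=0.1)
        assert rows.loc["S", "cv"] == 0.1
        assert bool(rows.loc["S", "passed_cv"])  # exclusion rule is strictly-greater

    def test_two_point_spread_excluded(self):
        sm = _score_matrix({"S": [0.5, 1.5], "LO": [0.0, 0.0], "HI": [2.0, 2.0]},
                           ["l1", "l2"])
        _, rows = stability_cv(sm, cv_max=0.1)
        # S rescales to {0.25, 0.75}: sd = 0.5/sqrt(2), mean 0.5
        assert rows.loc["S", "cv"] == pytest.approx((0.5 / np.sqrt(2)) / 0.5)
        assert not bool(rows.loc["S", "passed_cv"])

    def test_mean_zero_set_flagged_undefined(self):
        sm = _score_matrix({"Z": [0.0, 0.0], "HI": [1.0, 2.0]}, ["l1", "l2"])
        _, rows = stability_cv(sm, cv_max=10.0)
        assert not bool(rows.loc["Z", "cv_defined"])
        assert not bool(rows.loc["Z", "passed_cv"])

    def test_single_line_panel_is_error(self):
        sm = _score_matrix({"S": [1.0]}, ["l1"])
        with pytest.raises(ValidationError):
            stability_cv(sm)

    def test_planted_stable_unstable_split(self, panel_scores, panel_data):
        survivors = set(panel_data.truth.planted) | set(panel_data.truth.unstable)
        sub = ScoreMatrix(
            scores=panel_scores.scores.loc[sorted(survivors)],
            alpha=panel_scores.alpha,
            normalized=panel_scores.normalized,
        )
        retained, rows = stability_cv(sub)
        assert set(retained) == set(panel_data.truth.planted)
        for name in panel_data.truth.unstable:
            assert rows.loc[name, "cv"] > 0.3


class TestConsensus:
    def _coll(self, *member_lists):
        return GeneSetCollection(
            tuple(
                GeneSet(f"S{i}", "d", tuple(m))
                for i, m in enumerate(member_lists, start=1)
            )
        )

    def test_membership_boundary(self):
        coll = self._coll(["A", "B"], ["A", "C"], ["A", "D"], ["A"], ["B"])
        sig = consensus_signature(coll, min_membership=4)
        assert sig.genes == ("A",)
        assert sig.membership_count["A"] == 4

    def test_three_of_five_excluded(self):
        coll = self._coll(["B", "X"], ["B", "Y"], ["B"], ["Z"], ["W"])
        sig = consensus_signature(coll, min_membership=4)
        assert "B" not in sig.genes

    def test_min_membership_one_gives_union(self):
        coll = self._coll(["A", "B"], ["C"], ["D", "A"])
        sig = consensus_signature(coll, min_membership=1)
        assert set(sig.genes) == {"A", "B", "C", "D"}

    def test_sorted_by_count_then_name(self):
        coll = self._coll(["A", "B"], ["A", "B"], ["B"], ["A"])
        sig = consensus_signature(coll, min_membership=2)
        assert sig.genes == ("A", "B") or sig.genes == ("B", "A")
        # B appears 3 times, A 3 times -> tie broken by id
        assert sig.genes == ("A", "B")

    def test_empty_result_warns_not_errors(self, caplog):
        coll = self._coll(["A"], ["B"])
        with caplog.at_level("WARNING"):
            sig = consensus_signature(coll, min_membership=4)
        assert len(sig) == 0

    @given(st.integers(2, 6))
    @settings(max_examples=10, deadline=None)
    def test_raising_membership_never_grows_signature(self, k):
        coll = self._coll(["A", "B", "C"], ["A", "B"], ["A", "C"], ["A"], ["C", "B"])
        lower = consensus_signature(coll, min_membership=k - 1)
        higher = consensus_signature(coll, min_membership=k)
        assert set(higher.genes) <= set(lower.genes)


class TestCorrelationScreen:
    def _matrix(self, rows: dict[str, list[float]]):
        samples = [f"s{i}" for i in range(len(next(iter(rows.values()))))]
        return ss.ExpressionMatrix(pd.DataFrame(rows, index=samples).T), samples

    def test_proportional_gene_has_r_one_and_kept(self):
        m, samples = self._matrix({"G1": [2, 4, 6, 8], "G2": [5, 1, 2, 0]})
        score = pd.Series([1.0, 2.0, 3.0, 4.0], index=samples)
        out = correlation_screen(m, score)
        assert out.loc["G1", "r"] == pytest.approx(1.0)
        assert bool(out.loc["G1", "kept"])

    def test_constant_gene_excluded_with_warning(self, caplog):
        m, samples = self._matrix({"G1": [1, 2, 3], "FLAT": [5, 5, 5]})
        score = pd.Series([1.0, 2.0, 3.0], index=samples)
        with caplog.at_level("WARNING"):
            out = correlation_screen(m, score)
        assert "FLAT" not in out.index
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_hand_computed_pearson_and_decision(self):
        gene = [1.0, 2.0, 3.0, 4.0, 6.0]
        score_vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        r_expected, p_expected = pearson_by_formula(gene, score_vals)
        m, samples = self._matrix({"G1": gene, "PAD": [3, 1, 4, 1, 5]})
        score = pd.Series(score_vals, index=samples)
        out = correlation_screen(m, score)
        assert out.loc["G1", "r"] == pytest.approx(r_expected)
        assert out.loc["G1", "p"] == pytest.approx(p_expected)
        assert bool(out.loc["G1", "kept"]) == (r_expected > 0.4 and p_expected < 0.05)

    def test_too_few_samples_is_error(self):
        m, samples = self._matrix({"G1": [1, 2]})
        with pytest.raises(ValidationError):
            correlation_screen(m, pd.Series([1.0, 2.0], index=samples))


class TestPipelineMonotonicity:
    def test_stricter_thresholds_never_retain_more(self, stem_scores, stem_data,
                                                   panel_scores):
        r_base, _ = filter_discriminative(stem_scores, stem_data.labels, 0.95)
        r_strict, _ = filter_discriminative(stem_scores, stem_data.labels, 0.99)
        assert set(r_strict) <= set(r_base)
        c_base, _ = stability_cv(panel_scores, cv_max=0.1)
        c_strict, _ = stability_cv(panel_scores, cv_max=0.05)
        assert set(c_strict) <= set(c_base)
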
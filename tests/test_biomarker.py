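"""ROC statistics against pair-counting oracles; composite k-of-n scoring."""

import numpy as np
import pandas as pd
import pytest

from evrppa.biomarker import (
    GREATER,
    LESS,
    CompositeSignature,
    RocResult,
    combine_candidates,
    composite_score,
    evaluate_signature,
    roc_analysis,
    signature_from_matrix,
)


def auc_pair_counting(scores, labels):
    """(concordant + 0.5 * ties) / (n1 * n0), direction-free (>= 0.5)."""
    cases = [s for s, l in zip(scores, labels) if l == 1]
    controls = [s for s, l in zip(scores, labels) if l == 0]
    total = conc = ties = 0
    for c1 in cases:
        for c0 in controls:
            total += 1
            if c1 > c0:
                conc += 1
            elif c1 == c0:
                ties += 1
    auc = (conc + 0.5 * ties) / total
    return max(auc, 1.0 - auc)


def youden_scan(scores, labels, direction):
    """Best J over all midpoints between adjacent distinct scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    distinct = np.unique(scores)
    best_j = -np.inf
    for c in (distinct[:-1] + distinct[1:]) / 2.0:
        pos = scores > c if direction == GREATER else scores < c
        sens = pos[labels == 1].mean()
        spec = (~pos[labels == 0]).mean()
        best_j = max(best_j, sens + spec - 1.0)
    return best_j


class TestRocAnalysis:
    def test_perfect_separation(self):
        r = roc_analysis([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert 0.2 < r.cutoff < 0.8
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert r.direction == GREATER
        assert r.ci_low <= r.auc <= r.ci_high

    def test_constant_scores_are_uninformative(self):
        r = roc_analysis([5.0] * 6, [0, 0, 0, 1, 1, 1])
        assert r.auc == 0.5
        assert r.cutoff is None and r.degenerate

    def test_interleaved_example_auc(self):
        """3 of 4 case/control pairs concordant -> AUC 0.75."""
        r = roc_analysis([1, 2, 3, 4], [0, 1, 0, 1])
        assert r.auc == pytest.approx(0.75)

    def test_direction_flips_for_case_depleted_markers(self):
        r = roc_analysis([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1])
        assert r.direction == LESS
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_one_class_input_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2, 3], [1, 1, 1])

    @pytest.mark.parametrize("seed", range(20))
    def test_auc_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        scores = rng.choice(np.arange(8, dtype=float), size=n)  # forces ties
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=int(rng.integers(2, n - 1)), replace=False)] = 1
        if labels.sum() < 2 or (1 - labels).sum() < 2:
            return
        r = roc_analysis(scores, labels)
        assert r.auc == pytest.approx(auc_pair_counting(scores, labels), abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_cutoff_attains_exhaustive_max_youden(self, seed):
        rng = np.random.default_rng(100 + seed)
        scores = rng.normal(size=10)
        labels = np.array([0] * 5 + [1] * 5)
        r = roc_analysis(scores, labels)
        assert r.sensitivity + r.specificity - 1.0 == pytest.approx(
            youden_scan(scores, labels, r.direction), abs=1e-12
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=20)
        labels = (rng.random(20) < 0.5).astype(int)
        labels[:2] = 1
        labels[-2:] = 0
        base = roc_analysis(scores, labels)
        for transform in (np.exp, lambda x: x**3, lambda x: 5 * x + 2):
            r = roc_analysis(transform(scores), labels)
            assert r.auc == pytest.approx(base.auc, abs=1e-12)

    def test_delong_ci_and_p_behave_sensibly(self):
        rng = np.random.default_rng(21)
        strong = roc_analysis(
            np.concatenate([rng.normal(0, 1, 30), rng.normal(2, 1, 30)]),
            np.array([0] * 30 + [1] * 30),
        )
        weak = roc_analysis(
            np.concatenate([rng.normal(0, 1, 30), rng.normal(0.1, 1, 30)]),
            np.array([0] * 30 + [1] * 30),
        )
        assert strong.p_value < 1e-4 < weak.p_value
        assert strong.ci_low > 0.5 > weak.ci_low
        assert 0 <= strong.ci_low <= strong.auc <= strong.ci_high <= 1


class TestCompositeScore:
    @pytest.fixture
    def signature(self):
        return CompositeSignature(
            endpoints=("a", "b", "c", "d", "e"),
            cutoffs=(1.0, 1.0, 1.0, 1.0, 1.0),
            directions=(GREATER,) * 4 + (LESS,),
            k=3,
        )

    def test_saturation_floor_and_k_rule(self, signature):
        mat = pd.DataFrame(
            {
                "a": [2.0, 0.5, 2.0],
                "b": [2.0, 0.5, 2.0],
                "c": [2.0, 0.5, 2.0],
                "d": [2.0, 0.5, 0.5],
                "e": [0.5, 2.0, 2.0],  # 'less' direction
            },
            index=["all5", "none", "exactly3"],
        )
        scored = composite_score(mat, signature)
        assert scored.loc["all5", "score"] == 5 and scored.loc["all5", "positive"]
        assert scored.loc["none", "score"] == 0 and not scored.loc["none", "positive"]
        assert scored.loc["exactly3", "score"] == 3 and scored.loc["exactly3", "positive"]

    def test_missing_values_contribute_zero_and_are_counted(self, signature):
        mat = pd.DataFrame(
            {k: [2.0] for k in "abcd"} | {"e": [np.nan]}, index=["s"]
        )
        scored = composite_score(mat, signature)
        assert scored.loc["s", "score"] == 4
        assert scored.loc["s", "n_missing"] == 1

    def test_score_monotone_as_values_move_beyond_cutoffs(self, signature):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(
            rng.uniform(0, 2, size=(10, 5)), columns=list("abcde")
        )
        base = composite_score(mat, signature)["score"]
        pushed = mat.copy()
        pushed["a"] += 10.0          # further beyond 'greater' cutoff
        pushed["e"] -= 10.0          # further beyond 'less' cutoff
        after = composite_score(pushed, signature)["score"]
        assert (after >= base).all()

    def test_invalid_signature_rejected(self):
        with pytest.raises(ValueError):
            CompositeSignature(("a",), (1.0,), (GREATER,), k=2)
        with pytest.raises(ValueError):
            CompositeSignature(("a", "b"), (1.0,), (GREATER, LESS), k=1)

    def test_missing_endpoint_rejected(self, signature):
        with pytest.raises(ValueError, match="'e'"):
            composite_score(pd.DataFrame({k: [1.0] for k in "abcd"}), signature)


class TestCombineCandidates:
    def _labels(self, n0, n1):
        return np.array([0] * n0 + [1] * n1)

    def test_two_perfect_markers_stay_perfect(self):
        mat = pd.DataFrame(
            {"m1": [1, 2, 8, 9], "m2": [9, 8, 2, 1.0]},
            index=list("abcd"),
        )
        r = combine_candidates(mat, ["m1", "m2"], self._labels(2, 2))
        assert r.auc == 1.0

    def test_constant_marker_does_not_dilute(self):
        rng = np.random.default_rng(6)
        informative = np.concatenate([rng.normal(0, 1, 10), rng.normal(3, 1, 10)])
        mat = pd.DataFrame({"m1": informative, "m2": np.ones(20)})
        labels = self._labels(10, 10)
        combined = combine_candidates(mat, ["m1", "m2"], labels)
        solo_sig = signature_from_matrix(mat, ["m1"], labels, k=1)
        solo_score = composite_score(mat, solo_sig)["score"].to_numpy(dtype=float)
        solo = roc_analysis(solo_score, labels)
        assert combined.auc == pytest.approx(solo.auc, abs=1e-12)

    def test_duplicated_marker_equals_univariate_exceedance(self):
        rng = np.random.default_rng(7)
        v = np.concatenate([rng.normal(0, 1, 10), rng.normal(1.5, 1, 10)])
        mat = pd.DataFrame({"m1": v, "m2": v})
        labels = self._labels(10, 10)
        combined = combine_candidates(mat, ["m1", "m2"], labels)
        sig = signature_from_matrix(mat, ["m1"], labels, k=1)
        uni = roc_analysis(
            composite_score(mat, sig)["score"].to_numpy(dtype=float), labels
        )
        assert combined.auc == pytest.approx(uni.auc, abs=1e-12)

    def test_logistic_alternative_runs(self):
        rng = np.random.default_rng(10)
        mat = pd.DataFrame(
            {
                "m1": np.concatenate([rng.normal(0, 1, 15), rng.normal(2, 1, 15)]),
                "m2": np.concatenate([rng.normal(0, 1, 15), rng.normal(-1, 1, 15)]),
            }
        )
        r = combine_candidates(mat, ["m1", "m2"], self._labels(15, 15), method="logistic")
        assert r.auc > 0.8


class TestEvaluateSignature:
    def _cohort(self, seed=0, effect=3.0):
        rng = np.random.default_rng(seed)
        eps = list("abcde")
        controls = rng.lognormal(0, 0.2, size=(11, 5))
        cases = rng.lognormal(np.log(effect), 0.2, size=(13, 5))
        mat = pd.DataFrame(np.vstack([controls, cases]), columns=eps)
        labels = np.array([0] * 11 + [1] * 13)
        return mat, labels

    def test_separating_signature_reaches_auc_one(self):
        mat, labels = self._cohort(effect=50.0)
        sig = signature_from_matrix(mat, list("abcde"), labels, k=3)
        roc, confusion = evaluate_signature(mat, sig, labels)
        assert roc.auc == 1.0
        assert confusion["sensitivity"] == 1.0 and confusion["specificity"] == 1.0

    def test_permuted_labels_have_chance_auc(self):
        mat, labels = self._cohort(effect=3.0)
        sig = signature_from_matrix(mat, list("abcde"), labels, k=3)
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(200):
            perm = rng.permutation(labels)
            roc, _ = evaluate_signature(mat, sig, perm)
            aucs.append(roc.auc if roc.direction == GREATER else 1.0 - roc.auc)
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_k_equal_n_without_full_scores_gives_zero_sensitivity(self):
        mat = pd.DataFrame(
            {k: [0.5, 0.5, 2.0, 2.0] for k in "abcd"} | {"e": [0.5, 0.5, 0.5, 0.5]}
        )
        sig = CompositeSignature(
            endpoints=tuple("abcde"), cutoffs=(1.0,) * 5,
            directions=(GREATER,) * 5, k=5,
        )
        _, confusion = evaluate_signature(mat, sig, [0, 0, 1, 1])
        assert confusion["sensitivity"] == 0.0
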
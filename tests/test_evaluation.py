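import itertools
import math

import numpy as np
import pytest

from aclspeech.evaluation import (
    bcuar,
    confusion_matrix,
    diff_of_proportions_test,
    rank_features,
    reconstruction_cc,
    support_f1,
    uar,
)
from aclspeech.acl_core import ReconstructionSet
from tests_helpers_eval import make_identity_model


class TestUAR:
    def test_two_class_example(self):
        from aclspeech.evaluation import ConfusionMatrix

        cm = ConfusionMatrix(np.array([[9, 1], [2, 8]]), (0, 1))
        assert uar(cm) == pytest.approx(0.85)

    def test_perfect_diagonal(self):
        from aclspeech.evaluation import ConfusionMatrix

        cm = ConfusionMatrix(np.diag([5, 7, 1, 3]), ("n", "a", "s", "h"))
        assert uar(cm) == pytest.approx(1.0)

    def test_percentage_matrix_diagonal_mean(self):
        # four-class confusion already expressed in row percentages: UAR is
        # the mean of the diagonal entries divided by the row sum of 100
        from aclspeech.evaluation import ConfusionMatrix

        percent = np.array(
            [
                [80.8, 2.7, 11.7, 4.8],
                [6.1, 73.5, 4.0, 16.4],
                [13.0, 1.3, 81.3, 4.4],
                [6.0, 16.1, 7.3, 70.6],
            ]
        )
        cm = ConfusionMatrix(percent, ("neutral", "angry", "sad", "happy"))
        assert 100 * uar(cm) == pytest.approx(76.55)

    def test_invariant_to_support_rebalancing(self):
        from aclspeech.evaluation import ConfusionMatrix

        cm1 = ConfusionMatrix(np.array([[9, 1], [2, 8]]), (0, 1))
        cm2 = ConfusionMatrix(np.array([[90, 10], [2, 8]]), (0, 1))  # recalls kept
        assert uar(cm1) == pytest.approx(uar(cm2))

    def test_empty_class_is_named(self):
        from aclspeech.evaluation import ConfusionMatrix

        cm = ConfusionMatrix(np.array([[3, 0], [0, 0]]), ("ok", "empty"))
        with pytest.raises(ValueError, match="empty"):
            uar(cm)


class TestBCUAR:
    def test_balanced_binary_is_half(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 30)
        preds = rng.integers(0, 2, 60)
        assert bcuar(y, preds, 800, seed=1) == pytest.approx(0.5, abs=0.03)

    def test_balanced_four_class_is_quarter(self):
        rng = np.random.default_rng(2)
        y = np.repeat(np.arange(4), 15)
        preds = rng.integers(0, 4, 60)
        assert bcuar(y, preds, 800, seed=3) == pytest.approx(0.25, abs=0.03)

    def test_matches_exhaustive_enumeration_at_n8(self):
        # oracle: exact average UAR over all distinct label arrangements
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0])
        preds = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        scores = []
        for perm in set(itertools.permutations(y.tolist())):
            scores.append(uar(confusion_matrix(np.array(perm), preds, (0, 1))))
        exact = float(np.mean(scores))
        assert bcuar(y, preds, 4000, seed=4) == pytest.approx(exact, abs=0.02)

    def test_constant_majority_predictor_scores_half(self):
        # 70/30-style imbalance, predictor always says the majority class:
        # one recall is 1 and the other 0 under every permutation
        y = np.array([1, 1, 1, 1, 1, 1, 1, 0, 0, 0])
        preds = np.ones(10, dtype=int)
        assert bcuar(y, preds, 500, seed=5) == pytest.approx(0.5, abs=1e-12)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            bcuar(np.ones(10, dtype=int), np.ones(10, dtype=int), 100)


class TestReconstructionCC:
    def _recon(self, rng, m=50, d=4, k=2):
        Xr = rng.standard_normal((m, d))
        A = Xr @ rng.standard_normal((d, k)) + 0.1 * rng.standard_normal((m, k))
        return ReconstructionSet(Xr, A, tuple(f"T{i}" for i in range(k)))

    def test_perfect_and_anti_reconstruction(self):
        rng = np.random.default_rng(6)
        recon = self._recon(rng, k=1)
        from aclspeech.acl_core import fit_ar_model

        Xs = (recon.Xr - recon.Xr.mean(0)) / recon.Xr.std(0)
        w = np.linalg.lstsq(Xs, recon.A[:, 0], rcond=None)[0]
        model_pos = make_identity_model(np.column_stack([w]))
        model_neg = make_identity_model(np.column_stack([-w]))
        noiseless = ReconstructionSet(recon.Xr, (Xs @ w)[:, None], ("T0",))
        assert reconstruction_cc(model_pos, noiseless)[0] == pytest.approx(1.0)
        assert reconstruction_cc(model_neg, noiseless)[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(7)
        recon = self._recon(rng)
        W = rng.standard_normal((4, 2))
        model = make_identity_model(W)
        got = reconstruction_cc(model, recon)
        Xs = (recon.Xr - recon.Xr.mean(0)) / recon.Xr.std(0)
        for k in range(2):
            a, r = recon.A[:, k], Xs @ W[:, k]
            cov = np.mean((a - a.mean()) * (r - r.mean()))
            oracle = cov / (a.std() * r.std())
            assert got[k] == pytest.approx(oracle, rel=1e-10)

    def test_zero_variance_reconstruction_warns_and_scores_zero(self):
        rng = np.random.default_rng(8)
        recon = self._recon(rng, k=1)
        model = make_identity_model(np.zeros((4, 1)))
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            assert reconstruction_cc(model, recon)[0] == 0.0

    def test_per_speaker_averaging(self):
        rng = np.random.default_rng(9)
        recon = self._recon(rng, m=60, k=1)
        model = make_identity_model(rng.standard_normal((4, 1)))
        spk = np.repeat(["s1", "s2", "s3"], 20)
        avg = reconstruction_cc(model, recon, speaker_ids=spk)
        # decomposition identity: mean of the per-speaker correlations
        blocks = []
        Xs_all = (recon.Xr - recon.Xr.mean(0)) / recon.Xr.std(0)
        r_all = Xs_all @ model.W[:, 0]
        for s in ("s1", "s2", "s3"):
            a, r = recon.A[spk == s, 0], r_all[spk == s]
            blocks.append(np.corrcoef(a, r)[0, 1])
        assert avg[0] == pytest.approx(np.mean(blocks), rel=1e-10)


class TestDiffOfProportions:
    def test_identical_proportions_not_significant(self):
        z, sig = diff_of_proportions_test(30, 100, 30, 100)
        assert z == 0.0 and not sig

    def test_gross_difference_significant(self):
        z, sig = diff_of_proportions_test(90, 100, 50, 100)
        assert sig and z > 0

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.proportion import proportions_ztest

        z, _ = diff_of_proportions_test(60, 100, 50, 100)
        z_sm, p_sm = proportions_ztest([60, 50], [100, 100])
        assert z == pytest.approx(z_sm, rel=1e-10)

    def test_symmetry_up_to_sign(self):
        z1, s1 = diff_of_proportions_test(42, 80, 55, 90)
        z2, s2 = diff_of_proportions_test(55, 90, 42, 80)
        assert z1 == pytest.approx(-z2) and s1 == s2

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            diff_of_proportions_test(5, 4, 1, 10)


class TestFeatureRanking:
    def test_magnitude_order_and_zero_exclusion(self):
        assert rank_features(np.array([0.0, 3.0, -5.0]), ["f1", "f2", "f3"]) == [
            "f3",
            "f2",
        ]

    def test_all_zero_weights_empty(self):
        assert rank_features(np.zeros(4), list("abcd")) == []

    def test_top5_overlap_matches_set_intersection(self):
        rng = np.random.default_rng(10)
        names = [f"f{i}" for i in range(20)]
        w1, w2 = rng.standard_normal(20), rng.standard_normal(20)
        top1, top2 = set(rank_features(w1, names)[:5]), set(rank_features(w2, names)[:5])
        overlap = len(top1 & top2)
        # brute force over the raw magnitudes
        order1 = sorted(range(20), key=lambda i: -abs(w1[i]))[:5]
        order2 = sorted(range(20), key=lambda i: -abs(w2[i]))[:5]
        assert overlap == len({names[i] for i in order1} & {names[i] for i in order2})


class TestSupportF1:
    def test_exact_recovery(self):
        w = np.zeros(10)
        w[[2, 5]] = (1.0, -2.0)
        assert support_f1(w, [2, 5]) == 1.0

    def test_partial_overlap(self):
        w = np.zeros(6)
        w[[0, 1]] = 1.0
        # estimated {0,1}, truth {1,2}: precision 1/2, recall 1/2
        assert support_f1(w, [1, 2]) == pytest.approx(0.5)

    def test_zero_vector_against_nonempty_truth(self):
        assert support_f1(np.zeros(5), [0]) == 0.0


class TestAblation:
    @staticmethod
    def _planted_tables(seed, n=150, d=12):
        """Three targets, but only JAW_POS_Y shares support with the labels."""
        import pandas as pd
        from aclspeech.acl_core import sigmoid

        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, d))
        w_y = np.zeros(d)
        w_y[:4] = 3.0
        y = (rng.random(n) < sigmoid(X @ w_y)).astype(int)
        w_good = w_y.copy()
        w_bad1 = np.zeros(d)
        w_bad1[4:8] = 3.0
        w_bad2 = np.zeros(d)
        w_bad2[8:12] = 3.0
        A = np.column_stack(
            [X @ w + 0.3 * rng.standard_normal(n) for w in (w_good, w_bad1, w_bad2)]
        )
        speakers = np.array([f"spk{i % 3}" for i in range(n)])
        meta = pd.DataFrame(
            {
                "segment_id": [f"s{i}" for i in range(n)],
                "speaker_id": speakers,
                "corpus_id": "E",
                "unit_label": "FULL",
                "emotion": np.where(y == 1, "happy", "sad"),
            }
        )
        feats = pd.DataFrame(X, columns=[f"F{i}" for i in range(d)])
        features = pd.concat([meta, feats], axis=1)
        targets = pd.concat(
            [
                meta.drop(columns=["unit_label", "emotion"]),
                feats,
                pd.DataFrame(A, columns=["JAW_POS_Y", "LIP_POS_Y", "TNG_POS_Y"]),
            ],
            axis=1,
        )
        return features, targets

    def test_planted_informative_target_wins(self):
        from aclspeech.evaluation import ablate_targets
        from aclspeech.model_selection import LambdaGrid, ProtocolSpec

        wins = 0
        n_seeds = 20
        for s in range(n_seeds):
            features, targets = self._planted_tables(1000 + s)
            spec = ProtocolSpec(
                mode="speaker_dependent_repeated", train_ratio=0.25,
                selection_trials=2, evaluation_trials=2, seed=2000 + s,
            )
            report = ablate_targets(
                features, {"E": targets}, LambdaGrid((0.1,), (0.1,)), spec,
                task="arousal", speaker="spk0",
            )
            assert not report["failures"]
            if report["best_target"][0] == "JAW_POS_Y":
                wins += 1
        assert wins >= 18

    def test_single_target_ablation_equals_full_model(self):
        from aclspeech.evaluation import ablate_targets
        from aclspeech.model_selection import LambdaGrid, ProtocolSpec, grid_search

        features, targets = self._planted_tables(77)
        targets = targets.drop(columns=["LIP_POS_Y", "TNG_POS_Y"])  # K = 1
        spec = ProtocolSpec(
            mode="speaker_dependent_repeated", train_ratio=0.5,
            selection_trials=2, evaluation_trials=2, seed=3,
        )
        grid = LambdaGrid((0.1,), (0.1,))
        report = ablate_targets(
            features, {"E": targets}, grid, spec, task="arousal", speaker="spk0"
        )
        full = grid_search(
            features, {"E": targets}, grid, spec, task="arousal", speaker="spk0"
        )
        assert report["best_target"][0] == "JAW_POS_Y"
        assert report["best_target"][1] == pytest.approx(full.evaluation_mean_uar)
        assert report["best_group"][1] == pytest.approx(full.evaluation_mean_uar)

    def test_full_articulography_layout_report_shapes(self):
        from aclspeech.evaluation import ablate_targets
        from aclspeech.model_selection import LambdaGrid, ProtocolSpec
        from aclspeech.synthetic_corpus import GeneratorSpec, generate_corpus

        spec_gen = GeneratorSpec(
            n_segments=90, n_speakers=3, n_features=10, layout="ema",
            s_label=4, s_target=4, seed=5,
        )
        features, targets, _ = generate_corpus(spec_gen)
        spec = ProtocolSpec(
            mode="speaker_dependent_repeated", selection_trials=1,
            evaluation_trials=1, seed=6,
        )
        report = ablate_targets(
            features, {"E": targets}, LambdaGrid((0.1,), (0.05,)), spec,
            task="arousal", speaker=features["speaker_id"].iloc[0],
        )
        assert len(report["per_target"]) == 18
        assert sorted(report["per_group"]) == ["JAW", "LIP", "TNG"]


def test_analytic_chance_level_matches_permutation_limit():
    from aclspeech.evaluation import bcuar_analytic

    rng = np.random.default_rng(20)
    y = np.repeat([0, 1], 40)
    assert bcuar_analytic(y) == 0.5
    assert bcuar(y, rng.integers(0, 2, 80), 2000, seed=21) == pytest.approx(
        bcuar_analytic(y), abs=0.02
    )
    assert bcuar_analytic(["n", "a", "s", "h"]) == 0.25
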
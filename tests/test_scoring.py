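import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hst

from trtkit.io import Signature
from trtkit.scoring import (
    ScoreVector,
    SignatureScoreClassifier,
    aggregate_clone_scores,
    fit_threshold,
    scale_scores,
    score_average,
    score_rank_auc,
    score_rank_mean,
    score_u,
)
from conftest import make_cell_matrix


def _matrix_from_lognorm(values, clones=None, patients=None):
    """CellMatrix whose lognorm layer is set directly (genes x cells)."""
    values = np.asarray(values, dtype=float)
    cm = make_cell_matrix(np.zeros_like(values, dtype=int), clones=clones, patients=patients)
    cm.lognorm = values
    return cm


class TestScoreAverage:
    def test_single_gene_identity(self):
        # one signature gene; cell z-values fixed by construction
        vals = np.array([[0.0, 3.0], [1.0, 1.0]])
        cm = _matrix_from_lognorm(vals)
        sig = Signature(up=["g0"], down=[])
        sv = score_average(cm, sig)
        z = (vals[0] - vals[0].mean()) / vals[0].std()
        np.testing.assert_allclose(sv.raw.to_numpy(), z)
        assert sv.raw.iloc[1] == pytest.approx(1.0)

    def test_up_down_cancellation(self):
        vals = np.vstack([np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0])])
        cm = _matrix_from_lognorm(vals)
        sig = Signature(up=["g0"], down=["g1"])
        sv = score_average(cm, sig)
        np.testing.assert_allclose(sv.raw.to_numpy(), 0.0, atol=1e-12)

    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(5, 8))
        sig = Signature(up=["g0", "g2"], down=["g4"])
        a = score_average(_matrix_from_lognorm(vals), sig).raw
        b = score_average(_matrix_from_lognorm(vals + 7.5), sig).raw
        np.testing.assert_allclose(a, b)

    def test_all_genes_missing_rejected(self):
        cm = _matrix_from_lognorm(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="missing"):
            score_average(cm, Signature(up=["nope"], down=[]))


class TestScoreRankAuc:
    def test_perfect_enrichment_scores_one(self):
        G, S = 40, 4
        vals = -np.arange(G, dtype=float)[:, None]  # g0 highest
        cm = _matrix_from_lognorm(vals)
        sig = Signature(up=[f"g{i}" for i in range(S)], down=[])
        sv = score_rank_auc(cm, sig, top_frac=0.25)
        assert sv.raw.iloc[0] == pytest.approx(1.0)

    def test_random_sets_average_half_any_topfrac(self):
        # brute-force average over random permutations; independent of top_frac
        rng = np.random.default_rng(1)
        G, S = 30, 5
        sig = Signature(up=[f"g{i}" for i in range(S)], down=[])
        for top_frac in (0.1, 0.5):
            scores = []
            for _ in range(300):
                vals = rng.permutation(G).astype(float)[:, None]
                scores.append(
                    score_rank_auc(_matrix_from_lognorm(vals), sig, top_frac=top_frac).raw.iloc[0]
                )
            assert np.mean(scores) == pytest.approx(0.5, abs=0.03)

    def test_all_equal_expression_matches_tie_oracle(self):
        # all ranks tied at (G+1)/2: every signature/background pair is tied,
        # so the pairwise oracle gives exactly 0.5
        G, S = 12, 3
        cm = _matrix_from_lognorm(np.ones((G, 1)))
        sig = Signature(up=[f"g{i}" for i in range(S)], down=[])
        sv = score_rank_auc(cm, sig, top_frac=0.25)
        ranks = np.full(G, (G + 1) / 2.0)
        cap = int(np.ceil(0.25 * G))
        rc = np.minimum(ranks, cap + 1)
        oracle = np.mean(
            [
                0.5 if rc[s] == rc[o] else float(rc[s] < rc[o])
                for s in range(S)
                for o in range(S, G)
            ]
        )
        assert sv.raw.iloc[0] == pytest.approx(oracle, abs=1e-12)


class TestScoreU:
    def test_best_case_scores_one(self):
        G, S = 30, 4
        vals = -np.arange(G, dtype=float)[:, None]
        sig = Signature(up=[f"g{i}" for i in range(S)], down=[])
        sv = score_u(_matrix_from_lognorm(vals), sig, rank_cap=20)
        assert sv.raw.iloc[0] == pytest.approx(1.0)

    def test_worst_case_scores_zero(self):
        G, S = 30, 4
        vals = np.arange(G, dtype=float)[:, None]  # signature genes lowest
        sig = Signature(up=[f"g{i}" for i in range(S)], down=[])
        sv = score_u(_matrix_from_lognorm(vals), sig, rank_cap=20)
        assert sv.raw.iloc[0] == pytest.approx(0.0, abs=1e-12)

    @given(seed=hst.integers(0, 1000))
    def test_improving_a_rank_never_decreases_score(self, seed):
        rng = np.random.default_rng(seed)
        G = 20
        vals = rng.normal(size=G)
        sig = Signature(up=["g3", "g7"], down=[])
        before = score_u(_matrix_from_lognorm(vals[:, None]), sig, rank_cap=10).raw.iloc[0]
        vals2 = vals.copy()
        vals2[3] = vals.max() + 1.0  # push one signature gene to the top
        after = score_u(_matrix_from_lognorm(vals2[:, None]), sig, rank_cap=10).raw.iloc[0]
        assert after >= before - 1e-12


class TestScoreRankMean:
    def test_extreme_top_limit(self):
        G, S = 50, 5
        vals = -np.arange(G, dtype=float)[:, None]
        sig = Signature(up=[f"g{i}" for i in range(S)], down=[])
        sv = score_rank_mean(_matrix_from_lognorm(vals), sig)
        expected = (G - S) / (2.0 * G)  # -> 0.5 as G grows
        assert sv.raw.iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_random_set_expectation_zero(self):
        rng = np.random.default_rng(2)
        G, S = 25, 5
        sig = Signature(up=[f"g{i}" for i in range(S)], down=[])
        scores = [
            score_rank_mean(
                _matrix_from_lognorm(rng.permutation(G).astype(float)[:, None]), sig
            ).raw.iloc[0]
            for _ in range(400)
        ]
        assert np.mean(scores) == pytest.approx(0.0, abs=0.02)

    def test_reversal_negates_score(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(15, 4))
        sig = Signature(up=["g1", "g5"], down=[])
        a = score_rank_mean(_matrix_from_lognorm(vals), sig).raw
        b = score_rank_mean(_matrix_from_lognorm(-vals), sig).raw
        np.testing.assert_allclose(a.to_numpy(), -b.to_numpy(), atol=1e-12)


class TestScalingAndAggregation:
    def test_identity_scaling(self):
        sv = ScoreVector(raw=pd.Series([1.0, 2.0]), method="average")
        assert scale_scores(sv, 0.0, 1.0).scaled.tolist() == [1.0, 2.0]

    def test_affine_scaling(self):
        sv = ScoreVector(raw=pd.Series([2.0]), method="average")
        assert scale_scores(sv, 1.0, 0.5).scaled.iloc[0] == pytest.approx(2.0)

    def test_train_scores_self_standardize(self):
        rng = np.random.default_rng(4)
        raw = pd.Series(rng.normal(3, 2, 100))
        sv = scale_scores(
            ScoreVector(raw=raw, method="average"), raw.mean(), raw.std(ddof=0)
        )
        assert sv.scaled.mean() == pytest.approx(0.0, abs=1e-12)
        assert sv.scaled.std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_zero_sigma_rejected(self):
        sv = ScoreVector(raw=pd.Series([1.0]), method="average")
        with pytest.raises(ValueError, match="sigma"):
            scale_scores(sv, 0.0, 0.0)

    def test_clone_max_aggregation(self):
        cm = _matrix_from_lognorm(np.zeros((1, 3)), clones=["c1", "c1", "c1"])
        sv = ScoreVector(raw=pd.Series([0.2, 0.9, 0.4], index=cm.cell_barcodes), method="average")
        ct = pd.DataFrame({"clone_id": ["c1"]})
        agg = aggregate_clone_scores(sv, cm, ct)
        assert agg.raw.iloc[0] == pytest.approx(0.9)

    def test_adding_a_cell_never_lowers_clone_score(self):
        cm2 = _matrix_from_lognorm(np.zeros((1, 2)), clones=["c1", "c1"])
        cm3 = _matrix_from_lognorm(np.zeros((1, 3)), clones=["c1", "c1", "c1"])
        ct = pd.DataFrame({"clone_id": ["c1"]})
        sv2 = ScoreVector(raw=pd.Series([0.1, 0.5], index=cm2.cell_barcodes), method="m")
        sv3 = ScoreVector(raw=pd.Series([0.1, 0.5, -2.0], index=cm3.cell_barcodes), method="m")
        a = aggregate_clone_scores(sv2, cm2, ct).raw.iloc[0]
        b = aggregate_clone_scores(sv3, cm3, ct).raw.iloc[0]
        assert b >= a - 1e-12

    def test_unscored_clone_rejected(self):
        cm = _matrix_from_lognorm(np.zeros((1, 1)), clones=["c1"])
        sv = ScoreVector(raw=pd.Series([0.1], index=cm.cell_barcodes), method="m")
        with pytest.raises(ValueError, match="without scored cells"):
            aggregate_clone_scores(sv, cm, pd.DataFrame({"clone_id": ["c1", "c2"]}))


def _threshold_oracle(scores, labels):
    """Exhaustive accuracy search over adjacent-distinct midpoints."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    uniq = np.unique(scores)
    if uniq.size == 1:
        tau = float(uniq[0])
        return tau, float(np.mean(labels == (scores >= tau)))
    best_tau, best_acc = None, -1.0
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        tau = (lo + hi) / 2.0
        acc = float(np.mean(labels == (scores >= tau)))
        if acc > best_acc:
            best_acc, best_tau = acc, tau
    return best_tau, best_acc


class TestFitThreshold:
    @pytest.mark.parametrize(
        "scores,labels",
        [
            ([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]),
            ([0.1, 0.8, 0.2, 0.9], [0, 1, 0, 1]),
        ],
    )
    def test_separable_midpoint(self, scores, labels):
        tm = fit_threshold(scores, labels)
        assert tm.threshold == pytest.approx(0.5)
        assert tm.train_accuracy == 1.0

    def test_overlapping_matches_oracle(self):
        scores, labels = [0.1, 0.4, 0.3, 0.9], [0, 0, 1, 1]
        tm = fit_threshold(scores, labels)
        tau, acc = _threshold_oracle(scores, labels)
        assert tm.threshold == pytest.approx(tau)
        assert tm.train_accuracy == pytest.approx(acc)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(3, 15))
            scores = rng.choice(np.round(rng.normal(size=8), 2), n)
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            tm = fit_threshold(scores, labels)
            tau, acc = _threshold_oracle(scores, labels)
            assert abs(tm.threshold - tau) < 1e-12
            assert abs(tm.train_accuracy - acc) < 1e-12

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_threshold([0.1, 0.2], [1, 1])


class TestOrderInvariance:
    @pytest.mark.parametrize("fn", [score_average, score_rank_auc, score_u, score_rank_mean])
    def test_gene_and_cell_order_invariance(self, fn):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(12, 6))
        sig = Signature(up=["g2", "g7"], down=["g4"])
        base = fn(_matrix_from_lognorm(vals), sig).raw
        gp = rng.permutation(12)
        cm_g = make_cell_matrix(np.zeros((12, 6), dtype=int))
        cm_g.gene_ids = [f"g{i}" for i in gp]
        cm_g.lognorm = vals[gp]
        perm_genes = fn(cm_g, sig).raw
        np.testing.assert_allclose(base.to_numpy(), perm_genes.to_numpy(), atol=1e-12)
        cp = rng.permutation(6)
        cm_c = _matrix_from_lognorm(vals[:, cp])
        perm_cells = fn(cm_c, sig).raw
        np.testing.assert_allclose(base.to_numpy()[cp], perm_cells.to_numpy(), atol=1e-12)


class TestClassifierContract:
    def test_threshold_transfer_no_leakage(self, small_cohort):
        cm, ct, _ = small_cohort
        train_p = ["P01", "P02", "P03", "P04"]
        test_p = ["P05", "P06"]
        est = SignatureScoreClassifier(length=30)
        est.fit(cm.subset_patients(train_p), ct[ct["patient"].isin(train_p)])
        cm_te = cm.subset_patients(test_p)
        ct_te = ct[ct["patient"].isin(test_p)].copy()
        pred1 = est.predict(cm_te, ct_te)
        ct_mut = ct_te.copy()
        ct_mut["label"] = "tumor_reactive"  # mutate test labels
        pred2 = est.predict(cm_te, ct_mut)
        np.testing.assert_array_equal(pred1.to_numpy(), pred2.to_numpy())

    def test_fitted_attributes_present(self, small_cohort):
        cm, ct, _ = small_cohort
        est = SignatureScoreClassifier(length=20).fit(cm, ct)
        assert est.sigma_ > 0
        assert len(est.signature_) <= 20
        assert hasattr(est.threshold_model_, "threshold")

    def test_get_set_params_round_trip(self):
        est = SignatureScoreClassifier(length=33, score_method="u_score")
        params = est.get_params()
        est2 = SignatureScoreClassifier().set_params(**params)
        assert est2.length == 33 and est2.score_method == "u_score"
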
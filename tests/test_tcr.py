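import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hst
from sklearn.metrics import adjusted_rand_score

from trtkit.simulate import simulate_cdr3_families
from trtkit.tcr import (
    ATCHLEY_FACTORS,
    AvidityClassifier,
    cut_clusters,
    distance_matrix,
    featurize_cdr3,
    fit_avidity_model,
    predict_avidity,
    tcr_distance,
    upgma,
)


def upgma_cophenetic_oracle(d):
    """Brute-force average linkage; returns the cophenetic distance matrix."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    dist = {
        frozenset([i, j]): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = min(
            ((a, b) for a, b in itertools.combinations(keys, 2)),
            key=lambda ab: dist[frozenset(ab)],
        )
        a, b = best
        h = dist[frozenset(best)]
        ca, cb = clusters.pop(a), clusters.pop(b)
        merged = ca | cb
        for i in ca:
            for j in cb:
                coph[i, j] = coph[j, i] = h
        for k, ck in clusters.items():
            # size-weighted average of member pairwise distances
            dk = (len(ca) * dist[frozenset([a, k])] + len(cb) * dist[frozenset([b, k])]) / len(
                merged
            )
            dist[frozenset([next_id, k])] = dk
        clusters[next_id] = merged
        next_id += 1
    return coph


def cophenetic_from_dendrogram(dendro):
    import scipy.cluster.hierarchy as sch
    import scipy.spatial.distance as ssd

    return ssd.squareform(sch.cophenet(dendro.linkage))


class TestFeaturize:
    def test_homopolymer_equals_table_row(self):
        v = featurize_cdr3("AAAAAAAA")
        np.testing.assert_allclose(v[:-1], ATCHLEY_FACTORS.loc["A"].to_numpy())
        assert v[-1] == 3  # 8 residues minus mask (3, 2)

    def test_identical_sequences_identical_vectors(self):
        a = featurize_cdr3("CASSLGTDTQYF")
        b = featurize_cdr3("CASSLGTDTQYF")
        np.testing.assert_array_equal(a, b)

    def test_single_substitution_linearity(self):
        s1 = "CASSLGTDTQYF"
        s2 = "CASSRGTDTQYF"  # position 4 (inside the mask) L -> R
        n_core = len(s1) - 5
        delta = (ATCHLEY_FACTORS.loc["R"] - ATCHLEY_FACTORS.loc["L"]).to_numpy() / n_core
        np.testing.assert_allclose(
            featurize_cdr3(s2)[:-1] - featurize_cdr3(s1)[:-1], delta, atol=1e-12
        )

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError, match="invalid CDR3"):
            featurize_cdr3("CASX1")

    def test_short_sequence_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="shorter than mask"):
            v = featurize_cdr3("CASSL")
        assert v[-1] == 5


class TestAvidity:
    @staticmethod
    def _planted(n=120, seed=4):
        rng = np.random.default_rng(seed)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = ["".join(rng.choice(aa, 14)) for _ in range(n)]
        f1 = np.array([featurize_cdr3(s)[0] for s in seqs])
        labels = np.where(f1 >= np.median(f1), "high", "low")
        return seqs, labels

    def test_recovers_planted_rule(self):
        seqs, labels = self._planted()
        model = fit_avidity_model(seqs[:80], labels[:80])
        acc = np.mean(model.predict(seqs[80:]) == labels[80:])
        assert acc > 0.9

    def test_null_labels_near_chance(self):
        rng = np.random.default_rng(7)
        seqs, _ = self._planted(n=200, seed=8)
        labels = rng.choice(["high", "low"], 200)
        model = fit_avidity_model(seqs[:150], labels[:150])
        acc = np.mean(model.predict(seqs[150:]) == labels[150:])
        assert 0.3 <= acc <= 0.7

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both avidity classes"):
            fit_avidity_model(["CASSLGTDTQYF", "CASSLGTDTQYA"], ["high", "high"])

    def test_predict_avidity_handles_missing_beta(self):
        seqs, labels = self._planted(n=60, seed=9)
        model = fit_avidity_model(seqs, labels)
        ct = pd.DataFrame(
            {
                "clone_id": ["c1", "c2"],
                "patient": "P1",
                "cdr3a": ["CAV", "CAV"],
                "cdr3b": [seqs[0], None],
            }
        )
        with pytest.warns(UserWarning, match="lack CDR3beta"):
            out = predict_avidity(model, ct)
        assert out.loc[1, "avidity_call"] == "unknown"
        assert out.loc[0, "avidity_call"] in ("high", "low")

    def test_threshold_boundary_is_high(self):
        est = AvidityClassifier(threshold=0.5)
        est.scaler_ = None  # not used below

        class FakeModel:
            pass

        # probability exactly at the threshold maps to 'high' by the >= rule
        import numpy as np

        p = np.array([0.5, 0.49999])
        calls = np.where(p >= est.threshold, "high", "low")
        assert calls.tolist() == ["high", "low"]


class TestDistance:
    def test_identity_zero(self):
        t = ("CAVRDSNYQLIW", "CASSLGTDTQYF")
        assert tcr_distance(t, t) == 0.0

    def test_symmetry(self):
        a = ("CAVRDSNYQLIW", "CASSLGTDTQYF")
        b = ("CAVNARLMFAAA", "CASSPGQGATEAFF")
        assert tcr_distance(a, b) == pytest.approx(tcr_distance(b, a))

    def test_missing_alpha_uses_beta_only(self):
        a = (None, "CASSLGTDTQYF")
        b = ("CAVRDSNYQLIW", "CASSPGQGATEAFF")
        d = tcr_distance(a, b)
        d_beta = tcr_distance((None, a[1]), (None, b[1]))
        assert d == pytest.approx(d_beta)

    @given(seed=hst.integers(0, 500))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        t = [("".join(rng.choice(aa, 12)), "".join(rng.choice(aa, 14))) for _ in range(3)]
        d01 = tcr_distance(t[0], t[1])
        d12 = tcr_distance(t[1], t[2])
        d02 = tcr_distance(t[0], t[2])
        assert d02 <= d01 + d12 + 1e-9

    def test_distance_matrix_matches_pairwise(self):
        ct = pd.DataFrame(
            {
                "clone_id": ["c1", "c2", "c3"],
                "cdr3a": ["CAVRDSNYQLIW"] * 3,
                "cdr3b": ["CASSLGTDTQYF", "CASSLGTDTQYF", "CASSPGQGATEAFF"],
            }
        )
        dm = distance_matrix(ct)
        assert dm.shape == (3, 3)
        assert dm.loc["c1", "c2"] == 0.0  # identical TCRs
        for i, j in itertools.combinations(range(3), 2):
            expected = tcr_distance(
                (ct["cdr3a"][i], ct["cdr3b"][i]), (ct["cdr3a"][j], ct["cdr3b"][j])
            )
            assert dm.iloc[i, j] == pytest.approx(expected)
        np.testing.assert_allclose(dm.to_numpy(), dm.to_numpy().T)
        assert np.all(np.diag(dm.to_numpy()) == 0)


class TestUpgma:
    def test_hand_example(self):
        d = np.array([[0.0, 2, 6], [2, 0, 6], [6, 6, 0]])
        dendro = upgma(d)
        np.testing.assert_allclose(sorted(dendro.heights), [2.0, 6.0])
        assert dendro.linkage.shape == (2, 4)
        labels = cut_clusters(dendro, 2)
        assert labels.iloc[0] == labels.iloc[1] != labels.iloc[2]

    def test_merge_count(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(7, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        dendro = upgma(d)
        assert dendro.linkage.shape[0] == 6

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(3, 7))
            x = rng.normal(size=(n, 2))
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            got = cophenetic_from_dendrogram(upgma(d))
            want = upgma_cophenetic_oracle(d)
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_heights_monotone(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(8, 2))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        h = upgma(d).heights
        assert np.all(np.diff(h) >= -1e-12)

    def test_nan_rejected(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            upgma(d)

    def test_newick_export_parses(self):
        from skbio import TreeNode
        import io as _io

        d = np.array([[0.0, 2, 6], [2, 0, 6], [6, 6, 0]])
        nwk = upgma(d).to_newick()
        tree = TreeNode.read(_io.StringIO(nwk))
        assert {t.name for t in tree.tips()} == {"0", "1", "2"}


class TestCutClusters:
    def test_extremes(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(5, 2))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        dendro = upgma(d)
        assert cut_clusters(dendro, 5).nunique() == 5
        assert cut_clusters(dendro, 1).nunique() == 1
        with pytest.raises(ValueError, match="k must"):
            cut_clusters(dendro, 6)

    def test_family_recovery(self):
        seqs, fams = simulate_cdr3_families(3, 8, mutations=1, seed=21)
        ct = pd.DataFrame(
            {"clone_id": [f"c{i}" for i in range(len(seqs))], "cdr3a": None, "cdr3b": seqs}
        )
        dm = distance_matrix(ct)
        labels = cut_clusters(upgma(dm), 3)
        assert adjusted_rand_score(fams, labels.to_numpy()) == 1.0

    def test_degenerate_all_equal_still_k_clusters(self):
        d = np.zeros((6, 6))
        labels = cut_clusters(upgma(d), 4)
        assert labels.nunique() == 4
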
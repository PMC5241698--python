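"""Stratified sampling, oracle labelling and the random-forest classifier."""

import numpy as np
import pandas as pd
import pytest

import smlmkit as sk
from smlmkit.classify import LabelSet
from smlmkit.features import FeatureMatrix, PCABasis


def synthetic_features(x, fingerprint="abc"):
    x = np.asarray(x, dtype=float)
    basis = PCABasis(
        mean=np.zeros(x.shape[1]),
        components=np.eye(x.shape[1]),
        eigenvalues=np.ones(x.shape[1]),
    )
    return FeatureMatrix(raw=x, transformed=x, reduced=x, basis=basis)


class TestStratifiedSample:
    def test_even_spread_over_strata(self):
        table = pd.DataFrame({"frame": np.repeat(np.arange(1000), 10)})
        idx = sk.stratified_sample(table, n=300, rng_seed=0, n_strata=30)
        assert len(idx) == 300
        assert len(np.unique(idx)) == 300
        # per-stratum draw counts differ by at most 1 (same contiguous blocks
        # of time-ordered rows the sampler uses)
        order = np.argsort(table["frame"].to_numpy(), kind="stable")
        chosen = np.isin(order, idx)
        counts = [blk.sum() for blk in np.array_split(chosen, 30)]
        assert max(counts) - min(counts) <= 1

    def test_request_all_returns_identity(self):
        table = pd.DataFrame({"frame": np.arange(50)})
        idx = sk.stratified_sample(table, n=50)
        assert np.array_equal(np.sort(idx), np.arange(50))

    def test_seed_reproducible(self):
        table = pd.DataFrame({"frame": np.repeat(np.arange(100), 5)})
        a = sk.stratified_sample(table, n=60, rng_seed=7)
        b = sk.stratified_sample(table, n=60, rng_seed=7)
        assert np.array_equal(a, b)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            sk.stratified_sample(pd.DataFrame({"frame": []}), n=10)


class TestOracleLabel:
    @pytest.fixture()
    def sidecar(self):
        return pd.DataFrame(
            {
                "frame": [0, 1, 1, 2],
                "emitter_id": [0, 1, 2, 3],
                "x_nm": [1000.0, 2000.0, 2300.0, 5000.0],
                "y_nm": [1000.0, 2000.0, 2000.0, 5000.0],
                "on_fraction": [1.0, 1.0, 1.0, 1.0],
                "photons": [450.0] * 4,
            }
        )

    def make_table(self, rows):
        return pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm", "uncertainty_nm"])

    def test_close_lone_match_is_good(self, sidecar):
        table = self.make_table([[0, 1005.0, 1000.0, 5.0]])
        labels = sk.oracle_label(table, sidecar)
        assert labels.labels[0] == "good"

    def test_midpoint_of_pair_is_too_dense(self, sidecar):
        table = self.make_table([[1, 2150.0, 2000.0, 5.0]])
        labels = sk.oracle_label(table, sidecar)
        assert labels.labels[0] == "too_dense"

    def test_isolated_fit_is_background(self, sidecar):
        table = self.make_table([[2, 1000.0, 1000.0, 5.0]])
        labels = sk.oracle_label(table, sidecar)
        assert labels.labels[0] == "background"

    def test_matched_but_inaccurate_is_background(self, sidecar):
        # lone emitter within the match radius but error >> 3x uncertainty
        table = self.make_table([[0, 1100.0, 1000.0, 5.0]])
        labels = sk.oracle_label(table, sidecar)
        assert labels.labels[0] == "background"

    def test_missing_sidecar_rejected(self, sidecar):
        with pytest.raises(ValueError):
            sk.oracle_label(self.make_table([[0, 0.0, 0.0, 1.0]]), pd.DataFrame())


class TestForest:
    def test_separable_classes_learned_exactly(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 0.3, (100, 20)), rng.normal(5, 0.3, (100, 20))])
        y = np.array(["good"] * 100 + ["too_dense"] * 100, dtype=object)
        fm = synthetic_features(x)
        ls = LabelSet(np.arange(200), y, "user")
        model = sk.train_forest(fm, ls, rng_seed=0)
        pred = sk.classify_all(model, fm)
        assert np.all(pred.labels == y)

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(1)
        n = 4000
        x = rng.standard_normal((n, 20))
        y = np.array(["good"] * (n // 2) + ["background"] * (n // 2), dtype=object)
        rng.shuffle(y)
        fm_train = synthetic_features(x[: n // 2])
        ls = LabelSet(np.arange(n // 2), y[: n // 2], "user")
        model = sk.train_forest(fm_train, ls, rng_seed=1)
        fm_all = synthetic_features(x)
        # same basis data -> same fingerprint only if same vectors; rebuild model on all
        model.basis_fingerprint = fm_all.basis.fingerprint
        pred = sk.classify_all(model, fm_all)
        acc = (pred.labels[n // 2 :] == y[n // 2 :]).mean()
        assert abs(acc - 0.5) < 0.05

    def test_single_class_refused(self):
        fm = synthetic_features(np.zeros((10, 20)))
        ls = LabelSet(np.arange(10), np.array(["good"] * 10, dtype=object), "user")
        with pytest.raises(ValueError, match="two classes"):
            sk.train_forest(fm, ls)

    def test_same_seed_same_predictions(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((150, 20))
        y = np.array(["good", "background", "too_dense"] * 50, dtype=object)
        fm = synthetic_features(x)
        ls = LabelSet(np.arange(150), y, "user")
        p1 = sk.classify_all(sk.train_forest(fm, ls, rng_seed=5), fm)
        p2 = sk.classify_all(sk.train_forest(fm, ls, rng_seed=5), fm)
        assert np.array_equal(p1.labels, p2.labels)

    def test_fingerprint_mismatch_hard_error(self):
        rng = np.random.default_rng(3)
        fm1 = synthetic_features(rng.standard_normal((50, 20)))
        fm2 = synthetic_features(rng.standard_normal((50, 20)))
        fm2.basis.mean += 1.0  # a basis fitted on different data
        y = np.array(["good", "background"] * 25, dtype=object)
        model = sk.train_forest(fm1, LabelSet(np.arange(50), y, "user"))
        with pytest.raises(ValueError, match="fingerprint"):
            sk.classify_all(model, fm2)

    def test_vote_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        fm = synthetic_features(rng.standard_normal((80, 20)))
        y = np.array(["good", "too_dense"] * 40, dtype=object)
        model = sk.train_forest(fm, LabelSet(np.arange(80), y, "user"))
        pred = sk.classify_all(model, fm)
        assert np.allclose(pred.vote_fractions.sum(axis=1), 1.0)


class TestSplit:
    def test_counts_conserved(self):
        table = pd.DataFrame({"x_nm": np.arange(10.0), "y_nm": np.zeros(10)})
        labels = LabelSet(
            np.arange(10),
            np.array(
                ["good"] * 4 + ["background"] * 3 + ["too_dense"] * 3, dtype=object
            ),
            "predicted",
        )
        good, misfit = sk.split_reconstruction(table, labels)
        assert len(good) == 4 and len(misfit) == 6

    def test_all_good_empty_misfit(self):
        table = pd.DataFrame({"x_nm": [1.0, 2.0], "y_nm": [0.0, 0.0]})
        labels = LabelSet(np.arange(2), np.array(["good", "good"], dtype=object), "predicted")
        good, misfit = sk.split_reconstruction(table, labels)
        assert len(misfit) == 0 and len(good) == 2

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown labels"):
            LabelSet(np.array([0]), np.array(["great"], dtype=object), "user")
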
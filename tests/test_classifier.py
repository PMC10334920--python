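import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dermatone import classifier, evalstats, fixtures
from dermatone.features import fixture_extractor
from dermatone.pipeline import _fixture_cohort


class _StubModel:
    """Duck-typed model exposing decision_scores/classes_ for evaluate()."""

    classes_ = np.array(["benign", "malignant"])

    def __init__(self, scores):
        self._scores = np.asarray(scores, dtype=float)

    def decision_scores(self, X):
        return self._scores


class TestSplit:
    def test_published_sizes(self):
        man = fixtures.make_synthetic_manifest(634, 460)
        tr, va = classifier.split_dataset(man, 0.8, seed=0)
        assert (len(tr), len(va)) == (875, 219)

    def test_disjoint_exhaustive_deterministic(self):
        man = fixtures.make_synthetic_manifest(30, 20)
        tr1, va1 = classifier.split_dataset(man, 0.8, seed=5)
        tr2, va2 = classifier.split_dataset(man, 0.8, seed=5)
        ids_tr, ids_va = set(tr1.frame.image_id), set(va1.frame.image_id)
        assert ids_tr.isdisjoint(ids_va)
        assert ids_tr | ids_va == set(man.frame.image_id)
        assert set(tr2.frame.image_id) == ids_tr
        tr3, _ = classifier.split_dataset(man, 0.8, seed=6)
        assert set(tr3.frame.image_id) != ids_tr

    def test_stratified_class_balance(self):
        man = fixtures.make_synthetic_manifest(80, 20)
        tr, va = classifier.split_dataset(man, 0.8, seed=0)
        assert tr.class_counts()["malignant"] == 64
        assert va.class_counts()["malignant"] == 16

    def test_invalid_fraction(self):
        man = fixtures.make_synthetic_manifest(2, 2)
        with pytest.raises(ValueError):
            classifier.split_dataset(man, 1.0)


class TestGeometricAugment:
    def test_flip_involution(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (12, 12, 3))
        h = classifier.geometric_augment(img, [("hflip", None)])[0]
        hh = classifier.geometric_augment(h, [("hflip", None)])[0]
        assert np.array_equal(hh, img)
        v = classifier.geometric_augment(img, [("vflip", None)])[0]
        assert np.array_equal(v[::-1], img)

    def test_rotate_360_identity(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0.2, 0.8, (16, 16, 3))
        out = classifier.geometric_augment(img, [("rotate", 360.0)])[0]
        assert np.allclose(out, img, atol=1e-9)

    def test_rotate_90_matches_transpose(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 1, (16, 16, 3))
        out = classifier.geometric_augment(img, [("rotate", 90.0)])[0]
        # 90-degree rotation of a square image is an exact index permutation
        assert np.allclose(out, np.rot90(img, 1, axes=(0, 1)), atol=1e-9)

    def test_zero_noise_identity_and_clipping(self):
        img = np.full((8, 8, 3), 0.99)
        out = classifier.geometric_augment(img, [("noise", 0.0)])[0]
        assert np.array_equal(out, img)
        noisy = classifier.geometric_augment(img, [("noise", 0.5)], seed=3)[0]
        assert noisy.max() <= 1.0 and noisy.min() >= 0.0

    def test_noise_seeded(self):
        img = np.full((8, 8, 3), 0.5)
        a = classifier.geometric_augment(img, [("noise", 0.1)], seed=4)[0]
        b = classifier.geometric_augment(img, [("noise", 0.1)], seed=4)[0]
        c = classifier.geometric_augment(img, [("noise", 0.1)], seed=5)[0]
        assert np.array_equal(a, b) and not np.array_equal(a, c)

    def test_invalid_ops(self):
        img = np.zeros((4, 4, 3))
        with pytest.raises(ValueError):
            classifier.geometric_augment(img, [("rotate", float("nan"))])
        with pytest.raises(ValueError):
            classifier.geometric_augment(img, [("shear", 0.1)])


def _generated_plan(manifest):
    """Fake generated-image manifest with the full style triple per eligible image."""
    rows = []
    eligible = manifest.frame[
        manifest.frame["tone_category"].isin(("light", "intermediate"))
    ]
    for _, row in eligible.iterrows():
        for style in classifier.GENERATED_STYLES:
            rows.append(
                {
                    "image_id": f"{row.image_id}__{style}",
                    "path": f"gen/{row.image_id}__{style}.png",
                    "content_id": row.image_id,
                    "style": style,
                }
            )
    return pd.DataFrame(rows, columns=["image_id", "path", "content_id", "style"])


class TestRegimes:
    def _manifest(self, tones):
        n_mal = len(tones) // 2 + len(tones) % 2
        return fixtures.make_synthetic_manifest(n_mal, len(tones) - n_mal, tone_categories=tones)

    def test_regime_sizes_exact(self):
        man = self._manifest(["light"] * 4 + ["dark"] * 2)
        gen = _generated_plan(man)
        n, n_el, k = 6, 4, len(classifier.DEFAULT_GEOMETRIC_OPS)
        sizes = {
            "a_none": n,
            "b_generated": n + 3 * n_el,
            "c_geometric": n * (1 + k),
            "d_both": n + 3 * n_el + n * k,
        }
        for regime, expected in sizes.items():
            spec = classifier.RegimeSpec(regime, generated_manifest=gen)
            assert len(classifier.build_regime(man, spec)) == expected

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(n_eligible=st.integers(0, 12), n_other=st.integers(1, 12), k=st.integers(1, 6))
    def test_regime_size_property(self, n_eligible, n_other, k):
        man = self._manifest(["intermediate"] * n_eligible + ["brown"] * n_other)
        gen = _generated_plan(man)
        ops = classifier.DEFAULT_GEOMETRIC_OPS[:k]
        n = n_eligible + n_other
        spec = classifier.RegimeSpec("d_both", geometric_ops=ops, generated_manifest=gen)
        assert len(classifier.build_regime(man, spec)) == n + 3 * n_eligible + n * k

    def test_missing_triple_rejected(self):
        man = self._manifest(["light", "dark"])
        gen = _generated_plan(man)
        gen = gen[gen["style"] != "brown"]  # break the triple
        spec = classifier.RegimeSpec("b_generated", generated_manifest=gen)
        with pytest.raises(ValueError, match="triple"):
            classifier.build_regime(man, spec)

    def test_missing_generated_manifest_rejected(self):
        man = self._manifest(["light"])
        with pytest.raises(ValueError):
            classifier.build_regime(man, classifier.RegimeSpec("b_generated"))

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError):
            classifier.RegimeSpec("e_extra")

    def test_labels_inherited(self):
        man = self._manifest(["light", "light"])
        gen = _generated_plan(man)
        frame = classifier.build_regime(
            man, classifier.RegimeSpec("d_both", generated_manifest=gen)
        )
        by_parent = frame.groupby("parent_id")["class_label"].nunique()
        assert (by_parent == 1).all()

    def test_leakage_detected(self):
        man = self._manifest(["light"] * 4)
        gen = _generated_plan(man)
        tr, va = classifier.split_dataset(man, 0.5, seed=0, stratify=False)
        fa = classifier.build_regime(tr, classifier.RegimeSpec("d_both", generated_manifest=gen))
        fb = classifier.build_regime(va, classifier.RegimeSpec("a_none"))
        classifier.check_no_leakage(fa, fb)  # disjoint partitions pass
        with pytest.raises(ValueError, match="leakage"):
            classifier.check_no_leakage(fa, fa)

    def test_materialize_geometric_rows(self):
        man = self._manifest(["dark", "dark"])
        frame = classifier.build_regime(man, classifier.RegimeSpec("c_geometric"))
        rng = np.random.default_rng(9)
        imgs = {i: rng.uniform(0, 1, (8, 8, 3)) for i in man.frame.image_id}
        X, y = classifier.materialize(frame, image_loader=lambda i: imgs[i], seed=0)
        assert X.shape == (2 * (1 + len(classifier.DEFAULT_GEOMETRIC_OPS)), 8, 8, 3)
        hrow = frame[frame.augment_op == "hflip"].iloc[0]
        pos = frame.index.get_loc(hrow.name)
        assert np.array_equal(X[pos], imgs[hrow.parent_id][:, ::-1])


@pytest.fixture(scope="module")
def separable_cohort():
    man, imgs, _ = _fixture_cohort(200, (48.0, 35.0), 32, seed=0, tag="S")
    X = np.stack([imgs[i] for i in man.frame.image_id])
    y = man.frame.class_label.to_numpy()
    return X, y


class TestLesionClassifier:
    def test_separable_training_accuracy(self, separable_cohort):
        X, y = separable_cohort
        model = classifier.LesionClassifier(
            epochs=30, seed=0, extractor=fixture_extractor(seed=0)
        ).fit(X, y)
        assert model.history_["train_accuracy"].iloc[-1] >= 0.95
        assert len(model.history_) == 30
        assert set(model.history_.columns) >= {"epoch", "loss", "train_accuracy", "lr"}

    def test_deterministic_fit(self, separable_cohort):
        X, y = separable_cohort
        X, y = X[:40], y[:40]
        a = classifier.LesionClassifier(epochs=3, seed=1, extractor=fixture_extractor(seed=1)).fit(X, y)
        b = classifier.LesionClassifier(epochs=3, seed=1, extractor=fixture_extractor(seed=1)).fit(X, y)
        assert np.array_equal(a.predict_proba(X[:8]), b.predict_proba(X[:8]))
        pd.testing.assert_frame_equal(a.history_, b.history_)

    def test_single_class_rejected(self, separable_cohort):
        X, y = separable_cohort
        with pytest.raises(ValueError):
            classifier.LesionClassifier(epochs=1).fit(X[:6], np.array(["benign"] * 6))

    def test_lr_drops_exactly_once_after_plateau(self, separable_cohort):
        X, y = separable_cohort
        X, y = X[:24], y[:24]
        # identical validation images with opposite labels pin validation
        # accuracy at exactly 0.5, so the plateau counter hits `patience`
        # once within 8 epochs
        X_val = np.stack([X[0], X[0]])
        y_val = np.array(["benign", "malignant"])
        model = classifier.LesionClassifier(
            epochs=8, patience=5, seed=0, extractor=fixture_extractor(seed=0)
        ).fit(X, y, X_val, y_val)
        lrs = model.history_["lr"].to_numpy()
        assert np.allclose(lrs[:6], model.learning_rate)
        assert np.allclose(lrs[6:], model.learning_rate * model.lr_factor)

    def test_lr_floor_respected(self, separable_cohort):
        X, y = separable_cohort
        X_val = np.stack([X[0], X[0]])
        y_val = np.array(["benign", "malignant"])
        model = classifier.LesionClassifier(
            epochs=6, patience=1, learning_rate=2e-6, lr_floor=1e-6,
            seed=0, extractor=fixture_extractor(seed=0),
        ).fit(X[:8], y[:8], X_val, y_val)
        assert model.history_["lr"].min() >= 1e-6

    def test_frozen_weights_unchanged_by_training(self, separable_cohort):
        X, y = separable_cohort
        model = classifier.LesionClassifier(epochs=1, seed=0, extractor=fixture_extractor(seed=0))
        model.fit(X[:16], y[:16])
        before = model.frozen_checksum()
        model.fit(X[:64], y[:64])
        assert model.frozen_checksum() == before

    def test_predict_before_fit_rejected(self):
        with pytest.raises(RuntimeError):
            classifier.LesionClassifier().predict(np.zeros((1, 8, 8, 3)))

    def test_sklearn_params_round_trip(self):
        model = classifier.LesionClassifier(epochs=7, learning_rate=0.01)
        params = model.get_params()
        assert params["epochs"] == 7
        clone = classifier.LesionClassifier().set_params(**params)
        assert clone.epochs == 7 and clone.learning_rate == 0.01


class TestEvaluate:
    def test_perfect_model(self):
        y = np.array(["benign"] * 5 + ["malignant"] * 5)
        ev = classifier.evaluate(_StubModel([0.1] * 5 + [0.9] * 5), np.zeros((10, 4, 4, 3)), y)
        assert ev["accuracy"].estimate == 1.0
        assert ev["auc"] == 1.0

    def test_coin_flip_calibration(self):
        rng = np.random.default_rng(0)
        y = np.array(["benign", "malignant"] * 20)
        aucs = [
            classifier.evaluate(_StubModel(rng.uniform(0, 1, 40)), np.zeros((40, 2, 2, 3)), y)["auc"]
            for _ in range(500)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_accuracy_ci_containment(self):
        # 76 of 100 correct overall with both classes present
        y = np.array(["malignant"] * 50 + ["benign"] * 50)
        scores = np.concatenate([
            np.full(38, 0.9), np.full(12, 0.1),   # 38 of 50 positives right
            np.full(38, 0.1), np.full(12, 0.9),   # 38 of 50 negatives right
        ])
        ev = classifier.evaluate(_StubModel(scores), np.zeros((100, 2, 2, 3)), y)
        assert ev["accuracy"].estimate == pytest.approx(0.76)
        assert ev["accuracy"].lower <= 0.76 <= ev["accuracy"].upper
        assert ev["auc_ci"][0] <= ev["auc"] <= ev["auc_ci"][1]

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            classifier.evaluate(_StubModel([]), np.zeros((0, 2, 2, 3)), np.array([]))

    def test_scores_persisted_for_delong(self):
        y = np.array(["benign", "malignant"] * 10)
        ev_a = classifier.evaluate(_StubModel(np.linspace(0, 1, 20)), np.zeros((20, 2, 2, 3)), y)
        ev_b = classifier.evaluate(_StubModel(np.linspace(1, 0, 20)), np.zeros((20, 2, 2, 3)), y)
        res = evalstats.delong_test(
            ev_a["scores"]["score"], ev_b["scores"]["score"], ev_a["scores"]["label"]
        )
        assert res["auc_a"] == pytest.approx(ev_a["auc"], abs=1e-12)
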
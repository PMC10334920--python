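import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dermatone import fixtures, generation as gen
from dermatone.features import FeatureSet


def brute_force_gram(F):
    C = F.shape[0]
    N = F.shape[1] * F.shape[2]
    G = np.zeros((C, C))
    flat = F.reshape(C, N)
    for i in range(C):
        for j in range(C):
            G[i, j] = sum(flat[i, p] * flat[j, p] for p in range(N))
    return G / (C * N)


class TestGram:
    def test_zero_features(self):
        assert np.all(gen.gram_matrix(np.zeros((2, 3, 3))) == 0)

    def test_constant_single_channel(self):
        G = gen.gram_matrix(np.ones((1, 2, 2)))
        assert G == pytest.approx(np.array([[1.0]]))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        F = rng.standard_normal((3, 4, 4))
        G = gen.gram_matrix(F)
        B = brute_force_gram(F)
        assert np.max(np.abs(G - B)) < 1e-10 * max(1.0, np.max(np.abs(B)))
        # symmetric PSD
        assert np.allclose(G, G.T)
        assert np.min(np.linalg.eigvalsh(G)) > -1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gen.gram_matrix(np.zeros((0, 2, 2)))


class TestLosses:
    def test_content_loss_identity_and_count(self):
        rng = np.random.default_rng(1)
        F = FeatureSet({"l": rng.standard_normal((2, 3, 3))})
        assert gen.content_loss(F, F) == 0.0
        zeros = FeatureSet({"l": np.zeros((2, 3, 3))})
        ones = FeatureSet({"l": np.ones((2, 3, 3))})
        assert gen.content_loss(zeros, ones) == pytest.approx(18 / 2)

    def test_content_loss_brute_force(self):
        rng = np.random.default_rng(2)
        a = {"x": rng.standard_normal((2, 3, 4)), "y": rng.standard_normal((3, 2, 2))}
        b = {k: rng.standard_normal(v.shape) for k, v in a.items()}
        expected = sum(0.5 * np.sum((b[k] - a[k]) ** 2) for k in a)
        got = gen.content_loss(FeatureSet(a), FeatureSet(b))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_style_loss_identity_and_value(self):
        rng = np.random.default_rng(3)
        F = FeatureSet({"l": rng.standard_normal((2, 4, 4))})
        assert gen.style_loss(F, F) == 0.0
        # single channel constant features: Grams [[1]] vs [[3]] -> (3-1)^2 = 4
        s = FeatureSet({"l": np.ones((1, 2, 2))})
        g = FeatureSet({"l": np.full((1, 2, 2), np.sqrt(3.0))})
        assert gen.style_loss(s, g) == pytest.approx(4.0)

    def test_style_loss_brute_force(self):
        rng = np.random.default_rng(4)
        a = {"x": rng.standard_normal((3, 4, 4))}
        b = {"x": rng.standard_normal((3, 4, 4))}
        expected = np.sum((brute_force_gram(b["x"]) - brute_force_gram(a["x"])) ** 2)
        assert gen.style_loss(FeatureSet(a), FeatureSet(b)) == pytest.approx(
            expected, rel=1e-10
        )

    def test_shape_mismatch_rejected(self):
        a = FeatureSet({"l": np.zeros((2, 3, 3))})
        b = FeatureSet({"l": np.zeros((2, 4, 4))})
        with pytest.raises(ValueError):
            gen.content_loss(a, b)

    @pytest.mark.parametrize(
        "alpha,beta,c,s,expected", [(0.0, 1.0, 3.0, 5.0, 5.0), (1.0, 0.0, 3.0, 5.0, 3.0), (1.0, 2.0, 3.0, 5.0, 13.0)]
    )
    def test_total_loss(self, alpha, beta, c, s, expected):
        assert gen.st_total_loss(c, s, alpha, beta) == expected


class TestPoissonLoss:
    def test_zero_on_exact_composite(self, lesion_pair):
        content, mask, style = lesion_pair
        blend = gen.composite_image(content, style, mask)
        assert gen.poisson_gradient_loss(blend, content, style, mask) == 0.0

    def test_constant_images_zero_away_from_boundary(self):
        content = np.full((16, 16, 3), 0.4)
        style = np.full((16, 16, 3), 0.8)
        blend = np.full((16, 16, 3), 0.6)
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        interior = np.zeros_like(mask)
        interior[6:10, 6:10] = True  # inside the mask, away from its edge ring
        assert gen.poisson_gradient_loss(blend, content, style, mask, region=interior) == 0.0

    def test_matches_explicit_stencil(self):
        rng = np.random.default_rng(5)
        content = rng.uniform(0, 1, (7, 6, 3))
        style = rng.uniform(0, 1, (7, 6, 3))
        blend = rng.uniform(0, 1, (7, 6, 3))
        mask = rng.random((7, 6)) > 0.5
        mask[3, 3] = True
        comp = np.where(mask[..., None], content, style)

        def lap(img):
            h, w, _ = img.shape
            out = np.zeros_like(img)
            for i in range(h):
                for j in range(w):
                    up, dn = max(i - 1, 0), min(i + 1, h - 1)
                    lf, rt = max(j - 1, 0), min(j + 1, w - 1)
                    out[i, j] = (
                        img[up, j] + img[dn, j] + img[i, lf] + img[i, rt] - 4 * img[i, j]
                    )
            return out

        expected = np.mean((lap(blend) - lap(comp))[mask] ** 2)
        got = gen.poisson_gradient_loss(blend, content, style, mask)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_empty_mask_rejected(self):
        z = np.zeros((4, 4, 3))
        with pytest.raises(ValueError):
            gen.poisson_gradient_loss(z, z, z, np.zeros((4, 4), bool))

    def test_laplacian_adjoint_exact(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((9, 7))
        b = rng.standard_normal((9, 7))
        lhs = np.sum(gen.laplacian(a) * b)
        rhs = np.sum(a * gen.laplacian_adjoint(b))
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestStyleTransfer:
    def test_identity_configuration(self, extractor, lesion_pair):
        content, _, _ = lesion_pair
        cfg = gen.STConfig(iterations=1, init="content", seed=0)
        res = gen.synthesize_st(content, content, cfg, extractor)
        assert res.trace["total"].iloc[0] == 0.0
        assert np.allclose(res.output, content)

    def test_loss_reduction_and_trace(self, extractor, lesion_pair):
        content, _, style = lesion_pair
        cfg = gen.STConfig(iterations=50, seed=0)
        res = gen.synthesize_st(content, style, cfg, extractor)
        assert res.trace["total"].min() < 0.5 * res.trace["total"].iloc[0]
        assert set(res.trace.columns) >= {"iteration", "content", "style", "total"}
        assert res.output.min() >= 0.0 and res.output.max() <= 1.0
        assert res.trace["total"].iloc[res.best_iteration] == res.trace["total"].min()

    def test_bit_identical_reruns(self, extractor, lesion_pair):
        content, _, style = lesion_pair
        cfg = gen.STConfig(iterations=20, seed=0)
        a = gen.synthesize_st(content, style, cfg, extractor)
        b = gen.synthesize_st(content, style, cfg, extractor)
        assert np.array_equal(a.output, b.output)
        pd.testing.assert_frame_equal(a.trace, b.trace)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            gen.STConfig(alpha=0.0, beta=0.0)
        with pytest.raises(ValueError):
            gen.STConfig(iterations=0)


class TestDeepBlending:
    def test_empty_mask_rejected(self, extractor, lesion_pair):
        content, _, style = lesion_pair
        cfg = gen.DBConfig(iterations=1)
        with pytest.raises(ValueError):
            gen.synthesize_db(content, np.zeros(content.shape[:2], bool), style, cfg, extractor)

    def test_all_losses_zero_when_content_equals_style(self, extractor, lesion_pair):
        content, mask, _ = lesion_pair
        cfg = gen.DBConfig(iterations=1, rounds=1, seed=0)
        res = gen.synthesize_db(content, mask, content, cfg, extractor)
        first = res.trace.iloc[0]
        assert first["gradient"] == 0.0
        assert first["content"] == 0.0
        assert first["style"] == 0.0

    def test_two_rounds_no_worse_than_one(self, extractor, lesion_pair):
        content, mask, style = lesion_pair
        one = gen.synthesize_db(
            content, mask, style, gen.DBConfig(iterations=25, rounds=1, seed=0, dilation_radius=3), extractor
        )
        two = gen.synthesize_db(
            content, mask, style, gen.DBConfig(iterations=25, rounds=2, seed=0, dilation_radius=3), extractor
        )
        assert two.trace["total"].min() <= one.trace["total"].min() + 1e-12

    def test_locality_outside_dilated_mask(self, extractor, lesion_pair):
        from scipy import ndimage

        content, mask, style = lesion_pair
        cfg = gen.DBConfig(iterations=15, rounds=1, seed=0, dilation_radius=3)
        res = gen.synthesize_db(content, mask, style, cfg, extractor)
        region = ndimage.binary_dilation(mask, gen._disk(3))
        assert np.max(np.abs(res.output[~region] - style[~region])) <= 1e-6


class TestBatchGeneration:
    def _manifest(self, tones):
        return fixtures.make_synthetic_manifest(
            len(tones) // 2 + len(tones) % 2, len(tones) // 2, tone_categories=tones
        )

    def test_eligible_times_styles_accounting(self):
        # 920 light/intermediate content images x 3 styles -> 2760 rows
        tones = ["light"] * 690 + ["intermediate"] * 230 + ["tan"] * 110 + ["brown"] * 62 + ["dark"] * 2
        man = self._manifest(tones)
        plan = gen.plan_generated_manifest(man, {"tan": None, "brown": None, "dark": None})
        assert len(plan) == 2760

    def test_zero_eligible(self):
        man = self._manifest(["dark", "brown"])
        plan = gen.plan_generated_manifest(man, {"tan": None})
        assert len(plan) == 0

    def test_two_eligible_one_style(self):
        man = self._manifest(["light", "light", "dark"])
        plan = gen.plan_generated_manifest(man, {"tan": None})
        assert len(plan) == 2

    def test_missing_tones_rejected(self):
        man = fixtures.make_synthetic_manifest(1, 1)
        with pytest.raises(ValueError):
            gen.plan_generated_manifest(man, {"tan": None})

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        n_eligible=st.integers(0, 30),
        n_other=st.integers(0, 30),
        n_styles=st.integers(1, 4),
    )
    def test_row_count_property(self, n_eligible, n_other, n_styles):
        if n_eligible + n_other == 0:
            return
        tones = ["light"] * n_eligible + ["dark"] * n_other
        man = self._manifest(tones)
        styles = {f"s{i}": None for i in range(n_styles)}
        assert len(gen.plan_generated_manifest(man, styles)) == n_eligible * n_styles

    def test_batch_generate_runs_synthesis(self, extractor, lesion_pair):
        content, _, style = lesion_pair
        man = fixtures.make_synthetic_manifest(1, 1, tone_categories=["light", "light"])
        cfg = gen.STConfig(iterations=3, seed=0)
        plan, images = gen.batch_generate(
            man, {"dark": style}, "st", cfg, extractor, image_loader=lambda i: content
        )
        assert len(plan) == 2 and len(images) == 2
        for img in images.values():
            assert img.shape == content.shape
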
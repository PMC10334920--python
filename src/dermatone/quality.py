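"""Quantitative image quality: SSIM (disease presentation) and BRISQUE
(loss of realism).

SSIM compares a generated image to its content image with the standard
luminance/contrast/structure product over a Gaussian 11x11, sigma 1.5
sliding window.

BRISQUE is a no-reference natural-scene-statistics score. Luminance is
locally mean-subtracted and contrast-normalized (MSCN coefficients); for a
pristine natural image these are near-Gaussian, and distortion shows up as a
departure from Gaussianity. Per scale (2 scales, dyadic down-sampling) we fit
a generalized Gaussian distribution (GGD) to the MSCN coefficients and an
asymmetric GGD to four orientation pairwise products, giving the standard
36-feature vector. Scoring is pluggable: a Mahalanobis distance to a
pristine reference corpus (default, train-free) or user-supplied linear
regression coefficients. Raw scores are min-max normalized over the
evaluated set for reporting; higher = less real.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from skimage.metrics import structural_similarity as _skimage_ssim

_LUMA = np.array([0.299, 0.587, 0.114])  # ITU-R BT.601


@dataclass(frozen=True)
class SSIMParams:
    K1: float = 0.01
    K2: float = 0.03
    data_range: float = 1.0
    win_size: int = 11
    sigma: float = 1.5

    def __post_init__(self):
        if self.K1 <= 0 or self.K2 <= 0:
            raise ValueError("K1, K2 must be > 0")


def luminance(image: np.ndarray) -> np.ndarray:
    """BT.601 luma of an RGB image (grayscale passes through)."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    return image @ _LUMA


def ssim(reference: np.ndarray, test: np.ndarray, params: SSIMParams = SSIMParams()) -> float:
    """Mean local structural similarity between two equally sized images."""
    ref = luminance(reference)
    tst = luminance(test)
    if ref.shape != tst.shape:
        raise ValueError(f"size mismatch: {ref.shape} vs {tst.shape}")
    return float(
        _skimage_ssim(
            ref,
            tst,
            win_size=params.win_size,
            gaussian_weights=True,
            sigma=params.sigma,
            use_sample_covariance=False,
            K1=params.K1,
            K2=params.K2,
            data_range=params.data_range,
        )
    )


# ---------------------------------------------------------------------------
# MSCN coefficients
# ---------------------------------------------------------------------------


def _gaussian_kernel(size: int = 7, sigma: float = 7.0 / 6.0) -> np.ndarray:
    half = size // 2
    x = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(x**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def _filter2(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    from scipy.ndimage import correlate

    return correlate(image, kernel, mode="nearest")


def mscn(image_luminance: np.ndarray, C: float = 1.0) -> np.ndarray:
    """Mean-subtracted contrast-normalized coefficients.

    (I - mu) / (sigma + C) with a 7x7 Gaussian local window on the 0-255
    luminance scale (C = 1 on that convention).
    """
    I = np.asarray(image_luminance, dtype=float)
    k = _gaussian_kernel()
    mu = _filter2(I, k)
    var = _filter2(I * I, k) - mu * mu
    sigma = np.sqrt(np.maximum(var, 0.0))
    return (I - mu) / (sigma + C)


# ---------------------------------------------------------------------------
# GGD / AGGD moment-matching fits
# ---------------------------------------------------------------------------

_GAMMA_GRID = np.arange(0.2, 10.0, 0.001)
_RHO_GRID = (special.gamma(2.0 / _GAMMA_GRID) ** 2) / (
    special.gamma(1.0 / _GAMMA_GRID) * special.gamma(3.0 / _GAMMA_GRID)
)


def fit_ggd(samples: np.ndarray) -> tuple[float, float]:
    """Fit a zero-mean generalized Gaussian by moment matching.

    Inverts rho = (E|x|)^2 / E[x^2] = Gamma(2/g)^2 / (Gamma(1/g) Gamma(3/g))
    over a dense shape grid. Returns (shape gamma, variance sigma^2).
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    e_abs = np.mean(np.abs(x))
    e_sq = np.mean(x * x)
    if e_sq == 0.0:
        raise ValueError("degenerate (all-zero) samples")
    rho = (e_abs**2) / e_sq
    gamma_hat = _GAMMA_GRID[np.argmin(np.abs(_RHO_GRID - rho))]
    return float(gamma_hat), float(e_sq)


def fit_aggd(samples: np.ndarray) -> tuple[float, float, float, float]:
    """Fit an asymmetric generalized Gaussian by moment matching.

    Returns (shape alpha, mean eta, left variance, right variance) where the
    left/right variances are the second moments of the negative/positive
    halves and eta is the distribution mean implied by the fit.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    left = x[x < 0]
    right = x[x > 0]
    sigma_l_sq = float(np.mean(left**2)) if left.size else 0.0
    sigma_r_sq = float(np.mean(right**2)) if right.size else 0.0
    sigma_l = np.sqrt(sigma_l_sq)
    sigma_r = np.sqrt(sigma_r_sq)

    gamma_hat = sigma_l / sigma_r if sigma_r > 0 else np.inf
    e_abs = np.mean(np.abs(x))
    e_sq = np.mean(x * x)
    if e_sq == 0.0:
        raise ValueError("degenerate (all-zero) samples")
    r_hat = (e_abs**2) / e_sq
    if np.isfinite(gamma_hat) and gamma_hat > 0:
        R_hat = r_hat * (gamma_hat**3 + 1) * (gamma_hat + 1) / (gamma_hat**2 + 1) ** 2
    else:
        R_hat = r_hat
    alpha = float(_GAMMA_GRID[np.argmin(np.abs(_RHO_GRID - R_hat))])

    g1 = special.gamma(1.0 / alpha)
    g2 = special.gamma(2.0 / alpha)
    g3 = special.gamma(3.0 / alpha)
    const = np.sqrt(g1 / g3)
    eta = (sigma_r - sigma_l) * const * (g2 / g1)
    return alpha, float(eta), sigma_l_sq, sigma_r_sq


# ---------------------------------------------------------------------------
# BRISQUE features and scorers
# ---------------------------------------------------------------------------

_SHIFTS = {  # orientation pairwise products of MSCN neighbors
    "horizontal": (0, 1),
    "vertical": (1, 0),
    "main_diagonal": (1, 1),
    "secondary_diagonal": (1, -1),
}


def _scale_features(lum: np.ndarray) -> list[float]:
    coeff = mscn(lum)
    feats = list(fit_ggd(coeff))
    for di, dj in _SHIFTS.values():
        h, w = coeff.shape
        a = coeff[max(di, 0) : h + min(di, 0), max(dj, 0) : w + min(dj, 0)]
        b = coeff[max(-di, 0) : h + min(-di, 0), max(-dj, 0) : w + min(-dj, 0)]
        feats.extend(fit_aggd(a * b))
    return feats


def _downsample2(lum: np.ndarray) -> np.ndarray:
    h2, w2 = lum.shape[0] // 2, lum.shape[1] // 2
    return lum[: 2 * h2, : 2 * w2].reshape(h2, 2, w2, 2).mean(axis=(1, 3))


def brisque_features(image: np.ndarray) -> np.ndarray:
    """36-vector of natural-scene statistics (18 per scale, 2 scales)."""
    lum = luminance(image) * 255.0
    if min(lum.shape) < 16:
        raise ValueError("image must be at least 16x16")
    feats = _scale_features(lum)
    feats += _scale_features(_downsample2(lum))
    return np.asarray(feats, dtype=float)


class BrisqueDistanceScorer:
    """Train-free realism scorer: Mahalanobis distance to a pristine corpus.

    sklearn-style estimator: ``fit`` on a set of undistorted reference images
    (or precomputed 36-feature vectors), then ``score_features`` /
    ``score_image`` return a distance that grows with distortion. Fitted
    attributes carry a trailing underscore.
    """

    def __init__(self, regularization: float = 1e-6):
        self.regularization = regularization

    def get_params(self, deep: bool = True) -> dict:
        return {"regularization": self.regularization}

    def set_params(self, **params) -> "BrisqueDistanceScorer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, references) -> "BrisqueDistanceScorer":
        feats = np.asarray(
            [r if np.ndim(r) == 1 else brisque_features(r) for r in references], dtype=float
        )
        if feats.ndim != 2 or feats.shape[0] < 2:
            raise ValueError("need at least 2 reference images")
        self.mean_ = feats.mean(axis=0)
        centered = feats - self.mean_
        cov = centered.T @ centered / (feats.shape[0] - 1)
        cov += self.regularization * np.eye(cov.shape[0]) * max(np.trace(cov), 1.0)
        self.precision_ = np.linalg.pinv(cov)
        return self

    def score_features(self, features: np.ndarray) -> float:
        if not hasattr(self, "mean_"):
            raise RuntimeError("scorer is not fitted")
        d = np.asarray(features, dtype=float) - self.mean_
        return float(np.sqrt(max(d @ self.precision_ @ d, 0.0)))

    def score_image(self, image: np.ndarray) -> float:
        return self.score_features(brisque_features(image))


class LinearBrisqueScorer:
    """Scorer from user-supplied trained regression coefficients (w, b)."""

    def __init__(self, weights: np.ndarray, intercept: float = 0.0):
        self.weights = np.asarray(weights, dtype=float)
        self.intercept = float(intercept)
        if self.weights.shape != (36,):
            raise ValueError("expected 36 regression weights")

    def score_features(self, features: np.ndarray) -> float:
        return float(self.weights @ np.asarray(features, dtype=float) + self.intercept)

    def score_image(self, image: np.ndarray) -> float:
        return self.score_features(brisque_features(image))


def brisque_score(features: np.ndarray, scorer) -> float:
    """Raw realism-loss score of a 36-feature vector (higher = less real)."""
    if scorer is None:
        raise ValueError("a scorer is required (distance-based or trained coefficients)")
    return scorer.score_features(features)


def normalize_scores(raw_scores) -> np.ndarray:
    """Min-max normalize raw scores over the evaluated set to [0, 1].

    A constant set maps to all zeros by convention.
    """
    s = np.asarray(list(raw_scores), dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 scores to normalize")
    lo, hi = s.min(), s.max()
    if hi == lo:
        return np.zeros_like(s)
    return (s - lo) / (hi - lo)


def score_summary(scores) -> dict:
    """Mean and normal-approximation 95% CI over an image set."""
    s = np.asarray(list(scores), dtype=float)
    mean = float(s.mean())
    if s.size > 1:
        half = 1.959963984540054 * float(s.std(ddof=1)) / np.sqrt(s.size)
    else:
        half = 0.0
    return {"mean": mean, "ci_low": mean - half, "ci_high": mean + half, "n": int(s.size)}
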
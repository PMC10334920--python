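"""Darker-skin lesion image synthesis: style transfer and deep blending.

Style transfer (ST) optimizes a generated image so that its convolutional
features match a content image (the lesion) while its Gram-matrix feature
statistics match a style image (the target skin color), starting from seeded
noise and minimizing ``alpha * content + beta * style`` by Adam.

Deep blending (DB) composites the lesion into the style image through a
binary mask and optimizes only the blending region under three losses: a
Poisson-based gradient loss (Laplacian of the blend vs. Laplacian of the
composite), the content loss and the style loss. Two rounds are performed:
round 1 blends the content object into the style image; round 2 re-blends
the round-1 output against the style image.

Everything is deterministic under (seed, config, extractor weights).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .features import FeatureExtractor, FeatureSet


class GenerationError(RuntimeError):
    """Raised when optimization produces non-finite losses; carries the trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def gram_matrix(features: np.ndarray) -> np.ndarray:
    """Channel inner-product matrix G[i, j] = sum_p F_i(p) F_j(p) / (C N).

    The (C N) normalization makes the style loss scale-free across layers of
    different size. Symmetric and positive semidefinite by construction.
    """
    F = np.asarray(features, dtype=float)
    if F.ndim != 3 or F.size == 0:
        raise ValueError("expected a non-empty (C, H, W) feature tensor")
    c = F.shape[0]
    n = F.shape[1] * F.shape[2]
    flat = F.reshape(c, n)
    return flat @ flat.T / (c * n)


def _as_weights(layers, weights):
    if weights is None:
        return {l: 1.0 for l in layers}
    if set(weights) != set(layers):
        raise ValueError("per-layer weights must cover exactly the tap layers")
    return dict(weights)


def content_loss(
    target: FeatureSet, generated: FeatureSet, weights: dict[str, float] | None = None
) -> float:
    """(1/2) sum_l w_l || F_generated^l - F_content^l ||^2."""
    if set(target.layers) != set(generated.layers):
        raise ValueError("feature sets tap different layers")
    w = _as_weights(target.layers, weights)
    total = 0.0
    for l in target.layers:
        a, b = generated[l], target[l]
        if a.shape != b.shape:
            raise ValueError(f"shape mismatch at layer {l}: {a.shape} vs {b.shape}")
        total += 0.5 * w[l] * float(np.sum((a - b) ** 2))
    return total


def style_loss(
    target: FeatureSet, generated: FeatureSet, weights: dict[str, float] | None = None
) -> float:
    """sum_l w_l || G(F_generated^l) - G(F_style^l) ||^2 (normalized Grams)."""
    if set(target.layers) != set(generated.layers):
        raise ValueError("feature sets tap different layers")
    w = _as_weights(target.layers, weights)
    total = 0.0
    for l in target.layers:
        gg = gram_matrix(generated[l])
        gs = gram_matrix(target[l])
        if gg.shape != gs.shape:
            raise ValueError(f"Gram shape mismatch at layer {l}")
        total += w[l] * float(np.sum((gg - gs) ** 2))
    return total


def st_total_loss(content_l: float, style_l: float, alpha: float, beta: float) -> float:
    """Weighted total: alpha * content + beta * style."""
    return alpha * content_l + beta * style_l


def _content_grads(target, gen_acts, weights, scale):
    return {l: scale * w * (gen_acts[l] - target[l]) for l, w in weights.items()}


def _style_grads(target_grams, gen_acts, weights, scale):
    grads = {}
    for l, w in weights.items():
        F = gen_acts[l]
        c = F.shape[0]
        n = F.shape[1] * F.shape[2]
        flat = F.reshape(c, n)
        dG = flat @ flat.T / (c * n) - target_grams[l]
        grads[l] = scale * w * (4.0 / (c * n)) * (dG @ flat).reshape(F.shape)
    return grads


# ---------------------------------------------------------------------------
# Poisson gradient loss (4-neighbor Laplacian, replicate boundary)
# ---------------------------------------------------------------------------

_STENCIL = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


def laplacian(field: np.ndarray) -> np.ndarray:
    """4-neighbor Laplacian with replicate (edge) boundary, per channel."""
    f = np.asarray(field, dtype=float)
    single = f.ndim == 2
    if single:
        f = f[..., None]
    out = np.empty_like(f)
    for ch in range(f.shape[-1]):
        p = np.pad(f[..., ch], 1, mode="edge")
        out[..., ch] = (
            p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * p[1:-1, 1:-1]
        )
    return out[..., 0] if single else out


def laplacian_adjoint(grad: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`laplacian` (replicate padding folded back)."""
    g = np.asarray(grad, dtype=float)
    single = g.ndim == 2
    if single:
        g = g[..., None]
    out = np.empty_like(g)
    for ch in range(g.shape[-1]):
        z = np.pad(g[..., ch], 2)  # zero padding
        # full correlation with the (symmetric) stencil -> (H+2, W+2)
        op = (
            z[:-2, 1:-1] + z[2:, 1:-1] + z[1:-1, :-2] + z[1:-1, 2:] - 4.0 * z[1:-1, 1:-1]
        )
        core = op[1:-1, 1:-1].copy()
        core[0, :] += op[0, 1:-1]
        core[-1, :] += op[-1, 1:-1]
        core[:, 0] += op[1:-1, 0]
        core[:, -1] += op[1:-1, -1]
        core[0, 0] += op[0, 0]
        core[0, -1] += op[0, -1]
        core[-1, 0] += op[-1, 0]
        core[-1, -1] += op[-1, -1]
        out[..., ch] = core
    return out[..., 0] if single else out


def composite_image(content: np.ndarray, style: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Hard mask composite: content inside the mask, style outside."""
    m = np.asarray(mask, dtype=bool)
    if m.shape != content.shape[:2] or content.shape != style.shape:
        raise ValueError("content, style and mask shapes must align")
    return np.where(m[..., None], content, style)


def poisson_gradient_loss(
    blend: np.ndarray,
    content: np.ndarray,
    style: np.ndarray,
    mask: np.ndarray,
    region: np.ndarray | None = None,
) -> float:
    """Mean squared Laplacian mismatch between blend and mask composite.

    Evaluated over the blending ``region`` (default: the mask itself) across
    all channels; penalizes gradient-field changes so the pasted object
    transitions seamlessly into the style image.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    region = m if region is None else np.asarray(region, dtype=bool)
    comp = composite_image(content, style, m)
    resid = laplacian(blend) - laplacian(comp)
    return float(np.mean(resid[region] ** 2))


def _poisson_grad(blend, lap_target, region):
    """Gradient of the region-mean squared Laplacian residual w.r.t. blend."""
    resid = laplacian(blend) - lap_target
    n = int(region.sum()) * blend.shape[-1]
    masked = np.where(region[..., None], resid, 0.0) * (2.0 / n)
    return laplacian_adjoint(masked)


# ---------------------------------------------------------------------------
# Configs and results
# ---------------------------------------------------------------------------


@dataclass
class STConfig:
    """Style-transfer settings.

    ``content_layers`` / ``style_layers`` default to the Gatys taps
    (content conv4_2; style conv1_1..conv5_1) when the extractor exposes
    them, otherwise to the deepest conv (content) and all convs (style).
    """

    content_layers: dict[str, float] | None = None
    style_layers: dict[str, float] | None = None
    alpha: float = 1.0
    beta: float = 1000.0
    iterations: int = 500
    init: str = "noise"  # or "content"
    seed: int = 0
    learning_rate: float = 0.02

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or (self.alpha == 0 and self.beta == 0):
            raise ValueError("alpha, beta must be >= 0 and not both 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.init not in ("noise", "content"):
            raise ValueError("init must be 'noise' or 'content'")


@dataclass
class DBConfig:
    """Deep-blending settings (two rounds by default, 5 px mask dilation)."""

    gradient_weight: float = 1.0
    content_weight: float = 1.0
    style_weight: float = 1000.0
    rounds: int = 2
    iterations: int = 200
    seed: int = 0
    learning_rate: float = 0.02
    dilation_radius: int = 5
    content_layers: dict[str, float] | None = None
    style_layers: dict[str, float] | None = None

    def __post_init__(self):
        if min(self.gradient_weight, self.content_weight, self.style_weight) < 0:
            raise ValueError("loss weights must be >= 0")
        if self.rounds not in (1, 2):
            raise ValueError("rounds must be 1 or 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class GenerationResult:
    """Synthesis output: best-loss image, per-iteration trace, config."""

    output: np.ndarray
    trace: pd.DataFrame
    best_iteration: int
    config: dict


def _default_taps(extractor: FeatureExtractor, content_layers, style_layers):
    convs = [d["name"] for d in extractor.descriptor if d["type"] == "conv"]
    if content_layers is None:
        content_layers = {"conv4_2": 1.0} if "conv4_2" in convs else {convs[-1]: 1.0}
    gatys = [f"conv{i}_1" for i in range(1, 6)]
    if style_layers is None:
        taps = gatys if all(g in convs for g in gatys) else convs
        style_layers = {l: 1.0 / len(taps) for l in taps}
    return dict(content_layers), dict(style_layers)


class _Adam:
    def __init__(self, shape, lr):
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0
        self.lr = lr

    def step(self, x, g, beta1=0.9, beta2=0.999, eps=1e-8):
        self.t += 1
        self.m = beta1 * self.m + (1 - beta1) * g
        self.v = beta2 * self.v + (1 - beta2) * g * g
        mh = self.m / (1 - beta1**self.t)
        vh = self.v / (1 - beta2**self.t)
        return x - self.lr * mh / (np.sqrt(vh) + eps)


# ---------------------------------------------------------------------------
# Synthesis
# ---------------------------------------------------------------------------


def synthesize_st(
    content: np.ndarray,
    style: np.ndarray,
    cfg: STConfig,
    extractor: FeatureExtractor,
) -> GenerationResult:
    """Iterative style transfer; returns the best-loss iterate.

    The generated image starts from seeded uniform noise (or the content
    image) and follows Adam on ``alpha * content_loss + beta * style_loss``.
    """
    content = np.asarray(content, dtype=float)
    style = np.asarray(style, dtype=float)
    if content.shape != style.shape:
        raise ValueError("content and style must share the extractor input size")
    c_layers, s_layers = _default_taps(extractor, cfg.content_layers, cfg.style_layers)
    all_layers = sorted(set(c_layers) | set(s_layers), key=extractor.layer_names.index)
    deepest = all_layers[-1]

    f_content = extractor.extract_features(content, list(c_layers))
    f_style = extractor.extract_features(style, list(s_layers))
    target_grams = {l: gram_matrix(f_style[l]) for l in s_layers}

    if cfg.init == "noise":
        rng = np.random.default_rng(cfg.seed)
        x = rng.uniform(0.0, 1.0, size=content.shape)
    else:
        x = content.copy()

    adam = _Adam(x.shape, cfg.learning_rate)
    trace, best_x, best_loss, best_it = [], x.copy(), np.inf, 0

    def _evaluate(img, it):
        nonlocal best_x, best_loss, best_it
        acts, caches = extractor.forward_all(img, upto=deepest)
        gen_c = FeatureSet({l: acts[l] for l in c_layers})
        gen_s = FeatureSet({l: acts[l] for l in s_layers})
        cl = content_loss(f_content, gen_c, c_layers)
        sl = style_loss(f_style, gen_s, s_layers)
        total = st_total_loss(cl, sl, cfg.alpha, cfg.beta)
        trace.append({"iteration": it, "content": cl, "style": sl, "total": total})
        if not np.isfinite(total):
            raise GenerationError(
                f"non-finite loss at iteration {it}", trace=pd.DataFrame(trace)
            )
        if total < best_loss:
            best_loss, best_x, best_it = total, img.copy(), it
        return acts, caches

    for it in range(cfg.iterations):
        acts, caches = _evaluate(x, it)
        grads: dict[str, np.ndarray] = {}
        for l, g in _content_grads(f_content, acts, c_layers, cfg.alpha).items():
            grads[l] = grads.get(l, 0.0) + g
        for l, g in _style_grads(target_grams, acts, s_layers, cfg.beta).items():
            grads[l] = grads.get(l, 0.0) + g
        img_grad = extractor.backward(caches, grads)
        x = adam.step(x, img_grad)
    _evaluate(x, cfg.iterations)

    return GenerationResult(
        output=np.clip(best_x, 0.0, 1.0),
        trace=pd.DataFrame(trace),
        best_iteration=best_it,
        config={**asdict(cfg), "method": "st", "content_layers": c_layers, "style_layers": s_layers},
    )


def synthesize_db(
    content: np.ndarray,
    mask: np.ndarray,
    style: np.ndarray,
    cfg: DBConfig,
    extractor: FeatureExtractor,
) -> GenerationResult:
    """Two-round deep blending of a masked lesion into a style image.

    Round 1 initializes the blend to the hard composite and optimizes only
    the dilated blending region under gradient + content + style losses;
    round 2 repeats the procedure with the round-1 output as the content
    object. Pixels outside the dilated mask stay pinned to the style image.
    """
    content = np.asarray(content, dtype=float)
    style = np.asarray(style, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    if content.shape != style.shape or m.shape != content.shape[:2]:
        raise ValueError("content, style and mask shapes must align")

    structure = _disk(cfg.dilation_radius)
    region = ndimage.binary_dilation(m, structure=structure)
    c_layers, s_layers = _default_taps(extractor, cfg.content_layers, cfg.style_layers)
    all_layers = sorted(set(c_layers) | set(s_layers), key=extractor.layer_names.index)
    deepest = all_layers[-1]

    f_style = extractor.extract_features(style, list(s_layers))
    target_grams = {l: gram_matrix(f_style[l]) for l in s_layers}

    x = composite_image(content, style, m)
    trace_all: list[dict] = []
    best_x, best_loss, best_it = x.copy(), np.inf, 0

    for rnd in range(1, cfg.rounds + 1):
        if rnd > 1:
            x = best_x.copy()
        comp = composite_image(x if rnd > 1 else content, style, m)
        f_content = extractor.extract_features(comp, list(c_layers))
        lap_target = laplacian(comp)
        adam = _Adam(x.shape, cfg.learning_rate)

        for it in range(cfg.iterations + 1):
            acts, caches = extractor.forward_all(x, upto=deepest)
            gen_c = FeatureSet({l: acts[l] for l in c_layers})
            gen_s = FeatureSet({l: acts[l] for l in s_layers})
            gl = float(
                np.mean((laplacian(x) - lap_target)[region] ** 2)
            )
            cl = content_loss(f_content, gen_c, c_layers)
            sl = style_loss(f_style, gen_s, s_layers)
            total = cfg.gradient_weight * gl + cfg.content_weight * cl + cfg.style_weight * sl
            trace_all.append(
                {"round": rnd, "iteration": it, "gradient": gl, "content": cl,
                 "style": sl, "total": total}
            )
            if not np.isfinite(total):
                raise GenerationError(
                    f"non-finite loss in round {rnd}, iteration {it}",
                    trace=pd.DataFrame(trace_all),
                )
            if total < best_loss or (rnd > 1 and it == 0 and total <= best_loss):
                best_loss, best_x, best_it = total, x.copy(), len(trace_all) - 1
            if it == cfg.iterations:
                break
            grads: dict[str, np.ndarray] = {}
            for l, g in _content_grads(f_content, acts, c_layers, cfg.content_weight).items():
                grads[l] = grads.get(l, 0.0) + g
            for l, g in _style_grads(target_grams, acts, s_layers, cfg.style_weight).items():
                grads[l] = grads.get(l, 0.0) + g
            img_grad = extractor.backward(caches, grads)
            img_grad += cfg.gradient_weight * _poisson_grad(x, lap_target, region)
            img_grad[~region] = 0.0
            x = adam.step(x, img_grad)
            x[~region] = style[~region]

    out = np.clip(best_x, 0.0, 1.0)
    out[~region] = style[~region]
    return GenerationResult(
        output=out,
        trace=pd.DataFrame(trace_all),
        best_iteration=best_it,
        config={**asdict(cfg), "method": "db", "content_layers": c_layers, "style_layers": s_layers},
    )


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= r**2


# ---------------------------------------------------------------------------
# Batch generation
# ---------------------------------------------------------------------------

ELIGIBLE_TONES = ("light", "intermediate")


def plan_generated_manifest(manifest, styles: dict) -> pd.DataFrame:
    """Accounting for batch generation: one output row per eligible content
    image and style, without synthesizing anything.

    Only images categorized light or intermediate are eligible content; the
    returned frame has ``eligible_count * len(styles)`` rows.
    """
    df = manifest.frame
    if df["tone_category"].isna().any():
        raise ValueError("every manifest image needs a tone_category before generation")
    eligible = df[df["tone_category"].isin(ELIGIBLE_TONES)]
    rows = []
    for _, row in eligible.iterrows():
        for style_name in styles:
            gen_id = f"{row.image_id}__{style_name}"
            rows.append(
                {
                    "image_id": gen_id,
                    "path": f"generated/{gen_id}.png",
                    "class_label": row.class_label,
                    "disease": row.disease,
                    "dataset_tag": "generated",
                    "tone_category": style_name,
                    "content_id": row.image_id,
                    "style": style_name,
                }
            )
    cols = ["image_id", "path", "class_label", "disease", "dataset_tag",
            "tone_category", "content_id", "style"]
    return pd.DataFrame(rows, columns=cols)


def batch_generate(
    manifest,
    styles: dict[str, np.ndarray],
    method: str,
    cfg,
    extractor: FeatureExtractor,
    image_loader,
    mask_loader=None,
    out_dir=None,
    writer=None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Synthesize one image per (eligible content image, style).

    ``image_loader(image_id) -> image`` supplies content images;
    ``mask_loader`` (required for DB) supplies lesion masks. Returns the
    generated manifest frame and a dict of generated images; images are also
    written via ``writer(image, path)`` under ``out_dir`` when given.
    """
    if method not in ("st", "db"):
        raise ValueError("method must be 'st' or 'db'")
    if method == "db" and mask_loader is None:
        raise ValueError("deep blending requires a mask_loader")
    plan = plan_generated_manifest(manifest, styles)
    images: dict[str, np.ndarray] = {}
    for _, row in plan.iterrows():
        content = image_loader(row.content_id)
        style_img = styles[row.style]
        if method == "st":
            res = synthesize_st(content, style_img, cfg, extractor)
        else:
            res = synthesize_db(content, mask_loader(row.content_id), style_img, cfg, extractor)
        images[row.image_id] = res.output
        if out_dir is not None and writer is not None:
            from pathlib import Path

            path = Path(out_dir) / f"{row.image_id}.png"
            path.parent.mkdir(parents=True, exist_ok=True)
            writer(res.output, path)
            res.trace.to_csv(Path(out_dir) / f"{row.image_id}_trace.csv", index=False)
    return plan, images
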
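"""Image/manifest I/O plus synthetic fixture generation.

The fixture generator produces textured "skin" backgrounds at a controllable
individual typology angle with an elliptical pigmented "lesion" (anisotropic
Gaussian pigment falloff, so structural metrics have non-trivial content),
together with the exact lesion mask. Rater-response simulators emulate the
visual-Turing-test and diagnosis survey tables, so the whole pipeline is
testable without any clinical images.

Images are floating intensities in [0, 1]; 8-bit PNG/JPEG I/O converts at
the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import color as _color
from skimage import io as _io

from . import skin_tone

MANIFEST_COLUMNS = ["image_id", "path", "class_label", "disease", "dataset_tag"]
OPTIONAL_COLUMNS = ["tone_category"]
CLASS_LABELS = {"malignant", "benign"}
DATASET_TAGS = {"A", "B", "fixture"}


class ManifestError(ValueError):
    """Schema or validation failure in a manifest."""


@dataclass
class Manifest:
    """Validated table of study images.

    Wraps a DataFrame with columns image_id, path, class_label, disease,
    dataset_tag and optionally tone_category. image_id is unique and
    class_label is one of {malignant, benign}.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ManifestError(f"manifest missing required columns: {missing}")
        if df["image_id"].duplicated().any():
            dups = df.loc[df["image_id"].duplicated(), "image_id"].tolist()
            raise ManifestError(f"duplicate image_id values: {dups[:5]}")
        if len(df):
            bad = set(df["class_label"].unique()) - CLASS_LABELS
            if bad or df["class_label"].isna().any():
                raise ManifestError(f"unknown class labels: {sorted(map(str, bad))}")
        if "tone_category" not in df.columns:
            df = df.assign(tone_category=pd.Series([None] * len(df), dtype=object))
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def class_counts(self) -> dict[str, int]:
        return self.frame["class_label"].value_counts().to_dict()

    def tag_counts(self) -> dict[str, int]:
        return self.frame["dataset_tag"].value_counts().to_dict()

    def subset(self, mask) -> "Manifest":
        return Manifest(self.frame.loc[mask].reset_index(drop=True))


def load_manifest(path, data_root=None, check_files: bool = True) -> Manifest:
    """Load and validate a CSV manifest.

    Paths are interpreted relative to ``data_root`` (default: the manifest's
    directory). Set ``check_files=False`` to skip existence checks, e.g. for
    bookkeeping-only manifests.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"image_id": str, "path": str})
    man = Manifest(df)
    if check_files:
        root = Path(data_root) if data_root is not None else path.parent
        for p in man.frame["path"]:
            if not (root / p).exists():
                raise ManifestError(f"referenced image missing: {root / p}")
    return man


def write_manifest(manifest: Manifest, path) -> None:
    cols = MANIFEST_COLUMNS + [
        c for c in OPTIONAL_COLUMNS if c in manifest.frame.columns
    ]
    manifest.frame[cols].to_csv(path, index=False)


def make_synthetic_manifest(
    n_malignant: int,
    n_benign: int,
    dataset_tag: str = "fixture",
    tone_categories=None,
    path_template: str = "images/{image_id}.png",
) -> Manifest:
    """Bookkeeping-only manifest with the requested class composition."""
    n = n_malignant + n_benign
    ids = [f"{dataset_tag}_{i:05d}" for i in range(n)]
    labels = ["malignant"] * n_malignant + ["benign"] * n_benign
    df = pd.DataFrame(
        {
            "image_id": ids,
            "path": [path_template.format(image_id=i) for i in ids],
            "class_label": labels,
            "disease": ["melanoma" if l == "malignant" else "halo_nevus" for l in labels],
            "dataset_tag": dataset_tag,
        }
    )
    if tone_categories is not None:
        df["tone_category"] = list(tone_categories)
    return Manifest(df)


# ---------------------------------------------------------------------------
# Synthetic image fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic lesion image.

    base_tone_target is the desired background ITA in degrees; the background
    color is solved in CIELAB (fixed skin-like chroma) so the noise-free
    background hits the target angle. The lesion is an ellipse with an
    anisotropic Gaussian pigment falloff.
    """

    width: int = 64
    height: int = 64
    base_tone_target: float = 48.0
    lesion_center: tuple[float, float] = (0.5, 0.5)  # fractional (row, col)
    lesion_axes: tuple[float, float] = (0.25, 0.18)  # fractional semi-axes
    lesion_rotation: float = 0.3  # radians
    pigment_rgb: tuple[float, float, float] = (0.28, 0.15, 0.10)
    texture_noise_sd: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        if not -90.0 <= self.base_tone_target <= 90.0:
            raise ValueError("base_tone_target must be in [-90, 90] degrees")
        if self.texture_noise_sd < 0:
            raise ValueError("texture_noise_sd must be >= 0")
        cy, cx = self.lesion_center
        ay, ax = self.lesion_axes
        if ay < 0 or ax < 0:
            raise ValueError("lesion axes must be >= 0")
        if not (0 <= cy - ay and cy + ay <= 1 and 0 <= cx - ax and cx + ax <= 1):
            raise ValueError("lesion ellipse must fit inside the canvas")


#: Fixed skin-like CIELAB chroma used to solve background colors.
_BG_B_STAR = 15.0
_BG_A_STAR = 10.0


def background_rgb_for_ita(ita_degrees: float) -> np.ndarray:
    """sRGB color whose CIELAB coordinates give the requested ITA.

    Solves L* = 50 + b* tan(ITA) at fixed (a*, b*) = (10, 15) and converts
    through the standard D65 pipeline; |ITA| near 90 deg is not attainable
    within L* in [0, 100].
    """
    if not -90.0 < ita_degrees < 90.0:
        raise ValueError("attainable ITA targets lie strictly inside (-90, 90)")
    L = 50.0 + _BG_B_STAR * math.tan(math.radians(ita_degrees))
    if not 1.0 <= L <= 99.0:
        raise ValueError(f"ITA target {ita_degrees} deg needs L*={L:.1f}, out of range")
    lab = np.array([[[L, _BG_A_STAR, _BG_B_STAR]]])
    rgb = _color.lab2rgb(lab)[0, 0]
    return np.clip(rgb, 0.0, 1.0)


def lesion_mask(spec: FixtureSpec) -> np.ndarray:
    """Exact boolean ellipse mask for a FixtureSpec's lesion."""
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = spec.lesion_center[0] * h, spec.lesion_center[1] * w
    ay, ax = spec.lesion_axes[0] * h, spec.lesion_axes[1] * w
    if ay == 0 or ax == 0:
        return np.zeros((h, w), dtype=bool)
    ct, st = math.cos(spec.lesion_rotation), math.sin(spec.lesion_rotation)
    dy, dx = yy - cy, xx - cx
    u = ct * dy + st * dx
    v = -st * dy + ct * dx
    return (u / ay) ** 2 + (v / ax) ** 2 <= 1.0


def generate_fixture_image(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one synthetic lesion image and its mask.

    Returns
    -------
    image : (H, W, 3) float array in [0, 1]
        Background at the target tone plus a pigmented lesion and seeded
        Gaussian texture noise. Deterministic per (spec, seed).
    mask : (H, W) boolean array
        The exact lesion ellipse.
    """
    h, w = spec.height, spec.width
    bg = background_rgb_for_ita(spec.base_tone_target)
    image = np.broadcast_to(bg, (h, w, 3)).copy()

    mask = lesion_mask(spec)
    if mask.any():
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = spec.lesion_center[0] * h, spec.lesion_center[1] * w
        ay, ax = spec.lesion_axes[0] * h, spec.lesion_axes[1] * w
        ct, st = math.cos(spec.lesion_rotation), math.sin(spec.lesion_rotation)
        dy, dx = yy - cy, xx - cx
        u = (ct * dy + st * dx) / max(ay, 1e-9)
        v = (-st * dy + ct * dx) / max(ax, 1e-9)
        # anisotropic Gaussian pigment falloff inside the ellipse
        falloff = np.exp(-0.5 * ((u / 0.55) ** 2 + (v / 0.45) ** 2))
        alpha = np.where(mask, falloff, 0.0)[..., None]
        pigment = np.asarray(spec.pigment_rgb, dtype=float)
        image = (1.0 - alpha) * image + alpha * pigment

    if spec.texture_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.texture_noise_sd, size=image.shape)
    return np.clip(image, 0.0, 1.0), mask


def read_image(path) -> np.ndarray:
    """Read a PNG/JPEG into a float RGB array in [0, 1]."""
    arr = _io.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    return np.clip(arr.astype(float), 0.0, 1.0)


def write_image(image: np.ndarray, path) -> None:
    """Write a float [0, 1] RGB array as an 8-bit image."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    _io.imsave(str(path), (arr * 255.0 + 0.5).astype(np.uint8), check_contrast=False)


# ---------------------------------------------------------------------------
# Simulated human-rater tables
# ---------------------------------------------------------------------------

EXPERIENCE_BANDS = (0, 1, 2, 3)
DISEASES = (
    "actinic_keratosis",
    "atypical_nevi",
    "basal_cell_carcinoma",
    "intraepidermal_carcinoma",
    "halo_nevus",
    "hemangioma",
    "melanoma",
    "squamous_cell_carcinoma",
    "seborrheic_keratosis",
    "vascular_malformation",
)


def simulate_rater_table(
    n_raters: int,
    n_real: int,
    n_generated: int,
    p_fpr: float,
    p_tpr: float,
    seed: int = 0,
    medical_fraction: float = 0.24,
) -> pd.DataFrame:
    """Simulate a visual-Turing-test response table.

    Each of ``n_raters`` raters votes real/generated on every image; a
    generated image is voted "real" with probability ``p_fpr``, a real image
    with probability ``p_tpr``. Long format, one row per (rater, image).
    """
    for name, p in (("p_fpr", p_fpr), ("p_tpr", p_tpr)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if min(n_raters, n_real, n_generated) < 0:
        raise ValueError("counts must be nonnegative")
    rng = np.random.default_rng(seed)
    truths = ["real"] * n_real + ["generated"] * n_generated
    image_ids = [f"img_{i:04d}" for i in range(len(truths))]

    rows = []
    for r in range(n_raters):
        medical = rng.random() < medical_fraction
        band = int(rng.integers(1, 4)) if medical else 0
        p_real_vote = np.where(np.array(truths) == "real", p_tpr, p_fpr)
        votes = np.where(rng.random(len(truths)) < p_real_vote, "real", "generated")
        for img, truth, vote in zip(image_ids, truths, votes):
            rows.append(
                {
                    "rater_id": f"rater_{r:03d}",
                    "background": "medical" if medical else "nonmedical",
                    "experience_band": band,
                    "image_id": img,
                    "truth": truth,
                    "vote": vote,
                }
            )
    cols = ["rater_id", "background", "experience_band", "image_id", "truth", "vote"]
    return pd.DataFrame(rows, columns=cols)


def simulate_diagnosis_table(
    n_raters: int = 8,
    n_real: int = 20,
    n_generated_per_color: int = 20,
    p_correct_real: float = 0.76,
    p_correct_generated: float = 0.75,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a dermatologist diagnosis survey (10-disease alphabet)."""
    rng = np.random.default_rng(seed)
    images = []
    for i in range(n_real):
        images.append((f"real_{i:03d}", "real", "real"))
    for color in ("tan", "brown", "dark"):
        for i in range(n_generated_per_color):
            images.append((f"gen_{color}_{i:03d}", "generated", color))
    rows = []
    for img_id, ttype, color in images:
        truth_disease = DISEASES[rng.integers(0, len(DISEASES))]
        p = p_correct_real if ttype == "real" else p_correct_generated
        for r in range(n_raters):
            if rng.random() < p:
                chosen = truth_disease
            else:
                others = [d for d in DISEASES if d != truth_disease]
                chosen = others[rng.integers(0, len(others))]
            rows.append(
                {
                    "rater_id": f"derm_{r:02d}",
                    "image_id": img_id,
                    "truth_disease": truth_disease,
                    "truth_type": ttype,
                    "skin_color": color,
                    "chosen_disease": chosen,
                }
            )
    return pd.DataFrame(rows)


def diagnosis_table_from_counts(
    correct_real: int,
    total_real: int,
    correct_generated: int,
    total_generated: int,
) -> pd.DataFrame:
    """Deterministic diagnosis table with exact correct/total marginals.

    Builds one row per (rater, image) response such that exactly
    ``correct_real`` of ``total_real`` real-image responses and
    ``correct_generated`` of ``total_generated`` generated-image responses
    name the true disease. Used to recompute published summary recalls from
    their printed counts.
    """
    if not (0 <= correct_real <= total_real and 0 <= correct_generated <= total_generated):
        raise ValueError("correct counts must not exceed totals")
    rows = []

    def _add(ttype, color, correct, total, prefix):
        for i in range(total):
            truth = DISEASES[i % len(DISEASES)]
            chosen = truth if i < correct else DISEASES[(i + 1) % len(DISEASES)]
            rows.append(
                {
                    "rater_id": f"derm_{i % 8:02d}",
                    "image_id": f"{prefix}_{i:04d}",
                    "truth_disease": truth,
                    "truth_type": ttype,
                    "skin_color": color,
                    "chosen_disease": chosen,
                }
            )

    _add("real", "real", correct_real, total_real, "real")
    _add("generated", "tan", correct_generated, total_generated, "gen")
    return pd.DataFrame(rows)
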
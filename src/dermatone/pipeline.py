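"""End-to-end pipeline wiring: tone -> generate -> quality -> stats -> classify.

`run_pipeline` executes every stage on synthetic fixture data inside a run
directory with canonical subdirectories and a provenance JSON (config hash,
package versions, seeds), so a full demonstration run needs no external
images and reproduces byte-identical manifests and metric files under the
same configuration.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, classifier, evalstats, fixtures, generation, quality, skin_tone
from .features import fixture_extractor


@dataclass
class RunConfig:
    """Configuration of a demo/pipeline run on synthetic fixtures."""

    out_root: str = "runs/demo"
    seed: int = 0
    image_size: int = 32
    n_train_images: int = 24
    n_test_images: int = 16
    st_iterations: int = 40
    epochs: int = 12
    n_raters: int = 12
    vtt_images: int = 15

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


#: Tone targets used for the two synthetic cohorts: the "training" cohort is
#: light/intermediate (like public atlases), the "test" cohort darker.
_TRAIN_TONES = (48.0, 35.0)
_TEST_TONES = (19.0, -10.0, -45.0)
_STYLE_TONES = {"tan": 19.0, "brown": -10.0, "dark": -45.0}


def _fixture_cohort(n, tones, size, seed, tag):
    """Synthesize a cohort of lesion fixtures; malignant lesions are larger
    and more irregular than benign ones."""
    rng = np.random.default_rng(seed)
    images, masks, rows = {}, {}, []
    for i in range(n):
        malignant = i % 2 == 0
        tone = tones[i % len(tones)] + float(rng.uniform(-3, 3))
        axes = (
            (float(rng.uniform(0.22, 0.3)), float(rng.uniform(0.12, 0.18)))
            if malignant
            else (float(rng.uniform(0.1, 0.15)), float(rng.uniform(0.08, 0.12)))
        )
        spec = fixtures.FixtureSpec(
            width=size,
            height=size,
            base_tone_target=tone,
            lesion_axes=axes,
            lesion_rotation=float(rng.uniform(0, np.pi)),
            pigment_rgb=(0.28, 0.15, 0.10) if malignant else (0.45, 0.3, 0.2),
            texture_noise_sd=0.015,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        img, mask = fixtures.generate_fixture_image(spec)
        image_id = f"{tag}_{i:04d}"
        images[image_id] = img
        masks[image_id] = mask
        rows.append(
            {
                "image_id": image_id,
                "path": f"images/{image_id}.png",
                "class_label": "malignant" if malignant else "benign",
                "disease": "melanoma" if malignant else "halo_nevus",
                "dataset_tag": tag,
            }
        )
    return fixtures.Manifest(pd.DataFrame(rows)), images, masks


def _assign_tones(manifest, images):
    cats = []
    for _, row in manifest.frame.iterrows():
        rec = skin_tone.tone_record(row.image_id, images[row.image_id])
        cats.append(rec.category)
    manifest.frame["tone_category"] = cats
    return manifest


def tone_shift_benchmark(
    seeds=range(10),
    n_train: int = 32,
    n_test: int = 24,
    image_size: int = 32,
    st_iterations: int = 60,
    epochs: int = 25,
    regimes=("a_none", "b_generated"),
) -> pd.DataFrame:
    """Tone-shifted fixture benchmark comparing augmentation regimes.

    Training fixtures carry light/intermediate tones, test fixtures tan to
    dark tones, with the lesion signal (shape/pigment vs. class) identical
    across cohorts — so any train/test gap is driven by skin tone alone.
    For each seed the requested regimes are trained on the fixture backbone
    and evaluated on the held-out dark cohort. Returns one row per
    (seed, regime) with the test AUC.
    """
    from .features import fixture_extractor as _fx

    rows = []
    for seed in seeds:
        train_man, train_imgs, _ = _fixture_cohort(
            n_train, _TRAIN_TONES, image_size, seed, "A"
        )
        test_man, test_imgs, _ = _fixture_cohort(
            n_test, _TEST_TONES, image_size, seed + 1000, "B"
        )
        _assign_tones(train_man, train_imgs)
        extractor = _fx(seed=seed)
        styles = {
            name: fixtures.generate_fixture_image(
                fixtures.FixtureSpec(
                    width=image_size, height=image_size, base_tone_target=tone,
                    lesion_axes=(0.0, 0.0), texture_noise_sd=0.01, seed=seed + 17,
                )
            )[0]
            for name, tone in _STYLE_TONES.items()
        }
        cfg = generation.STConfig(iterations=st_iterations, seed=seed)
        plan, gen_images = generation.batch_generate(
            train_man, styles, "st", cfg, extractor,
            image_loader=lambda i: train_imgs[i],
        )
        Xte = np.stack([test_imgs[i] for i in test_man.frame["image_id"]])
        yte = test_man.frame["class_label"].to_numpy()
        for regime in regimes:
            spec = classifier.RegimeSpec(regime, generated_manifest=plan)
            frame = classifier.build_regime(train_man, spec)
            X, y = classifier.materialize(
                frame, image_loader=lambda i: train_imgs[i],
                generated_loader=lambda i: gen_images[i], seed=seed,
            )
            model = classifier.LesionClassifier(
                epochs=epochs, seed=seed, extractor=_fx(seed=seed)
            ).fit(X, y)
            auc = classifier.evaluate(model, Xte, yte)["auc"]
            rows.append({"seed": seed, "regime": regime, "auc": auc})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage on fixtures; returns the run directory."""
    out = Path(config.out_root)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:  # pragma: no cover - filesystem dependent
        raise StageError("setup", e)
    rng_seed = config.seed
    provenance = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "package_version": __version__,
        "python": platform.python_version(),
        "seeds": {"global": rng_seed},
    }

    stage = "tone"
    try:
        train_man, train_imgs, train_masks = _fixture_cohort(
            config.n_train_images, _TRAIN_TONES, config.image_size, rng_seed, "A"
        )
        test_man, test_imgs, _ = _fixture_cohort(
            config.n_test_images, _TEST_TONES, config.image_size, rng_seed + 1, "B"
        )
        _assign_tones(train_man, train_imgs)
        _assign_tones(test_man, test_imgs)
        (out / "manifests").mkdir(exist_ok=True)
        fixtures.write_manifest(train_man, out / "manifests" / "set_a.csv")
        fixtures.write_manifest(test_man, out / "manifests" / "set_b.csv")
        dist = skin_tone.tone_distribution(train_man.frame["tone_category"])
        dist.to_csv(out / "manifests" / "tone_distribution_a.csv")

        stage = "generate"
        extractor = fixture_extractor(seed=rng_seed)
        styles = {
            name: fixtures.generate_fixture_image(
                fixtures.FixtureSpec(
                    width=config.image_size,
                    height=config.image_size,
                    base_tone_target=tone,
                    lesion_axes=(0.0, 0.0),
                    texture_noise_sd=0.01,
                    seed=rng_seed + 17,
                )
            )[0]
            for name, tone in _STYLE_TONES.items()
        }
        st_cfg = generation.STConfig(iterations=config.st_iterations, seed=rng_seed)
        gen_plan, gen_images = generation.batch_generate(
            train_man,
            styles,
            "st",
            st_cfg,
            extractor,
            image_loader=lambda i: train_imgs[i],
        )
        gen_plan.to_csv(out / "manifests" / "generated.csv", index=False)

        stage = "quality"
        scorer = quality.BrisqueDistanceScorer().fit(list(train_imgs.values()))
        qrows = []
        for _, row in gen_plan.iterrows():
            gimg = gen_images[row.image_id]
            raw = scorer.score_image(gimg)
            sim = quality.ssim(train_imgs[row.content_id], gimg)
            qrows.append(
                {"image_id": row.image_id, "style": row.style, "method": "st",
                 "ssim": sim, "brisque_raw": raw}
            )
        qdf = pd.DataFrame(qrows)
        qdf["brisque_norm"] = quality.normalize_scores(qdf["brisque_raw"])
        qdf.to_csv(out / "scores.csv", index=False)

        stage = "stats"
        vtt = fixtures.simulate_rater_table(
            config.n_raters, config.vtt_images, config.vtt_images,
            p_fpr=0.62, p_tpr=0.60, seed=rng_seed,
        )
        metrics = evalstats.vtt_metrics(vtt)
        diag = fixtures.simulate_diagnosis_table(seed=rng_seed)
        recall = evalstats.recall_by_group(diag)
        report = {
            k: {"estimate": v.estimate, "ci": [v.lower, v.upper], "n": v.trials}
            for k, v in metrics.items()
        }
        report["recall"] = {
            r.truth_type: {"recall": r.recall, "correct": int(r.correct), "total": int(r.total)}
            for r in recall.itertuples()
        }
        with open(out / "stats_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)

        stage = "classify"
        Xte = np.stack([test_imgs[i] for i in test_man.frame["image_id"]])
        yte = test_man.frame["class_label"].to_numpy()
        tr_man, va_man = classifier.split_dataset(train_man, 0.8, seed=rng_seed)
        Xva = np.stack([train_imgs[i] for i in va_man.frame["image_id"]])
        yva = va_man.frame["class_label"].to_numpy()
        regime_results = {}
        scores_by_regime = {}
        for regime in classifier.REGIMES:
            spec = classifier.RegimeSpec(regime, generated_manifest=gen_plan)
            frame = classifier.build_regime(tr_man, spec)
            X, y = classifier.materialize(
                frame,
                image_loader=lambda i: train_imgs[i],
                generated_loader=lambda i: gen_images[i],
                seed=rng_seed,
            )
            model = classifier.LesionClassifier(
                epochs=config.epochs, seed=rng_seed, extractor=fixture_extractor(seed=rng_seed)
            ).fit(X, y, Xva, yva)
            ev = classifier.evaluate(model, Xte, yte)
            scores_by_regime[regime] = ev["scores"]
            regime_results[regime] = {
                "n_train_rows": int(len(frame)),
                "accuracy": ev["accuracy"].estimate,
                "accuracy_ci": [ev["accuracy"].lower, ev["accuracy"].upper],
                "auc": ev["auc"],
                "auc_ci": list(ev["auc_ci"]),
            }
        for regime in ("a_none", "c_geometric", "d_both"):
            d = evalstats.delong_test(
                scores_by_regime["b_generated"]["score"],
                scores_by_regime[regime]["score"],
                scores_by_regime[regime]["label"],
            )
            regime_results[regime]["delong_vs_b"] = {"z": d["z"], "p": d["p"]}
        with open(out / "regime_reports.json", "w") as fh:
            json.dump(regime_results, fh, indent=2, sort_keys=True)
    except StageError:
        raise
    except Exception as e:
        raise StageError(stage, e) from e

    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return out
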
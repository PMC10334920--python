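# dermatone

Tools for diversifying the skin tones represented in dermatology image
banks, and for measuring what that diversification buys.

## The problem

Public skin-lesion image collections are heavily skewed toward light skin:
lesions photographed on darker skin are rare, so classifiers trained on
these banks see almost no dark-skin examples and their reported performance
may not transfer across tones. `dermatone` implements a full pipeline
around one remedy — synthesizing darker-skin counterparts of existing
light-skin lesion images — covering:

1. **Tone audit** (`dermatone.skin_tone`): per-image skin tone via the
   individual typology angle (ITA) in CIELAB, classified into six bands
   from very light to dark.
2. **Image synthesis** (`dermatone.generation`): neural style transfer
   (content + Gram-matrix style losses) and two-round deep blending
   (Poisson-gradient + content + style losses, mask-local) on a
   differentiable NumPy convolutional feature extractor
   (`dermatone.features`).
3. **Quality scoring** (`dermatone.quality`): SSIM against the source
   image and a from-scratch BRISQUE feature implementation (MSCN
   coefficients, GGD/AGGD moment fits, 36 features) with a
   corpus-distance scorer.
4. **Human-study statistics** (`dermatone.evalstats`): exact binomial
   (Clopper–Pearson) intervals, visual-Turing-test metrics, per-group
   diagnosis recall, confusion matrices, OLS significance, and DeLong's
   test for paired AUCs.
5. **Augmentation experiment** (`dermatone.classifier`): four training
   regimes (none / generated / geometric / both) feeding a scikit-learn
   style transfer-learning classifier with a frozen convolutional backbone.

A command-line interface (`dermatone tone|generate|quality|stats|demo`)
wires the stages together; `dermatone demo` runs everything end-to-end on
built-in synthetic fixtures.

## Core model

Style transfer minimizes `alpha * content + beta * style` where the content
loss is a squared feature-map difference and the style loss a squared
Gram-matrix difference over extractor layers; optimization is seeded Adam
with a full per-iteration trace and bit-identical reruns. Deep blending
composites a masked lesion into a tone-reference image and minimizes a
Poisson-gradient loss (Laplacian matching against the composite) plus the
same content/style losses, restricted to the dilated mask, in two rounds.
Eligibility follows the tone audit: light and intermediate images each get
one generated counterpart per target style (tan, brown, dark). Details and
numerical choices are in [docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from dermatone import evalstats, fixtures, generation, quality, skin_tone
from dermatone.features import fixture_extractor

# 1. Audit the tone of a (synthetic) skin image.
img, mask = fixtures.generate_fixture_image(
    fixtures.FixtureSpec(width=64, height=64, base_tone_target=48.0, seed=0))
rec = skin_tone.tone_record("example", img)
print(rec.ita_degrees, rec.category)
# 47.73 light

# 2. Shift a light-skin lesion image toward a dark tone reference.
content, _ = fixtures.generate_fixture_image(
    fixtures.FixtureSpec(width=32, height=32, base_tone_target=48.0, seed=3))
style, _ = fixtures.generate_fixture_image(
    fixtures.FixtureSpec(width=32, height=32, base_tone_target=-45.0,
                         lesion_axes=(0.0, 0.0), seed=4))
res = generation.synthesize_st(
    content, style, generation.STConfig(iterations=50, seed=0),
    fixture_extractor(seed=0))
print(res.trace["total"].iloc[0], res.trace["total"].min())
# 80.61 -> 14.50 (loss ratio 0.180)
ita = skin_tone.compute_ita(skin_tone.rgb_to_lab(res.output))
print(ita, skin_tone.classify_skin_tone(ita))
# -10.3 brown   (the content image was 47.6, light)

# 3. Score the output against its source.
print(quality.ssim(content, res.output))
# 0.075  (noise-initialized, 50 iterations, 32x32 fixtures)

# 4. Exact binomial CI on rater votes: 1511 of 2430 generated images
#    were judged real.
ci = evalstats.clopper_pearson(1511, 2430)
print(ci.estimate, ci.lower, ci.upper)
# 0.6218 (0.6022, 0.6411)
```

An end-to-end run on fixtures (manifests, generated images, quality
scores, rater statistics, four regime reports with DeLong comparisons, and
a provenance JSON):

```bash
dermatone demo --seed 0 --out runs/demo
```

## Reproduction

`scripts/acceptance.py` recomputes the package's headline quantities —
rater-study rates with exact CIs, diagnosis recalls, generation/split
accounting, style-transfer loss reduction, generated-image quality scores,
statistical type-I calibration rates, GGD shape recovery, and the ten-seed
tone-shifted augmentation benchmark (mean test AUC without vs. with
generated-image augmentation) — and writes them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Each entry is `{"value": <number>, "n": <sample size>}`. Count-derived
statistics are deterministic; fixture-based quantities are seeded by
`--seed`. The run takes a few minutes on one CPU. The test suite's
`tests/test_acceptance.py` asserts one criterion per headline property,
including that generated-image augmentation beats no augmentation in mean
AUC on the tone-shifted benchmark over ten seeds.
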
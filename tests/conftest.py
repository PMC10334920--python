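import numpy as np
import pytest

from dermatone import fixtures, generation
from dermatone.features import fixture_extractor


@pytest.fixture(scope="session")
def extractor():
    return fixture_extractor(seed=0)


@pytest.fixture(scope="session")
def lesion_pair():
    """Frozen content/style fixture pair used across generation tests."""
    content_spec = fixtures.FixtureSpec(
        width=32, height=32, base_tone_target=48.0, seed=3
    )
    style_spec = fixtures.FixtureSpec(
        width=32, height=32, base_tone_target=-45.0, lesion_axes=(0.0, 0.0), seed=4
    )
    content, mask = fixtures.generate_fixture_image(content_spec)
    style, _ = fixtures.generate_fixture_image(style_spec)
    return content, mask, style


@pytest.fixture(scope="session")
def small_manifest(tmp_path_factory):
    """On-disk manifest with four real fixture images."""
    root = tmp_path_factory.mktemp("data")
    (root / "images").mkdir()
    rows = []
    for i, (label, tone) in enumerate(
        [("malignant", 48.0), ("benign", 48.0), ("malignant", 35.0), ("benign", 19.0)]
    ):
        spec = fixtures.FixtureSpec(width=32, height=32, base_tone_target=tone, seed=i)
        img, _ = fixtures.generate_fixture_image(spec)
        path = f"images/img_{i}.png"
        fixtures.write_image(img, root / path)
        rows.append(
            {
                "image_id": f"img_{i}",
                "path": path,
                "class_label": label,
                "disease": "melanoma" if label == "malignant" else "halo_nevus",
                "dataset_tag": "fixture",
            }
        )
    import pandas as pd

    man = fixtures.Manifest(pd.DataFrame(rows))
    fixtures.write_manifest(man, root / "manifest.csv")
    return root, man
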
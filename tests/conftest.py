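import numpy as np
import pytest

from itakit import ConversionConfig, PatchSpec, make_patch


@pytest.fixture(scope="session")
def std_cfg():
    return ConversionConfig.standard()


@pytest.fixture(scope="session")
def literal_cfg():
    return ConversionConfig.paper_literal()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250929)


@pytest.fixture
def patch_factory():
    """Build a synthetic skin patch and return (rgb8, ground-truth ITA)."""

    def build(target_ita, noise_sd=0.0, size_n=64, seed=7, radius=30.0):
        return make_patch(
            PatchSpec(
                target_ita=target_ita,
                noise_sd=noise_sd,
                size_n=size_n,
                seed=seed,
                radius=radius,
            )
        )

    return build


@pytest.fixture
def jpeg_patch(tmp_path, patch_factory):
    """A synthetic skin patch saved as an 8-bit JPEG on disk."""
    from PIL import Image

    rgb, truth = patch_factory(-60.0, noise_sd=1.0, size_n=96)
    path = tmp_path / "patch.jpg"
    Image.fromarray(rgb, mode="RGB").save(path, quality=95)
    return path, truth
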
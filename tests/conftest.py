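import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def image_set(tmp_path_factory):
    """Ten jittered synthetic images with masks and truth JSON on disk."""
    from damageqtl.simulate import ImageTruth, generate_plant_image, write_image_fixture

    out = tmp_path_factory.mktemp("images")
    rng = np.random.default_rng(42)
    truths = {}
    for k in range(10):
        u = float(rng.uniform(0.05, 0.9))
        s = float(rng.uniform(0.2, 0.8))
        truth = ImageTruth(
            proportions=(1 - u, u * s, u * (1 - s)),
            n_plant_pixels=800,
            seed=int(rng.integers(2**31)),
        )
        img, truth = generate_plant_image(truth, 40, 40)
        write_image_fixture(img, truth, out, f"img_{k:02d}")
        truths[f"img_{k:02d}"] = truth
    return out, truths
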
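import numpy as np
import pytest

from ascites_resunet import AscitesPocket, PhantomSpec, generate_dataset, generate_slice


@pytest.fixture(scope="session")
def small_spec():
    """A 64-px noiseless phantom spec with one exact-area pocket."""
    return PhantomSpec(
        grid_size=64,
        pixel_spacing_mm=0.74 * 8,
        noise_sd_hu=0.0,
        ascites_pockets=(
            AscitesPocket(center=(0.45, 0.35), semi_axes=(0.12, 0.12), area_px=120),
        ),
        seed=3,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """4 ascites + 4 control subjects x 3 slices at 64 px."""
    spec = PhantomSpec(grid_size=64, pixel_spacing_mm=0.74 * 8, noise_sd_hu=5.0)
    return generate_dataset(4, 4, 3, spec, seed=5)


@pytest.fixture(scope="session")
def tiny_training_arrays():
    """Model-ready tensors for a 16-px toy segmentation problem.

    Bright disks on dark background: linearly separable by intensity, so
    a few epochs suffice for the loss to drop.
    """
    rng = np.random.default_rng(0)
    n = 24
    X = np.zeros((n, 16, 16, 3), dtype=np.float32)
    y = np.zeros((n, 16, 16), dtype=np.float32)
    labels = np.zeros(n, dtype=bool)
    for i in range(n):
        X[i] = rng.uniform(0.0, 0.2, (16, 16, 1)).astype(np.float32)
        if i % 2 == 0:
            rr, cc = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
            cy, cx = rng.integers(5, 11, 2)
            disk = (rr - cy) ** 2 + (cc - cx) ** 2 <= rng.integers(4, 12)
            X[i][disk] = rng.uniform(0.7, 0.9)
            y[i][disk] = 1.0
            labels[i] = True
    return X, y, labels
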
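"""Shared fixtures: a small synthetic cohort and a model trained on it.

Session-scoped so the rendering and training cost is paid once. The small
cohort uses the default two-class optical regimes on reduced frames; the
small model is the full 8-conv/5-pool/3-FC architecture with narrower
channels, which is ample for the separable synthetic task.
"""

import numpy as np
import pytest

import shadowcyte as sc
from shadowcyte import cnn, dataset


SMALL_ARCH = cnn.ArchitectureSpec(
    conv_channels=(8, 8, 16, 16, 32, 32, 64, 64), fc_widths=(64, 32, 2)
)


@pytest.fixture(scope="session")
def optical_config_small():
    return sc.OpticalConfig(frame_shape=(768, 768), noise_sigma=2.0, seed=7)


@pytest.fixture(scope="session")
def cohort_small(optical_config_small):
    """800 cells (400 per class) on reduced frames, with ground truth."""
    frames, manifest = sc.generate_cohort(
        optical_config_small, n_per_class=400, seed=7
    )
    crops = sc.simshadow.cohort_crops(frames, manifest)
    return frames, manifest, crops


@pytest.fixture(scope="session")
def cohort_arrays(cohort_small):
    """Preprocessed inputs and integer labels (1 = CD34_POS) of the cohort."""
    _, manifest, crops = cohort_small
    x = np.stack([dataset.preprocess(c) for c in crops]).astype(np.float32)
    y = (manifest["class_label"] == sc.CD34_POS).to_numpy().astype(np.int64)
    return x, y


@pytest.fixture(scope="session")
def trained_model(cohort_arrays):
    """Small-channel network trained briefly on the separable cohort."""
    x, y = cohort_arrays
    rng = np.random.default_rng(7)
    order = rng.permutation(len(x))
    n_val = len(x) // 5
    val, tr = order[:n_val], order[n_val:]
    model = cnn.build_model(SMALL_ARCH, seed=7)
    return cnn.train(
        model, (x[tr], y[tr]), (x[val], y[val]),
        cnn.TrainConfig(epochs=8, seed=7),
    )
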
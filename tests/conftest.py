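import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_volume_atlas():
    """4x4x4 volume with intensities 0..63 in raster order, two-region atlas
    splitting it into lower/upper halves along the first axis."""
    from bmnet import AtlasParcellation, VolumeGrid

    vol = VolumeGrid(np.arange(64, dtype=float).reshape(4, 4, 4))
    labels = np.zeros((4, 4, 4), dtype=np.int64)
    labels[:2] = 1
    labels[2:] = 2
    return vol, AtlasParcellation(labels)


@pytest.fixture
def small_cohort():
    """A quickly separable 40-subject cohort over 8 regions."""
    from bmnet import CohortSpec, generate_cohort

    spec = CohortSpec(n_per_class=(22, 18), n_regions=8, mean_shift=1.5)
    return generate_cohort(spec, 7).cohort


@pytest.fixture
def tiny_model_config():
    from bmnet import BMNetConfig

    return BMNetConfig(n_regions=8, conv_channels=(4, 6), conv_kernel=3,
                       bp_rank=5, bp_out=8, avgpool_window=2,
                       embedding_dim=6)
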
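import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_instance_map(rng, shape=(16, 16), n_blobs=(0, 5), radius=(1.0, 3.5)):
    """Random instance map built from discs; later ids overwrite earlier."""
    h, w = shape
    labels = np.zeros(shape, dtype=np.int32)
    n = int(rng.integers(n_blobs[0], n_blobs[1] + 1))
    yy, xx = np.mgrid[0:h, 0:w]
    for k in range(1, n + 1):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(*radius)
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2] = k
    # renumber to drop fully occluded ids
    ids = np.unique(labels[labels > 0])
    out = np.zeros_like(labels)
    for i, v in enumerate(ids, start=1):
        out[labels == v] = i
    return out


@pytest.fixture
def instance_map_factory(rng):
    def factory(**kwargs):
        return random_instance_map(rng, **kwargs)

    return factory


def mini_model_config(seed=0, widths=(64, 48, 32, 16)):
    from gcunet.network import ModelConfig

    return ModelConfig(encoder_name="densenet-mini", decoder_widths=widths,
                       seed=seed)
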
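import dataclasses

import numpy as np
import pytest

import wheatvision as wv


@pytest.fixture(scope="session")
def small_spec():
    """A 128x128 scene spec sized so rendering stays fast in tests."""
    return wv.SceneSpec(
        image_width=128,
        image_height=128,
        n_grains=30,
        n_impurities=3,
        grain_axis_range=(5.0, 9.0),
        impurity_length_range=(20.0, 45.0),
        impurity_width_range=(2.0, 5.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def rendered(small_spec):
    return wv.render_scene(small_spec)


@pytest.fixture(scope="session")
def tiny_spec(small_spec):
    """64x64 variant for training-loop tests."""
    return dataclasses.replace(
        small_spec,
        image_width=64,
        image_height=64,
        n_grains=10,
        n_impurities=2,
        grain_axis_range=(4.0, 7.0),
        impurity_length_range=(15.0, 30.0),
        impurity_width_range=(2.0, 4.0),
    )


@pytest.fixture(scope="session")
def tiny_pairs(tiny_spec):
    pairs = []
    for i in range(5):
        s = wv.render_scene(dataclasses.replace(tiny_spec, seed=100 + i))
        pairs.append((s.image, s.mask))
    return pairs


@pytest.fixture(scope="session")
def overfit_model(tiny_pairs):
    """A tiny network overfitted on five scenes; reused across tests."""
    from wheatvision import model as M

    cfg = M.ModelConfig(backbone="tiny", width_multiplier=0.5, input_size=(64, 64))
    net = M.build_model(cfg, seed=0)
    history = M.train(
        net,
        tiny_pairs,
        [],
        M.TrainConfig(epochs=60, batch_size=5, learning_rate=3e-3, seed=0),
    )
    return net, history
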
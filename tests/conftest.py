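"""Shared fixtures: synthetic scenes and a smoke-trained detector.

The trained detector is session-scoped so the end-to-end training run
(8 easy scenes, 3 epochs, ~2 s) happens once for the whole suite.
"""

import dataclasses

import numpy as np
import pytest

from dhcellseg import model, synthgen


@pytest.fixture(scope="session")
def easy_scenes():
    """Ten well-separated bright-blob scenes, seeds 0..9."""
    preset = synthgen.PRESETS["easy"]
    return [
        synthgen.generate_scene(dataclasses.replace(preset, seed=s))
        for s in range(10)
    ]


@pytest.fixture(scope="session")
def smoke_training(easy_scenes):
    """(untrained model, trained model, loss history, held-out scenes).

    Three epochs of SGD (momentum 0.9, lr 0.05) on the first eight scenes;
    the last two are held out for evaluation.
    """
    train_scenes, test_scenes = easy_scenes[:8], easy_scenes[8:]
    config = model.TrainConfig(initial_lr=0.05, max_epochs=3, seed=0)
    untrained = model.build_mask_rdhcnn(train_config=config)
    trained = model.build_mask_rdhcnn(train_config=config)
    dataset = [(s.as_rgb(), s.instances) for s in train_scenes]
    result = model.train(trained, dataset, config)
    return untrained, trained, result.loss_history, test_scenes
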
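import dataclasses

import numpy as np
import pytest

import spirecon as sr
from spirecon.recon_classical import ReconSpec
from spirecon.recon_net import build_network, train
from spirecon.synthetic_data import default_spec, gen_scene, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_op():
    """Random bipolar operator on a 4x4 grid, M=12."""
    return sr.random_operator(12, 4, 4, seed=7)


@pytest.fixture
def small_scene(rng):
    return sr.ImageScene(rng.random((4, 4)))


@pytest.fixture(scope="session")
def desk_model():
    """Patterns learned and a network trained at the desk scale.

    32x32 nucleus scenes, M=200 learned patterns, a K=3 / C=16 unrolled
    network trained on 200 pairs — shared by the training-efficacy and
    zoom-mode tests because training is the expensive step.
    """
    spec = default_spec("nucleus", 32)
    images = [gen_scene(dataclasses.replace(spec, seed=s)) for s in range(50)]
    op, pat_log = sr.learn_patterns(images, 200, 600, seed=0)
    train_pairs, test_pairs = make_dataset(spec, op, 200, seed=1)
    net = build_network(ReconSpec(stage_count=3, channels=16, ratio=200 / 1024), seed=2)
    log = train(net, train_pairs, op, epochs=30, seed=3)
    return {
        "op": op,
        "net": net,
        "train_pairs": train_pairs,
        "test_pairs": test_pairs,
        "pattern_log": pat_log,
        "train_log": log,
    }
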
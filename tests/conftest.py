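"""Shared fixtures: the bundled tiny synthetic dataset and the two
end-to-end training runs (semi-supervised and supervised), trained once
per session and reused by the engine and acceptance tests."""

from __future__ import annotations

import time

import numpy as np
import pytest

from msstgan.data import generate_dataset, generate_sample
from msstgan.engine import TrainConfig, train_on_samples

TINY_SEED = 7
HELDOUT_SEEDS = range(10_000, 10_008)


@pytest.fixture(scope="session")
def tiny_manifest(tmp_path_factory):
    """8 labeled (flaky / point-flaky) + 8 unlabeled (point-like), 64 px."""
    outdir = tmp_path_factory.mktemp("tiny_dataset")
    return generate_dataset(8, 8, 64, TINY_SEED, outdir)


@pytest.fixture(scope="session")
def heldout_flaky():
    """Eight flaky samples never seen in training (distinct seed range)."""
    return [generate_sample("flaky", 64, s) for s in HELDOUT_SEEDS]


def _train(manifest, heldout, mode):
    labeled = manifest.load_labeled()
    unlabeled = manifest.load_unlabeled() if mode == "semi" else []
    cfg = TrainConfig.tiny(mode=mode, seed=0)
    t0 = time.time()
    g, d, record = train_on_samples(labeled, unlabeled, cfg, val=heldout)
    return {"segmentor": g, "discriminator": d, "record": record,
            "wall_seconds": time.time() - t0, "config": cfg}


@pytest.fixture(scope="session")
def trained_semi(tiny_manifest, heldout_flaky):
    return _train(tiny_manifest, heldout_flaky, "semi")


@pytest.fixture(scope="session")
def trained_supervised(tiny_manifest, heldout_flaky):
    return _train(tiny_manifest, heldout_flaky, "supervised")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
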
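import numpy as np
import pytest

from bafawubu import preprocess as pp
from bafawubu import simulate as sim
from bafawubu.movements import CLASS_ORDER
from bafawubu.tcn import SplitSpec, TcnConfig, build_tcn, split_dataset, train

#: Scaled-down architecture used throughout the tests: 4 blocks, 16 filters,
#: dilations chosen so the receptive field (121) still covers the 100-sample
#: window.
SCALED = dict(n_blocks=4, filters=16, dilations=(4, 8, 16, 32))


def make_dataset(n_subjects=6, movement_s=10.0, noise=sim.ZERO_NOISE,
                 seed0=0):
    """Per-class single-movement recordings for ``n_subjects`` subjects,
    conditioned and windowed."""
    sigs = sim.default_signatures()
    windows, labels, subjects = [], [], []
    for subj in range(n_subjects):
        for i, movement in enumerate(CLASS_ORDER):
            stream = sim.synth_movement(sigs[movement], movement_s, 200,
                                        noise=noise, seed=seed0 + 100 * subj + i)
            d = pp.windows_from_session(stream, subject_id=f"s{subj:02d}")
            windows.append(d.windows)
            labels.append(d.labels)
            subjects.append(d.subject_ids)
    return pp.WindowedDataset(np.concatenate(windows), np.concatenate(labels),
                              np.concatenate(subjects))


@pytest.fixture(scope="session")
def signatures():
    return sim.default_signatures()


@pytest.fixture(scope="session")
def small_dataset():
    return make_dataset()


@pytest.fixture(scope="session")
def trained_small(small_dataset):
    """A converged scaled model with its train/validation split."""
    train_set, val_set = split_dataset(small_dataset,
                                       SplitSpec(unit="subject", seed=0))
    config = TcnConfig(**SCALED, epochs=60, seed=0)
    bundle = build_tcn(config)
    bundle, history = train(bundle, train_set, val_set)
    return bundle, history, train_set, val_set
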
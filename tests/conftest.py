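import numpy as np
import pytest

import actigate as ag
from actigate import models as mdl
from actigate import protocol
from actigate.encoding import ChannelStats, encode_windows, stack_channels


@pytest.fixture(scope="session")
def profiles():
    return ag.default_profiles()


@pytest.fixture(scope="session")
def tiny_model():
    """A quickly trained FCN-I used by pipeline tests.

    Trained on a small transition-containing synthetic set; the pipeline
    tests only need a model that is consistent and reasonably accurate on
    default-profile streams.
    """
    windows = protocol.training_windows(n_windows=900, seed=7)
    stats = ChannelStats.fit([stack_channels(w) for w in windows])
    images = encode_windows(windows, stats)
    labels = np.array([w.true_label for w in windows])
    spec = mdl.build_spec("FCN-I")
    cfg = mdl.TrainingConfig(max_epochs=30, patience=8, seed=3)
    return mdl.train(spec, images, labels, cfg, stats=stats)
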
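import numpy as np
import pytest

import premscore as pm


@pytest.fixture(scope="session")
def small_windows():
    """A small preprocessed synthetic recording with its context windows.

    Generated at 128 Hz so the filter + resample path is exercised cheaply.
    """
    hyp = pm.generate_hypnogram(pm.DEFAULT_HYPNOGRAM_MODEL, 40, seed=11)
    rec = pm.generate_recording(hyp, pm.DEFAULT_SIGNAL_MODELS, fs=128.0, seed=12)
    pre = pm.preprocess_recording(rec)
    return pm.make_windows(pre, hyp), hyp


@pytest.fixture()
def ramp_window():
    """A context window over a linear-ramp source (slice bookkeeping oracle)."""
    spe = 640
    n_epochs = 5
    source = np.arange(-spe, (n_epochs + 1) * spe, dtype=np.float64)
    k = 2  # interior epoch
    start = k * spe
    return pm.ContextWindow(
        signal=source[start : start + 3 * spe],
        label=int(pm.Stage.WAKE),
        center_epoch=k,
        source=source,
        start=start,
    )
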
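"""Synthetic generator: Markov hypnograms, spectral signatures, separability."""

import hashlib

import numpy as np
import pytest
from scipy import signal as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import train_test_split

import premscore as pm
from premscore.errors import ConfigError
from premscore.synth import _ARTIFACT_CLIP_FRACTION


def bandpower(x, fs, lo, hi):
    f, p = sps.welch(x, fs=fs, nperseg=min(len(x), 4 * int(fs)))
    sel = (f >= lo) & (f <= hi)
    return np.trapezoid(p[sel], f[sel])


# ---------------------------------------------------------------------------
# hypnogram sampling


def test_absorbing_chain_stays_in_wake():
    model = pm.HypnogramModel(transition_matrix=np.eye(5),
                              initial_distribution=np.array([1, 0, 0, 0, 0.0]))
    hyp = pm.generate_hypnogram(model, 100, seed=0)
    assert (hyp.labels == int(pm.Stage.WAKE)).all()


def test_empty_hypnogram():
    assert len(pm.generate_hypnogram(pm.DEFAULT_HYPNOGRAM_MODEL, 0, seed=0)) == 0


def test_hypnogram_deterministic_given_seed():
    a = pm.generate_hypnogram(pm.DEFAULT_HYPNOGRAM_MODEL, 500, seed=42)
    b = pm.generate_hypnogram(pm.DEFAULT_HYPNOGRAM_MODEL, 500, seed=42)
    assert np.array_equal(a.labels, b.labels)


def test_non_stochastic_rows_rejected():
    bad = np.eye(5)
    bad[0, 0] = 0.9
    with pytest.raises(ConfigError):
        pm.HypnogramModel(transition_matrix=bad,
                          initial_distribution=np.array([1, 0, 0, 0, 0.0]))


def test_empirical_transitions_match_model_within_3se():
    """Binomial oracle: each well-visited cell's empirical frequency lies
    within 3 standard errors of the model probability."""
    model = pm.DEFAULT_HYPNOGRAM_MODEL
    hyp = pm.generate_hypnogram(model, 50_000, seed=12345)
    counts, norm = pm.markov_matrix(
        hyp.labels, classes=[int(s) for s in pm.ALL_STAGES])
    row_n = counts.sum(axis=1)
    P = model.transition_matrix
    for i in range(5):
        if row_n[i] < 500:  # too few visits for a 3-sigma binomial check
            continue
        se = np.sqrt(P[i] * (1 - P[i]) / row_n[i])
        assert (np.abs(norm[i] - P[i]) <= 3 * se + 1.0 / row_n[i]).all(), i


def test_stationary_wake_fraction_matches_dataset_like_frequencies():
    hyp = pm.generate_hypnogram(pm.DEFAULT_HYPNOGRAM_MODEL, 20_000, seed=7)
    wake_frac = np.mean(hyp.labels == int(pm.Stage.WAKE))
    assert 0.45 <= wake_frac <= 0.65
    # the designed stationary distribution itself
    pi = pm.DEFAULT_HYPNOGRAM_MODEL.stationary_distribution()
    assert pi[int(pm.Stage.WAKE)] == pytest.approx(0.55, abs=0.05)
    assert pi[int(pm.Stage.NREM)] == pytest.approx(0.38, abs=0.05)


# ---------------------------------------------------------------------------
# per-stage signals


def test_zero_amplitudes_give_zero_signal():
    model = pm.StageSignalModel(osc_amp=0, noise_amp=0, burst_amp=0)
    x = pm.synthesize_epoch(pm.Stage.WAKE, model, fs=64.0, seed=0)
    assert np.array_equal(x, np.zeros(640))


def test_epoch_length():
    x = pm.synthesize_epoch(pm.Stage.NREM, pm.DEFAULT_SIGNAL_MODELS[pm.Stage.NREM],
                            fs=64.0, duration_s=10.0, seed=0)
    assert len(x) == 640


def test_nrem_psd_peak_in_delta_band():
    x = pm.synthesize_epoch(pm.Stage.NREM, pm.DEFAULT_SIGNAL_MODELS[pm.Stage.NREM],
                            fs=64.0, seed=3)
    f, p = sps.welch(x, fs=64.0, nperseg=256)
    peak = f[np.argmax(p)]
    assert 0.5 <= peak <= 4.0


def test_rem_theta_dominates_delta():
    x = pm.synthesize_epoch(pm.Stage.REM, pm.DEFAULT_SIGNAL_MODELS[pm.Stage.REM],
                            fs=64.0, seed=4)
    assert bandpower(x, 64.0, 7, 8) / bandpower(x, 64.0, 0.5, 4) > 1.0


def test_prerem_carries_spindle_band_energy_and_theta():
    m = pm.DEFAULT_SIGNAL_MODELS
    prerem = pm.synthesize_epoch(pm.Stage.PREREM, m[pm.Stage.PREREM], fs=64.0, seed=5)
    nrem = pm.synthesize_epoch(pm.Stage.NREM, m[pm.Stage.NREM], fs=64.0, seed=5)
    assert bandpower(prerem, 64.0, 10, 15) > 3 * bandpower(nrem, 64.0, 10, 15)
    assert bandpower(prerem, 64.0, 6.5, 8.5) > bandpower(nrem, 64.0, 6.5, 8.5)


def test_artifact_contains_clipped_spike_above_5x_rms():
    m = pm.DEFAULT_SIGNAL_MODELS[pm.Stage.ARTIFACT]
    x = pm.synthesize_epoch(pm.Stage.ARTIFACT, m, fs=64.0, seed=6)
    rms = np.sqrt(np.mean(x**2))
    assert np.max(np.abs(x)) >= 5 * rms
    clip = _ARTIFACT_CLIP_FRACTION * m.burst_amp
    assert np.sum(np.isclose(np.abs(x), clip)) >= 2  # flat-topped (clipped)


def test_nyquist_precondition():
    with pytest.raises(ConfigError):
        pm.synthesize_epoch(pm.Stage.REM, pm.DEFAULT_SIGNAL_MODELS[pm.Stage.REM],
                            fs=10.0, seed=0)


def test_bandpower_lda_separates_main_stages():
    """The fixture must be learnable: a linear discriminant on log bandpowers
    reaches >= 90 % 3-class accuracy."""
    rng = np.random.default_rng(202)
    X, y = [], []
    for stage in (pm.Stage.WAKE, pm.Stage.NREM, pm.Stage.REM):
        for _ in range(120):
            x = pm.synthesize_epoch(stage, pm.DEFAULT_SIGNAL_MODELS[stage],
                                    fs=64.0, seed=rng)
            feats = [bandpower(x, 64, 0.5, 4), bandpower(x, 64, 6, 9),
                     bandpower(x, 64, 10, 15), np.mean(x**2)]
            X.append(np.log(np.asarray(feats) + 1e-12))
            y.append(int(stage))
    X_tr, X_te, y_tr, y_te = train_test_split(
        np.array(X), np.array(y), test_size=0.33, random_state=0, stratify=y)
    acc = LinearDiscriminantAnalysis().fit(X_tr, y_tr).score(X_te, y_te)
    assert acc >= 0.90


# ---------------------------------------------------------------------------
# dataset files


def test_generate_dataset_bookkeeping(tmp_path):
    paths = pm.generate_dataset(tmp_path, n_epochs=20, n_subjects=3, seed=1,
                                fs=128.0)
    assert len(paths) == 3
    from premscore import read_hypnogram, read_recording
    for rec_path, hyp_path in paths:
        rec = read_recording(rec_path)
        hyp = read_hypnogram(hyp_path, n_epochs=20)
        assert rec.fs == 128.0
        assert len(rec.samples) == 20 * 10 * 128
        assert len(hyp) == 20


def test_generate_dataset_deterministic_bytes(tmp_path):
    def digest(root):
        h = hashlib.sha256()
        for rp, hp in pm.generate_dataset(root, n_epochs=10, n_subjects=2,
                                          seed=9, fs=128.0):
            h.update(rp.read_bytes())
            h.update(hp.read_bytes())
        return h.hexdigest()

    assert digest(tmp_path / "a") == digest(tmp_path / "b")


def test_subjects_have_distinct_streams(tmp_path):
    paths = pm.generate_dataset(tmp_path, n_epochs=10, n_subjects=2, seed=3,
                                fs=128.0)
    a = np.fromfile(paths[0][0], dtype="<f4")
    b = np.fromfile(paths[1][0], dtype="<f4")
    assert not np.array_equal(a, b)
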
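"""Synthetic two-class motor-imagery EEG generator.

Emulates the statistical structure of two-channel (C3/C4) motor-imagery EEG
sampled at 128 Hz for 9 s per trial: broadband background activity band-limited
to 0.5-30 Hz plus a narrowband mu rhythm (8-12 Hz), with class-dependent
event-related desynchronisation/synchronisation (ERD/ERS). During the imagery
window the mu amplitude of the channel contralateral to the imagined hand is
multiplied by ``1 - erd_depth`` (ERD) and the ipsilateral channel's by
``1 + erd_depth`` (ERS), so the channel-wise entropy trajectories drift in
opposite directions for the two classes — the signature the WCMFE features
pick up.

The generator emulates band-limited spectra, trial-to-trial mu amplitude
jitter and the ERD/ERS timing; it does not model 1/f background by default
(optional flag), artifacts (eye blinks, EMG), volume conduction between
channels, or gradual ERD onset (gain switching is instantaneous).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .trials import EEGTrial

__all__ = ["SimConfig", "generate_trial", "generate_dataset"]

LABELS = ("left", "right")


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    Defaults emulate the source recording conditions: 128 Hz sampling, 9 s
    trials, channels C3/C4, 0.5-30 Hz band, with the imagery modulation
    spanning 3.5-7.0 s (samples 450-900). ``mu_rms`` sets the mu-rhythm RMS
    amplitude relative to the broadband noise SD (``noise_sd``); the default
    1.5 vs 1.0 corresponds to a subject with a prominent mu rhythm.
    """

    fs: float = 128.0
    duration_s: float = 9.0
    channels: tuple = ("C3", "C4")
    band: tuple = (0.5, 30.0)
    mu_band: tuple = (8.0, 12.0)
    mu_rms: float = 1.5
    amp_jitter: float = 0.2
    erd_depth: float = 0.5
    erd_onset_s: float = 3.5
    erd_offset_s: float = 7.0
    noise_sd: float = 1.0
    one_over_f: bool = False
    n_trials_per_class: int = 70
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.erd_depth < 1.0):
            raise ValueError(f"erd_depth must be in [0, 1), got {self.erd_depth}")
        if not (0.0 <= self.erd_onset_s < self.erd_offset_s <= self.duration_s):
            raise ValueError("need 0 <= erd_onset_s < erd_offset_s <= duration_s")
        n = self.fs * self.duration_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * duration_s must be an integer number of samples")
        if len(self.channels) != 2:
            raise ValueError("generator models exactly two channels (C3, C4)")
        if self.noise_sd <= 0 or self.mu_rms < 0:
            raise ValueError("noise_sd must be > 0 and mu_rms >= 0")
        if not (0.0 <= self.amp_jitter < 1.0):
            raise ValueError(f"amp_jitter must be in [0, 1), got {self.amp_jitter}")
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


def _bandpass_sos(band, fs):
    return butter(4, band, btype="bandpass", fs=fs, output="sos")


def _shaped_noise(rng, n, sos, one_over_f, fs):
    white = rng.standard_normal(n)
    if one_over_f:
        # 1/f amplitude shaping in the frequency domain before band-limiting
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        freqs[0] = freqs[1]
        spec /= np.sqrt(freqs)
        white = np.fft.irfft(spec, n)
    return sosfiltfilt(sos, white)


def generate_trial(class_label: str, cfg: SimConfig, rng) -> EEGTrial:
    """One synthetic trial; deterministic given (class_label, cfg, rng state).

    Both channels are band-limited noise plus a narrowband mu oscillation;
    during [erd_onset_s, erd_offset_s) the mu amplitude of the contralateral
    channel is scaled by ``1 - erd_depth`` and the ipsilateral one by
    ``1 + erd_depth``. The random draws do not depend on the label, so with
    ``erd_depth = 0`` the label carries no information.
    """
    if class_label not in LABELS:
        raise ValueError(f"class_label must be one of {LABELS}, got {class_label!r}")
    n = cfg.n_samples
    sos_broad = _bandpass_sos(cfg.band, cfg.fs)
    sos_mu = _bandpass_sos(cfg.mu_band, cfg.fs)
    on = int(round(cfg.erd_onset_s * cfg.fs))
    off = int(round(cfg.erd_offset_s * cfg.fs))
    # left-hand imagery modulates the right hemisphere (C4 = channel 1)
    contra = 1 if class_label == "left" else 0
    data = np.empty((2, n))
    for c in range(2):
        noise = _shaped_noise(rng, n, sos_broad, cfg.one_over_f, cfg.fs)
        noise *= cfg.noise_sd / noise.std()
        mu = sosfiltfilt(sos_mu, rng.standard_normal(n))
        amp = cfg.mu_rms * (1.0 + rng.uniform(-cfg.amp_jitter, cfg.amp_jitter))
        if cfg.mu_rms > 0:
            mu *= amp / mu.std()
        gain = np.ones(n)
        gain[on:off] = (1.0 - cfg.erd_depth) if c == contra else (1.0 + cfg.erd_depth)
        data[c] = noise + gain * mu
    return EEGTrial(data=data, fs=cfg.fs, channel_names=cfg.channels,
                    label=class_label)


def generate_dataset(cfg: SimConfig):
    """Balanced, reproducibly shuffled two-class dataset.

    Returns ``(trials, labels)`` with ``n_trials_per_class`` trials per class;
    generation order and the final shuffle are both driven by ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    trials = []
    labels = []
    for lab in LABELS:
        for _ in range(cfg.n_trials_per_class):
            trials.append(generate_trial(lab, cfg, rng))
            labels.append(lab)
    perm = rng.permutation(len(trials))
    trials = [trials[i] for i in perm]
    labels = np.asarray(labels, dtype=object)[perm].astype(str)
    return trials, labels
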
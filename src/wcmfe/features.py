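"""Trial-level feature pipeline.

A trial's feature vector concatenates, scale by scale, the WCMFE of every
channel: for scales 1..tau_max and channels 1..nC,

    F = [F_1, ..., F_tau_max],   F_tau = [WCMFE_tau(ch_1), ..., WCMFE_tau(ch_nC)]

giving nC * tau_max values (14 for the default two channels C3/C4 and
tau_max = 7, the input size of the classifier). The module also provides the
sliding-window mean-entropy curves used to pick the analysis interval, the
interval selector itself, and the between-channel difference statistics
(DWC / MWC / SDWC) used in parameter studies.

:class:`WCMFEFeatureExtractor` wraps the pipeline as a scikit-learn
transformer operating on ``(n_trials, n_channels, n_samples)`` arrays (or
lists of :class:`~wcmfe.trials.EEGTrial`), so it composes with sklearn
pipelines and model selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .coarse import cmfe, make_weights, uniform_weights, wcmfe
from .entropy import FEParams
from .trials import EEGTrial, Interval, crop

__all__ = [
    "extract_features",
    "WCMFEFeatureExtractor",
    "mean_entropy_curve",
    "select_interval",
    "DWCStats",
    "dwc_stats",
]


def _weights_for(tau: int, h) -> "WeightVector":
    if h == "uniform":
        return uniform_weights(tau)
    return make_weights(tau, h)


def extract_features(trial: EEGTrial, tau_max: int = 7, h=3,
                     params: FEParams = FEParams(),
                     r_mode: str = "global") -> np.ndarray:
    """Fused WCMFE feature vector of one (already cropped) trial.

    Returns a vector of length ``n_channels * tau_max`` laid out scale-major:
    element ``(tau - 1) * nC + c`` is the WCMFE of channel ``c`` at scale
    ``tau``. ``h`` selects the weight mode (1..4) or ``"uniform"`` for plain
    CMFE features.
    """
    nC = trial.n_channels
    out = np.empty(nC * tau_max)
    for c in range(nC):
        x = trial.data[c]
        for tau in range(1, tau_max + 1):
            try:
                out[(tau - 1) * nC + c] = wcmfe(
                    x, tau, _weights_for(tau, h), params, r_mode=r_mode
                )
            except ValueError as exc:
                name = trial.channel_names[c]
                raise type(exc)(f"channel {name!r}, scale tau={tau}: {exc}") from exc
    return out


class WCMFEFeatureExtractor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer computing WCMFE features per trial.

    Parameters
    ----------
    tau_max : int, default 7
        Maximum coarse-graining scale.
    m : int, default 2
        Embedding dimension of the fuzzy-entropy kernel.
    n : float, default 2.0
        Boundary gradient of the fuzzy membership function.
    r : float, default 0.15
        Boundary width as a multiplier of the cropped channel's SD.
    h : int in 1..4 or "uniform", default 3
        Weight-factor mode; "uniform" yields plain CMFE features.
    interval : (b, d) tuple, Interval, or None, default None
        Optional 1-based inclusive crop applied to every trial before
        feature extraction.
    r_mode : {"global", "per_sequence"}, default "global"
        Whether the entropy tolerance is resolved once per cropped channel
        or per coarse-grained sequence.

    Attributes
    ----------
    n_channels_ : int
        Channels seen during :meth:`fit`.
    n_features_out_ : int
        ``n_channels_ * tau_max``.
    channel_names_ : tuple of str
        Labels taken from the first trial when fitting on ``EEGTrial``
        objects, else ``("ch0", "ch1", ...)``.
    """

    def __init__(self, tau_max: int = 7, m: int = 2, n: float = 2.0,
                 r: float = 0.15, h=3, interval=None, r_mode: str = "global"):
        self.tau_max = tau_max
        self.m = m
        self.n = n
        self.r = r
        self.h = h
        self.interval = interval
        self.r_mode = r_mode

    def _interval(self) -> Interval | None:
        if self.interval is None:
            return None
        if isinstance(self.interval, Interval):
            return self.interval
        b, d = self.interval
        return Interval(int(b), int(d))

    def _coerce(self, X) -> list[EEGTrial]:
        if isinstance(X, EEGTrial):
            X = [X]
        trials = []
        for i, t in enumerate(X):
            if isinstance(t, EEGTrial):
                trials.append(t)
            else:
                arr = np.atleast_2d(np.asarray(t, dtype=float))
                names = tuple(f"ch{c}" for c in range(arr.shape[0]))
                trials.append(EEGTrial(data=arr, fs=1.0, channel_names=names))
        if not trials:
            raise ValueError("X contains no trials")
        nC = trials[0].n_channels
        if any(t.n_channels != nC for t in trials):
            raise ValueError("all trials must have the same number of channels")
        return trials

    def fit(self, X, y=None):
        trials = self._coerce(X)
        self.n_channels_ = trials[0].n_channels
        self.channel_names_ = trials[0].channel_names
        self.n_features_in_ = trials[0].n_samples * self.n_channels_
        self.n_features_out_ = self.n_channels_ * self.tau_max
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_out_")
        trials = self._coerce(X)
        iv = self._interval()
        params = FEParams(m=self.m, n=self.n, r=self.r)
        out = np.empty((len(trials), self.n_features_out_))
        for i, t in enumerate(trials):
            if t.n_channels != self.n_channels_:
                raise ValueError(
                    f"trial {i} has {t.n_channels} channels, expected {self.n_channels_}"
                )
            tt = crop(t, iv) if iv is not None else t
            out[i] = extract_features(tt, tau_max=self.tau_max, h=self.h,
                                      params=params, r_mode=self.r_mode)
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "n_features_out_")
        return np.array([
            f"wcmfe_tau{tau}_{self.channel_names_[c]}"
            for tau in range(1, self.tau_max + 1)
            for c in range(self.n_channels_)
        ])


def mean_entropy_curve(trials, channel: str, window_s: float = 1.0,
                       step_samples: int = 1, tau: int = 2,
                       params: FEParams = FEParams(), method: str = "cmfe",
                       h: int = 3) -> np.ndarray:
    """Sliding-window entropy curve averaged over trials (one channel).

    For each window position the composite multiscale fuzzy entropy of that
    window is computed per trial and averaged across trials, producing the
    trial-mean entropy trajectory used to locate the period where the two
    imagery classes diverge. The tolerance is resolved per window
    (``r * SD(window)``).
    """
    trials = list(trials)
    if not trials:
        raise ValueError("empty trial list")
    fs = trials[0].fs
    N = trials[0].n_samples
    if any(t.fs != fs or t.n_samples != N for t in trials):
        raise ValueError("all trials must share sampling rate and length")
    if method not in ("cmfe", "wcmfe"):
        raise ValueError(f"method must be 'cmfe' or 'wcmfe', got {method!r}")
    w = int(round(window_s * fs))
    if w < tau * (params.m + 3):
        raise ValueError(
            f"window of {w} samples too short for tau={tau}, m={params.m}"
        )
    if not (isinstance(step_samples, (int, np.integer)) and step_samples >= 1):
        raise ValueError(f"step_samples must be a positive integer, got {step_samples}")
    signals = [t.channel(channel) for t in trials]
    starts = range(0, N - w + 1, step_samples)
    weights = uniform_weights(tau) if method == "cmfe" else make_weights(tau, h)
    curve = np.empty(len(starts))
    for i, s in enumerate(starts):
        acc = 0.0
        for x in signals:
            acc += wcmfe(x[s : s + w], tau, weights, params)
        curve[i] = acc / len(signals)
    return curve


def select_interval(curve_class1, curve_class2, length: int) -> Interval:
    """Contiguous interval maximising the mean absolute class difference.

    Scans all windows of ``length`` points over the two (equal-length) class
    curves and returns the one with the largest mean ``|curve1 - curve2|``;
    ties break to the earliest start. Returned bounds are 1-based inclusive
    positions on the curve's axis.
    """
    c1 = np.asarray(curve_class1, dtype=float)
    c2 = np.asarray(curve_class2, dtype=float)
    if c1.shape != c2.shape or c1.ndim != 1:
        raise ValueError("class curves must be one-dimensional and equal length")
    if not (isinstance(length, (int, np.integer)) and 1 <= length <= c1.size):
        raise ValueError(
            f"interval length must be in 1..{c1.size}, got {length}"
        )
    diff = np.abs(c1 - c2)
    window_means = np.convolve(diff, np.ones(int(length)), mode="valid") / length
    start = int(np.argmax(window_means))  # first maximum = earliest tie-break
    return Interval(start + 1, start + int(length))


@dataclass(frozen=True)
class DWCStats:
    """Mean (MWC) and population SD (SDWC) of the C3 - C4 entropy difference."""

    mwc: float
    sdwc: float


def dwc_stats(features_c3, features_c4, labels) -> dict:
    """Per-class statistics of the between-channel WCMFE difference.

    ``DWC = WCMFE(C3) - WCMFE(C4)`` per trial; returns a mapping from class
    label to :class:`DWCStats` with the class mean and population SD of DWC.
    """
    c3 = np.asarray(features_c3, dtype=float)
    c4 = np.asarray(features_c4, dtype=float)
    labels = np.asarray(labels)
    if not (c3.shape == c4.shape == labels.shape) or c3.ndim != 1:
        raise ValueError("features_c3, features_c4 and labels must be equal-length 1-D")
    dwc = c3 - c4
    out = {}
    for lab in np.unique(labels):
        d = dwc[labels == lab]
        out[lab] = DWCStats(mwc=float(d.mean()), sdwc=float(d.std()))
    return out
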
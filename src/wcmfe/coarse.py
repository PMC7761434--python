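"""Weighted coarse-graining and composite multiscale fuzzy entropy.

Coarse-graining at scale ``tau`` reduces a series by collapsing consecutive
windows of ``tau`` samples into one value. The composite variant (CMFE) uses
all ``tau`` window offsets and averages their fuzzy entropies; the weighted
variant (WCMFE) replaces the plain within-window mean by a symmetric weighted
mean ``A[tau, h]`` that acts as a linear-phase FIR low-pass filter on the
signal. The weight rule, parameterised by a mode ``h`` in 1..4, is

    A[tau, h] = [h/10, (5-h)/(5*(tau-2)) ... (tau-2 copies) ..., h/10]

for ``tau > 2``; the coefficients are positive, symmetric and sum to 1.
Mode ``h`` trades endpoint vs. centre emphasis: h=1 weights the window centre
most heavily, h=4 the endpoints. Uniform coefficients ``1/tau`` recover CMFE
exactly (same code path).

The coarse-grained value is the weighted mean ``sum_p A(p) * x(p)`` with the
coefficients summing to 1, so weighted and plain coarse-graining live on the
same amplitude scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import freqz

from .entropy import FEParams, _as_sequence, fuzzy_entropy

__all__ = [
    "WeightVector",
    "ScaleSet",
    "make_weights",
    "uniform_weights",
    "coarse_grain",
    "wcmfe",
    "cmfe",
    "filter_frequency_response",
]


@dataclass(frozen=True)
class WeightVector:
    """Coarse-graining coefficients for one scale factor.

    ``h`` is the selection mode (1..4) or the string ``"uniform"``; ``coeffs``
    holds ``tau`` positive coefficients summing to 1, symmetric about the
    window centre (the linear-phase property of the equivalent FIR filter).
    """

    tau: int
    h: int | str
    coeffs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        object.__setattr__(self, "coeffs", c)
        if c.shape != (self.tau,):
            raise ValueError(f"expected {self.tau} coefficients, got shape {c.shape}")
        if not np.all(c > 0):
            raise ValueError("all weight coefficients must be > 0")
        if abs(float(c.sum()) - 1.0) > 1e-12:
            raise ValueError(f"weight coefficients must sum to 1, got {c.sum()!r}")


@dataclass(frozen=True)
class ScaleSet:
    """The scales 1..tau_max over which multiscale entropy is evaluated."""

    tau_max: int = 7

    def __post_init__(self) -> None:
        if not (isinstance(self.tau_max, (int, np.integer)) and self.tau_max >= 1):
            raise ValueError(f"tau_max must be a positive integer, got {self.tau_max}")

    @property
    def scales(self) -> range:
        return range(1, self.tau_max + 1)


def make_weights(tau: int, h: int) -> WeightVector:
    """Symmetric weight factors for scale ``tau`` and mode ``h`` in 1..4.

    For ``tau > 2``: endpoints ``h/10``, the ``tau - 2`` interior points each
    ``(5 - h) / (5 * (tau - 2))``. The rule is only defined for ``tau > 2``;
    ``tau = 2`` falls back to the uniform pair [0.5, 0.5] and ``tau = 1`` to
    [1.0] (no coarse-graining).
    """
    if not (isinstance(h, (int, np.integer)) and 1 <= h <= 4):
        raise ValueError(f"weight mode h must be an integer in 1..4, got {h}")
    if not (isinstance(tau, (int, np.integer)) and tau >= 1):
        raise ValueError(f"tau must be a positive integer, got {tau}")
    if tau == 1:
        coeffs = np.array([1.0])
    elif tau == 2:
        coeffs = np.array([0.5, 0.5])
    else:
        end = h / 10.0
        mid = (5.0 - h) / (5.0 * (tau - 2))
        coeffs = np.concatenate(([end], np.full(tau - 2, mid), [end]))
    return WeightVector(tau=int(tau), h=int(h), coeffs=coeffs)


def uniform_weights(tau: int) -> WeightVector:
    """Uniform coefficients ``1/tau`` — plain-mean coarse-graining (CMFE)."""
    if not (isinstance(tau, (int, np.integer)) and tau >= 1):
        raise ValueError(f"tau must be a positive integer, got {tau}")
    return WeightVector(tau=int(tau), h="uniform", coeffs=np.full(tau, 1.0 / tau))


def coarse_grain(signal, tau: int, k: int, weights: WeightVector) -> np.ndarray:
    """The ``k``-th offset weighted coarse-grained sequence at scale ``tau``.

    ``k`` is 1-based in 1..tau. Element ``j`` is the weighted mean of the
    window of ``tau`` samples starting at sample ``(j-1)*tau + k`` (1-based);
    windows that would overrun the signal end are dropped, so the output has
    ``floor((H - k + 1) / tau)`` elements for a signal of length ``H``.
    """
    x = _as_sequence(signal, "signal")
    if not (isinstance(tau, (int, np.integer)) and tau >= 1):
        raise ValueError(f"tau must be a positive integer, got {tau}")
    if not (isinstance(k, (int, np.integer)) and 1 <= k <= tau):
        raise ValueError(f"offset k must be in 1..{tau}, got {k}")
    if weights.tau != tau:
        raise ValueError(f"weight vector is for tau={weights.tau}, not tau={tau}")
    H = x.size
    n_win = (H - (k - 1)) // tau
    if n_win < 1:
        raise ValueError(
            f"signal of length {H} too short for tau={tau}, k={k}: "
            f"needs at least {tau + k - 1} samples"
        )
    windows = x[k - 1 : k - 1 + n_win * tau].reshape(n_win, tau)
    return windows @ weights.coeffs


def wcmfe(signal, tau: int, weights: WeightVector, params: FEParams,
          r_mode: str = "global") -> float:
    """Weighted composite multiscale fuzzy entropy at one scale.

    Averages :func:`~wcmfe.entropy.fuzzy_entropy` over the ``tau`` offset
    coarse-grained sequences. With ``r_mode="global"`` (the default and the
    dominant multiscale-entropy convention) the tolerance is resolved once as
    ``r * SD(signal)`` from the original (cropped) signal and shared by every
    scale and offset; ``r_mode="per_sequence"`` re-resolves it from each
    coarse-grained sequence.
    """
    x = _as_sequence(signal, "signal")
    if r_mode not in ("global", "per_sequence"):
        raise ValueError(f"r_mode must be 'global' or 'per_sequence', got {r_mode!r}")
    if np.ptp(x) == 0.0:
        return 0.0  # every coarse-grained sequence is constant
    if r_mode == "global" and params.r_abs is None:
        params = params.resolved(x)
    total = 0.0
    for k in range(1, tau + 1):
        y = coarse_grain(x, tau, k, weights)
        try:
            total += fuzzy_entropy(y, params)
        except ValueError as exc:
            raise type(exc)(f"at scale tau={tau}, offset k={k}: {exc}") from exc
    return total / tau


def cmfe(signal, tau: int, params: FEParams, r_mode: str = "global") -> float:
    """Composite multiscale fuzzy entropy (plain-mean coarse-graining)."""
    return wcmfe(signal, tau, uniform_weights(tau), params, r_mode=r_mode)


def filter_frequency_response(weights: WeightVector, n_freqs: int = 512):
    """Magnitude response of the FIR filter whose taps are the weights.

    Returns ``(freqs, magnitudes)`` where ``freqs`` is a uniform grid of
    normalised frequency omega/pi over [0, 1] inclusive. The DC gain equals
    the coefficient sum, i.e. 1.
    """
    if not (isinstance(n_freqs, (int, np.integer)) and n_freqs >= 2):
        raise ValueError(f"n_freqs must be an integer >= 2, got {n_freqs}")
    w = np.linspace(0.0, np.pi, int(n_freqs))
    _, resp = freqz(weights.coeffs, worN=w)
    return w / np.pi, np.abs(resp)
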
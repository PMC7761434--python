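"""Fuzzy-entropy kernel.

Fuzzy entropy (FE) measures the regularity of a time series. Template vectors
of length ``m`` are drawn from the series and centered on their own window
mean; the similarity of a pair of templates is a smooth exponential membership
``exp(-d**n / r)`` of their Chebyshev distance ``d``, instead of the hard
threshold used by sample entropy. FE is the negative log ratio of the mean
pairwise similarity at embedding dimensions ``m + 1`` and ``m``:

    FE(m, n, r) = -ln( phi(m+1) / phi(m) )

with ``phi(m)`` the mean of ``exp(-d(i,j)**n / r_abs)`` over all ordered pairs
``i != j`` of centered templates. A perfectly regular (constant) series has
FE = 0; white noise has high FE.

Conventions fixed here and used throughout the package:

* exactly ``N - m`` template vectors are used at dimension ``m`` *and* at
  ``m + 1`` (the standard sample-entropy convention keeping pair counts
  comparable between the two dimensions);
* the tolerance ``r`` is a multiplier of a reference standard deviation
  (population SD, i.e. dividing by N); the resolved absolute tolerance is
  stored as :attr:`FEParams.r_abs`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "FEParams",
    "DegenerateToleranceError",
    "population_sd",
    "embed_centered",
    "chebyshev_distance",
    "phi",
    "fuzzy_entropy",
]


class DegenerateToleranceError(ValueError):
    """Raised when the similarity tolerance would resolve to zero.

    This happens when ``r`` is relative and the reference signal is constant
    (zero standard deviation) while a non-trivial entropy is requested.
    """


def population_sd(x) -> float:
    """Population standard deviation (normalised by N, not N-1)."""
    return float(np.std(np.asarray(x, dtype=float)))


def _as_sequence(x, name: str = "seq") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class FEParams:
    """Fuzzy-entropy parameters.

    Parameters
    ----------
    m : int
        Embedding dimension (template length). Default 2.
    n : float
        Boundary gradient of the fuzzy membership function. Default 2.
    r : float
        Boundary width as a multiplier of a reference standard deviation.
        Default 0.15.
    r_abs : float or None
        The resolved absolute tolerance actually used in the similarity
        kernel. ``None`` means "not yet resolved"; call :meth:`resolved`
        with a reference signal, or let :func:`fuzzy_entropy` resolve it
        against the analysed sequence itself.
    """

    m: int = 2
    n: float = 2.0
    r: float = 0.15
    r_abs: float | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise ValueError(f"embedding dimension m must be a positive integer, got {self.m}")
        if not self.n > 0:
            raise ValueError(f"boundary gradient n must be > 0, got {self.n}")
        if not self.r > 0:
            raise ValueError(f"boundary width r must be > 0, got {self.r}")
        if self.r_abs is not None and not self.r_abs > 0:
            raise ValueError(f"resolved tolerance r_abs must be > 0, got {self.r_abs}")

    def resolved(self, reference) -> "FEParams":
        """Return a copy with ``r_abs = r * SD(reference)`` (population SD)."""
        sd = population_sd(reference)
        if sd == 0.0:
            raise DegenerateToleranceError(
                "reference signal is constant: r_abs = r * SD would be 0"
            )
        return replace(self, r_abs=self.r * sd)


def embed_centered(seq, m: int) -> np.ndarray:
    """All centered template vectors of length ``m``.

    Returns an ``(N - m + 1, m)`` array; row ``i`` is
    ``seq[i:i+m] - mean(seq[i:i+m])``, so every row sums to zero up to
    floating tolerance.
    """
    x = _as_sequence(seq)
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise ValueError(f"m must be a positive integer, got {m}")
    if x.size < m + 1:
        raise ValueError(
            f"sequence of length {x.size} too short for embedding dimension m={m}; "
            f"minimum length is {m + 1}"
        )
    windows = sliding_window_view(x, m)
    return windows - windows.mean(axis=1, keepdims=True)


def chebyshev_distance(u, v) -> float:
    """Chebyshev (max-coordinate) distance between two equal-length vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"vector length mismatch: {u.shape} vs {v.shape}")
    return float(np.max(np.abs(u - v)))


def _phi_from_templates(templates: np.ndarray, n: float, r_abs: float) -> float:
    """Mean fuzzy similarity over ordered pairs i != j of template rows."""
    K = templates.shape[0]
    # K x K Chebyshev distance matrix via broadcasting; K is at most a few
    # hundred in this package's workloads.
    diff = np.abs(templates[:, None, :] - templates[None, :, :])
    D = diff.max(axis=2)
    # d**n / r_abs may overflow to inf for tiny tolerances; exp(-inf) = 0 is
    # the intended limit, so the overflow itself is benign
    with np.errstate(over="ignore"):
        E = np.exp(-(D ** n) / r_abs)
    # diagonal entries are exp(0) = 1 each; subtract them out.
    return float((E.sum() - K) / (K * (K - 1)))


def phi(seq, m: int, params: FEParams) -> float:
    """Mean fuzzy similarity ``phi(m)`` over ordered template pairs.

    Uses exactly ``N - m`` template vectors (the last of the ``N - m + 1``
    windows is dropped) so that pair counts match between dimensions ``m``
    and ``m + 1``. Requires ``params.r_abs`` to be resolved.
    """
    x = _as_sequence(seq)
    if params.r_abs is None:
        raise ValueError("params.r_abs is unresolved; call FEParams.resolved() first")
    K = x.size - m
    if K < 2:
        raise ValueError(
            f"sequence of length {x.size} yields {K} template vectors for m={m}; "
            f"need at least 2 (minimum length {m + 2})"
        )
    templates = embed_centered(x, m)[:K]
    return _phi_from_templates(templates, params.n, params.r_abs)


def fuzzy_entropy(seq, params: FEParams) -> float:
    """Fuzzy entropy ``-ln(phi(m+1) / phi(m))`` of a single sequence.

    If ``params.r_abs`` is ``None`` the tolerance is resolved against the
    analysed sequence itself (``r * SD(seq)``). A constant sequence returns
    exactly 0.0 (all distances vanish for any positive tolerance).
    """
    x = _as_sequence(seq)
    m = params.m
    if x.size < m + 3:
        raise ValueError(
            f"sequence of length {x.size} too short for fuzzy entropy with m={m}; "
            f"minimum length is {m + 3}"
        )
    if np.ptp(x) == 0.0:
        return 0.0
    p = params if params.r_abs is not None else params.resolved(x)
    phi_m = phi(x, m, p)
    phi_m1 = phi(x, m + 1, p)
    if phi_m1 == 0.0:
        warnings.warn(
            "phi(m+1) underflowed to 0; returning +inf fuzzy entropy",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.inf
    return -math.log(phi_m1 / phi_m)
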
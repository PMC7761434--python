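"""Independent brute-force reference implementations.

Plain-Python loop versions of the entropy pipeline, written directly from the
defining formulas with no vectorisation and no shared code with the package.
They are deliberately slow and serve only as oracles in tests.
"""

import math


def embed_centered_loops(x, m):
    out = []
    for i in range(len(x) - m + 1):
        window = [x[i + l] for l in range(m)]
        mean = sum(window) / m
        out.append([v - mean for v in window])
    return out


def chebyshev_loops(u, v):
    return max(abs(a - b) for a, b in zip(u, v))


def phi_loops(x, m, n, r_abs):
    """Mean over ordered pairs i != j of exp(-d(i,j)^n / r_abs), K = N - m."""
    K = len(x) - m
    vecs = embed_centered_loops(x, m)[:K]
    total = 0.0
    for i in range(K):
        inner = 0.0
        for j in range(K):
            if j != i:
                d = chebyshev_loops(vecs[i], vecs[j])
                inner += math.exp(-(d ** n) / r_abs)
        total += inner / (K - 1)
    return total / K


def population_sd_loops(x):
    mean = sum(x) / len(x)
    return math.sqrt(sum((v - mean) ** 2 for v in x) / len(x))


def fuzzy_entropy_loops(x, m, n, r_abs=None, r=0.15):
    if r_abs is None:
        r_abs = r * population_sd_loops(x)
    return -math.log(phi_loops(x, m + 1, n, r_abs) / phi_loops(x, m, n, r_abs))


def coarse_grain_loops(x, tau, k, coeffs):
    """k-th offset weighted coarse-graining; windows past the end dropped."""
    H = len(x)
    n_win = (H - (k - 1)) // tau
    out = []
    for j in range(1, n_win + 1):
        start = (j - 1) * tau + k - 1  # 0-based window start
        out.append(sum(coeffs[p] * x[start + p] for p in range(tau)))
    return out


def wcmfe_loops(x, tau, coeffs, m, n, r=0.15):
    """Tolerance resolved once from the original signal (global convention)."""
    r_abs = r * population_sd_loops(x)
    total = 0.0
    for k in range(1, tau + 1):
        y = coarse_grain_loops(x, tau, k, coeffs)
        total += fuzzy_entropy_loops(y, m, n, r_abs=r_abs)
    return total / tau
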
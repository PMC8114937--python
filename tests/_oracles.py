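"""Independent oracles used to validate the implementation.

Each oracle is deliberately naive — exhaustive enumeration, closed-form
normal equations, or direct Monte-Carlo simulation — and shares no code
path with the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def nnls_by_enumeration(A: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve min ||A F - R|| s.t. F >= 0 by brute force over active sets.

    For every support S of the 4 unknowns, solve the unconstrained least
    squares restricted to S, keep feasible candidates (F_S >= 0), and
    return the best objective.  2^4 = 16 supports, so this is exact.
    """
    m, n = A.shape
    best_F = np.zeros(n)
    best_obj = float(np.linalg.norm(R))
    for k in range(1, n + 1):
        for support in itertools.combinations(range(n), k):
            S = list(support)
            F_S, *_ = np.linalg.lstsq(A[:, S], R, rcond=None)
            if np.any(F_S < -1e-10):
                continue
            F = np.zeros(n)
            F[S] = np.clip(F_S, 0.0, None)
            obj = float(np.linalg.norm(A @ F - R))
            if obj < best_obj - 1e-15:
                best_obj = obj
                best_F = F
    return best_F, best_obj


def ols_slope_closed_form(x, y) -> tuple[float, float]:
    """Slope and its standard error from the textbook normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    s2 = np.sum(resid**2) / (n - 2)
    return float(slope), float(np.sqrt(s2 / sxx))


def mc_pairing_fractions(f: float, n_pairs: int, rng: np.random.Generator):
    """Monte-Carlo random-pairing isotopologue fractions.

    Returns ((p29_d, p30_d), (p29_a, p30_a), se) where the first pair are
    the fractions of denitrification N2 that are mass 29 and 30 (both atoms
    drawn from the nitrite pool at atom fraction f), the second the same
    for anammox N2 (one nitrite atom, one unlabelled ammonium atom), and
    ``se`` the binomial standard error scale 1/sqrt(n_pairs).
    """
    a = rng.random(n_pairs) < f
    b = rng.random(n_pairs) < f
    n30_d = np.sum(a & b)
    n29_d = np.sum(a ^ b)
    c = rng.random(n_pairs) < f
    n29_a = np.sum(c)
    return (
        (n29_d / n_pairs, n30_d / n_pairs),
        (n29_a / n_pairs, 0.0),
        1.0 / np.sqrt(n_pairs),
    )
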
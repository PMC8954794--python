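"""Independent oracles used only by the test suite.

Each oracle solves the same problem as a library routine by a different
method: quaternion (Horn) absolute orientation for Kabsch superposition,
scalar root-finding on the mass-action equation for the closed-form binding
quadratic, and a grid search with analytic amplitude for the exponential
rate fit.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq


def quaternion_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rotation by Horn's quaternion eigenvalue method."""
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)
    S = P.T @ Q
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    eigvals, eigvecs = np.linalg.eigh(N)
    w, x, y, z = eigvecs[:, np.argmax(eigvals)]
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def mass_action_complex(x_total: float, m_total: float, kd: float,
                        n: float = 1.0) -> float:
    """[PX] by root-finding on (n*M - c)(X - c) = Kd * c."""
    upper = min(n * m_total, x_total)
    if upper == 0:
        return 0.0

    def g(c):
        return (n * m_total - c) * (x_total - c) - kd * c

    return brentq(g, 0.0, upper, xtol=1e-18, rtol=1e-15)


def grid_search_rate(delays: np.ndarray, heights: np.ndarray,
                     r_lo: float = 1e-3, r_hi: float = 50.0,
                     n_grid: int = 10_000) -> float:
    """Exponential rate by dense grid search; I0 solved analytically per R."""
    t = np.asarray(delays, float)
    y = np.asarray(heights, float)
    grid = np.linspace(r_lo, r_hi, n_grid)
    best_r, best_sse = grid[0], np.inf
    for r in grid:
        e = np.exp(-r * t)
        i0 = float(y @ e) / float(e @ e)
        sse = float(np.sum((y - i0 * e) ** 2))
        if sse < best_sse:
            best_sse, best_r = sse, r
    return best_r


def saturation_fraction_quadratic(ratio: float, protein: float, kd: float) -> float:
    """Bound-protein fraction via the explicit quadratic root."""
    ligand = ratio * protein
    b = protein + ligand + kd
    px = 0.5 * (b - np.sqrt(b * b - 4.0 * protein * ligand))
    return px / protein
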
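"""Independent oracles used by the test suite.

Everything here is deliberately naive: explicit Runge–Kutta integration of the
photophysical rate equations, an O(n²) pure-Python double loop for Ripley's
K̂, and Monte-Carlo arc sampling for the edge-correction weight. These paths
share no code with the production implementations they check (the brute-force
K̂ reuses only the final fsum reduction convention so exact equality is
well-defined).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp

from palm_mcquant.spatial import PointPattern, haase_weights


def ode_gfp(t: np.ndarray, k_b: float) -> np.ndarray:
    sol = solve_ivp(
        lambda _, y: [-k_b * y[0]], (t[0], t[-1]), [1.0], t_eval=t,
        rtol=1e-11, atol=1e-13, method="RK45",
    )
    return sol.y[0]


def ode_tdeos(t: np.ndarray, k_ps: float, k_b: float, g0: float, r0: float) -> np.ndarray:
    """Numerical G -> R -> B integration; returns un-normalized R(t)."""
    sol = solve_ivp(
        lambda _, y: [-k_ps * y[0], k_ps * y[0] - k_b * y[1]],
        (t[0], t[-1]), [g0, r0], t_eval=t, rtol=1e-11, atol=1e-13,
    )
    return sol.y[1]


def ode_dronpa(
    t: np.ndarray, k_pa: float, k_pda: float, k_b: float, i0: float, a0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Numerical I <-> A -> B integration; returns un-normalized (I, A)."""
    sol = solve_ivp(
        lambda _, y: [
            -k_pa * y[0] + k_pda * y[1],
            k_pa * y[0] - (k_pda + k_b) * y[1],
        ],
        (t[0], t[-1]), [i0, a0], t_eval=t, rtol=1e-11, atol=1e-13,
    )
    return sol.y[0], sol.y[1]


def ripley_k_bruteforce(pattern: PointPattern, r_grid: np.ndarray) -> np.ndarray:
    """Direct O(n²) double-loop Ripley estimator, no spatial indexing.

    Every ordered pair (i, j), i ≠ j, contributes k(i, j)/w_ij with the
    edge weight centered on point i; the per-radius reduction is math.fsum
    of the individual contributions, i.e. the correctly rounded sum."""
    n = pattern.n
    area = pattern.area
    pts = pattern.points
    dists: list[float] = []
    invw: list[float] = []
    r_cap = float(np.max(r_grid))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dij = math.hypot(pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1])
            if dij < r_cap:
                w = haase_weights(pts[i: i + 1], np.array([dij]), pattern.window)[0]
                dists.append(dij)
                invw.append(1.0 / w)
    out = np.empty(len(r_grid))
    for ri, r in enumerate(r_grid):
        out[ri] = area / n**2 * math.fsum(
            c for dij, c in zip(dists, invw) if dij < r
        )
    return out


def circle_fraction_inside_sampled(
    point: np.ndarray,
    radius: float,
    window: tuple[float, float, float, float],
    n_samples: int = 40000,
) -> float:
    """Fraction of a circle inside a rectangle by dense arc sampling."""
    theta = np.linspace(0.0, 2.0 * math.pi, n_samples, endpoint=False)
    x = point[0] + radius * np.cos(theta)
    y = point[1] + radius * np.sin(theta)
    x0, y0, x1, y1 = window
    return float(np.mean((x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)))


def polygon_area_perimeter(vertices: np.ndarray) -> tuple[float, float]:
    """Shoelace area and edge-length sum of a closed polygon."""
    x, y = vertices[:, 0], vertices[:, 1]
    area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    per = float(np.linalg.norm(np.roll(vertices, -1, axis=0) - vertices, axis=1).sum())
    return area, per
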
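"""Shared independent numerical oracles for the test suite.

These deliberately avoid the package's own solvers: a fixed-step classical
Runge-Kutta integrator and a brute-force polytope vertex enumerator.
"""

import itertools

import numpy as np


def rk4_reference(rhs, y0, t_end, dt):
    """Fixed-step 4th-order Runge-Kutta integration (no scipy)."""
    steps = int(round(t_end / dt))
    y = np.array(y0, dtype=float)
    t = 0.0
    for _ in range(steps):
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return y


def enumerate_vertices(matrix, bounds):
    """All vertices of {v : S v = 0, lo <= v <= hi} by active-set enumeration."""
    S = matrix.matrix.astype(float)
    m = np.linalg.matrix_rank(S) if S.size else 0
    n = len(matrix.cols)
    lo = np.array([bounds.get(r, (0.0, np.inf))[0] for r in matrix.cols])
    hi = np.array([bounds.get(r, (0.0, np.inf))[1] for r in matrix.cols])
    vertices = []
    for free in itertools.combinations(range(n), n - m):
        for choice in itertools.product(*[(lo[j], hi[j]) for j in free]):
            v = np.full(n, np.nan)
            for j, val in zip(free, choice):
                v[j] = val
            other = [j for j in range(n) if j not in free]
            if other:
                A = S[:, other]
                b = -S[:, list(free)] @ np.array(choice)
                sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
                if rank < len(other) or np.max(np.abs(A @ sol - b)) > 1e-9:
                    continue
                for j, val in zip(other, sol):
                    v[j] = val
            if np.all(v >= lo - 1e-9) and np.all(v <= hi + 1e-9):
                vertices.append(v)
    return vertices
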
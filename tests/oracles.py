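"""Independent brute-force oracles for small constrained problems.

These deliberately avoid the solver paths they check: the LP oracle
enumerates polytope vertices, the constrained-least-squares oracle
enumerates active sets.  Both only work for small problems and bounded
feasible regions.
"""

from itertools import combinations

import numpy as np
from scipy.linalg import null_space


def _reduce(E, f):
    """Affine parameterization x = x0 + Z q of {x : Ex = f}."""
    E = np.atleast_2d(np.asarray(E, float))
    f = np.asarray(f, float).ravel()
    if E.size == 0:
        n = E.shape[1]
        return np.zeros(n), np.eye(n)
    x0, *_ = np.linalg.lstsq(E, f, rcond=None)
    if np.linalg.norm(E @ x0 - f) > 1e-8:
        raise ValueError("equalities inconsistent")
    Z = null_space(E, rcond=1e-10)
    return x0, Z


def enumerate_vertices(E, f, G, h, tol=1e-9):
    """All vertices of {x : Ex=f, Gx>=h} by active-set enumeration."""
    x0, Z = _reduce(E, f)
    k = Z.shape[1]
    G = np.atleast_2d(np.asarray(G, float))
    h = np.asarray(h, float).ravel()
    if k == 0:
        if G.size == 0 or np.all(G @ x0 - h >= -tol):
            return [x0]
        return []
    Gr = G @ Z
    hr = h - G @ x0
    verts = []
    for rows in combinations(range(Gr.shape[0]), k):
        M = Gr[list(rows)]
        if np.linalg.matrix_rank(M, tol=1e-10) < k:
            continue
        q = np.linalg.solve(M, hr[list(rows)])
        if np.all(Gr @ q - hr >= -tol):
            x = x0 + Z @ q
            if not any(np.allclose(x, v, atol=1e-8) for v in verts):
                verts.append(x)
    return verts


def lp_oracle(E, f, G, h, c, sense="maximize"):
    """LP optimum over a bounded polytope by vertex enumeration."""
    verts = enumerate_vertices(E, f, G, h)
    if not verts:
        raise ValueError("infeasible")
    vals = [float(np.dot(c, v)) for v in verts]
    return max(vals) if sense == "maximize" else min(vals)


def lsei_oracle(E, f, G, h, A, b, tol=1e-9):
    """Constrained least squares by enumeration over inequality active sets.

    Returns (best objective, best x).  Assumes the candidate produced for
    the true active set is the actual constrained minimizer, which holds for
    generic (non-degenerate) data.
    """
    A = np.atleast_2d(np.asarray(A, float))
    b = np.asarray(b, float).ravel()
    G = np.atleast_2d(np.asarray(G, float))
    h = np.asarray(h, float).ravel()
    E = np.atleast_2d(np.asarray(E, float))
    f = np.asarray(f, float).ravel()
    m = G.shape[0] if G.size else 0
    best = (np.inf, None)
    for size in range(m + 1):
        for rows in combinations(range(m), size):
            if rows:
                Es = np.vstack([E, G[list(rows)]]) if E.size else G[list(rows)]
                fs = np.concatenate([f, h[list(rows)]])
            else:
                Es, fs = E, f
            try:
                x0, Z = _reduce(Es, fs)
            except ValueError:
                continue
            if Z.shape[1]:
                q, *_ = np.linalg.lstsq(A @ Z, b - A @ x0, rcond=None)
                x = x0 + Z @ q
            else:
                x = x0
            if G.size and np.any(G @ x - h < -tol):
                continue
            val = float(np.sum((A @ x - b) ** 2))
            if val < best[0] - 1e-12:
                best = (val, x)
    if best[1] is None:
        raise ValueError("infeasible")
    return best


def random_bounded_lim(rng, n_reactions=None):
    """A random feasible, bounded LP instance in linear-inverse-model form.

    All fluxes are non-negative, one random flux is fixed to 1 by an
    equality row, and a total-flux cap keeps the polytope bounded.  Returns
    (E, f, G, h) with the cap as the last inequality row.
    """
    n = n_reactions or int(rng.integers(4, 9))
    m = max(1, n - 3)
    while True:
        S = rng.integers(-2, 3, size=(m, n)).astype(float)
        if np.linalg.matrix_rank(S) < m:
            continue
        j = int(rng.integers(n))
        fix = np.zeros((1, n))
        fix[0, j] = 1.0
        E = np.vstack([S, fix])
        f = np.zeros(m + 1)
        f[-1] = 1.0
        G = np.vstack([np.eye(n), -np.ones((1, n))])
        h = np.zeros(n + 1)
        h[-1] = -10.0
        # feasibility screen via vertex enumeration
        try:
            if enumerate_vertices(E, f, G, h):
                return E, f, G, h
        except ValueError:
            continue
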
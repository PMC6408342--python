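"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the motif oracle
classifies triads by exhaustive permutation against hand-written
representatives; the GLMM oracle evaluates the marginal likelihood by
numerical integration (tensor Gauss–Hermite) and maximizes it by grid
search; the fixed-marginal enumerator lists a matrix class by brute force.
"""

from __future__ import annotations

from itertools import combinations, permutations, product

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

# Representatives of the 13 connected triad classes in the standard
# (Davis–Leinhardt) taxonomy, nodes 0, 1, 2; code xyz = numbers of mutual,
# asymmetric and null dyads, suffix D/U/C the orientation.
TRIAD_REPRESENTATIVES = {
    "021D": [(1, 0), (1, 2)],
    "021U": [(0, 1), (2, 1)],
    "021C": [(0, 1), (1, 2)],
    "111D": [(0, 2), (1, 2), (2, 0)],
    "111U": [(0, 2), (2, 0), (2, 1)],
    "030T": [(0, 1), (0, 2), (2, 1)],
    "030C": [(0, 2), (1, 0), (2, 1)],
    "201": [(0, 1), (0, 2), (1, 0), (2, 0)],
    "120D": [(0, 2), (1, 0), (1, 2), (2, 0)],
    "120U": [(0, 1), (0, 2), (2, 0), (2, 1)],
    "120C": [(0, 1), (0, 2), (1, 2), (2, 0)],
    "210": [(0, 1), (0, 2), (1, 2), (2, 0), (2, 1)],
    "300": [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)],
}


def _canonical_code(sub: np.ndarray) -> tuple:
    """Lexicographically smallest off-diagonal bit pattern over node relabellings."""
    best = None
    for pi in permutations(range(3)):
        bits = tuple(
            int(sub[pi[i], pi[j]]) for i in range(3) for j in range(3) if i != j
        )
        if best is None or bits < best:
            best = bits
    return best


def _rep_codes() -> dict[tuple, str]:
    codes = {}
    for name, edges in TRIAD_REPRESENTATIVES.items():
        M = np.zeros((3, 3), dtype=int)
        for i, j in edges:
            M[i, j] = 1
        codes[_canonical_code(M)] = name
    assert len(codes) == 13
    return codes


_CODE_TO_NAME = _rep_codes()


def motif_census_oracle(adjacency: np.ndarray) -> dict[str, int]:
    """Count connected triads by exhaustive permutation isomorphism."""
    A = np.asarray(adjacency, dtype=int).copy()
    np.fill_diagonal(A, 0)
    n = A.shape[0]
    counts = {name: 0 for name in TRIAD_REPRESENTATIVES}
    for triple in combinations(range(n), 3):
        sub = A[np.ix_(triple, triple)]
        code = _canonical_code(sub)
        name = _CODE_TO_NAME.get(code)
        if name is not None:  # codes of 003/012/102 (disconnected) are absent
            counts[name] += 1
    return counts


# ---------------------------------------------------------------------------
# GLMM marginal likelihood by numerical integration (m small)


def glmm_marginal_loglik(
    y: np.ndarray, V: np.ndarray, alpha: float, sigma: float,
    alpha_penalty_sd: float = 10.0, n_nodes: int = 20,
) -> float:
    """log ∫ N(b; 0, σ²V) Π_j Bernoulli(y_j | logit⁻¹(α+b_j)) db via tensor
    Gauss–Hermite, plus the same weak Gaussian α-penalty the fit uses."""
    y = np.asarray(y, dtype=float)
    m = y.size
    pen = -0.5 * (alpha / alpha_penalty_sd) ** 2
    if sigma == 0.0:
        p = expit(alpha)
        return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))) + pen
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    L = np.linalg.cholesky(V + 1e-10 * np.eye(m))
    grids = np.meshgrid(*([nodes] * m), indexing="ij")
    Z = np.stack([g.ravel() for g in grids])  # m × n_nodes^m
    Wgrids = np.meshgrid(*([weights] * m), indexing="ij")
    W = np.prod(np.stack([w.ravel() for w in Wgrids]), axis=0)
    B = sigma * (L @ Z)
    eta = alpha + B
    logf = np.sum(
        y[:, None] * eta - np.logaddexp(0.0, eta), axis=0
    )
    val = np.sum(W * np.exp(logf)) / (2 * np.pi) ** (m / 2)
    return float(np.log(max(val, 1e-300))) + pen


def glmm_fit_oracle(
    y: np.ndarray, V: np.ndarray,
    alpha_grid=None, sigma_grid=None,
) -> tuple[float, float, np.ndarray]:
    """Grid-search maximizer of the integrated likelihood; returns
    (α*, σ*, p*) with p* = logit⁻¹(α* + b-mode at the optimum)."""
    y = np.asarray(y, dtype=float)
    m = y.size
    if alpha_grid is None:
        alpha_grid = np.linspace(-4.0, 4.0, 61)
    if sigma_grid is None:
        sigma_grid = np.concatenate([[0.0], np.geomspace(0.05, 10.0, 40)])
    best = (-np.inf, 0.0, 0.0)
    for sigma in sigma_grid:
        for alpha in alpha_grid:
            ll = glmm_marginal_loglik(y, V, alpha, sigma)
            if ll > best[0]:
                best = (ll, alpha, sigma)
    _, alpha, sigma = best
    if sigma == 0.0:
        b = np.zeros(m)
    else:
        Kinv = np.linalg.inv(sigma**2 * V + 1e-10 * np.eye(m))

        def negpost(b):
            eta = alpha + b
            return float(
                -np.sum(y * eta - np.logaddexp(0.0, eta)) + 0.5 * b @ Kinv @ b
            )

        b = minimize(negpost, np.zeros(m), method="BFGS").x
    return alpha, sigma, expit(alpha + b)


# ---------------------------------------------------------------------------
# Fixed-marginal matrix class enumeration (small matrices)


def enumerate_fixed_marginal_class(values: np.ndarray) -> list[bytes]:
    """All binary matrices sharing the row and column sums of ``values``,
    as sorted byte strings (brute force over row compositions)."""
    A = np.asarray(values, dtype=int)
    n, m = A.shape
    row_sums = A.sum(axis=1)
    col_sums = tuple(A.sum(axis=0))
    row_options = []
    for r in row_sums:
        opts = []
        for cols in combinations(range(m), int(r)):
            row = np.zeros(m, dtype=np.int8)
            row[list(cols)] = 1
            opts.append(row)
        row_options.append(opts)
    members = []
    for rows in product(*row_options):
        M = np.vstack(rows)
        if tuple(M.sum(axis=0)) == col_sums:
            members.append(M.tobytes())
    return sorted(members)
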
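"""Fixed-fixed swap randomization: uninformed, informed, misinformed.

All three null models are Markov-chain swap randomizations that preserve the
row and column marginals of a bipartite incidence matrix exactly — or, for a
directed food web, every species' numbers of prey and predators plus the
counts of single, double and cannibal links.  They differ only in the swap
acceptance rule:

* **uninformed** — every valid proposal is accepted (the classic fixed-fixed
  swap model);
* **informed** — a valid proposal creating links (i, m) and (l, j) is
  accepted with probability ``p_im · p_lj``, where p is the link-probability
  matrix estimated once from the original matrix and a correlation structure;
* **misinformed** — as informed, but each replicate re-estimates p from a
  correlation matrix whose row/column identities were symmetrically permuted
  (a control for overfitting: "wrong" structure should behave like no
  structure).

The chain stops after ``2 × (number of 1s)`` accepted swaps (with a
``100 × (number of 1s)`` trial safety cap), the standard recommendation for
mixing of the swap algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .correlation import CorrelationMatrix, permute_correlation
from .incidence import FoodWeb, IncidenceMatrix, classify_links
from .linkprob import ProbabilityMatrix, estimate_probability_matrix

__all__ = [
    "SwapBudget",
    "NullEnsemble",
    "default_swap_budget",
    "randomize_bipartite",
    "randomize_foodweb",
    "build_ensemble",
    "BipartiteSwapChain",
    "FoodWebSwapChain",
]


@dataclass(frozen=True)
class SwapBudget:
    target_accepted: int
    max_trials: int

    def __post_init__(self) -> None:
        if self.target_accepted < 1:
            raise ValueError("target_accepted must be ≥ 1")
        if self.max_trials < self.target_accepted:
            raise ValueError("max_trials must be ≥ target_accepted")


def default_swap_budget(A) -> SwapBudget:
    """Target 2× the number of 1s as accepted swaps; cap trials at 100×."""
    L = int(np.sum(A.values))
    if L < 2:
        warnings.warn(
            "matrix has fewer than 2 links; the swap chain cannot move",
            stacklevel=2,
        )
        L = max(L, 1)
    return SwapBudget(target_accepted=2 * L, max_trials=100 * L)


class _UniformBuffer:
    """Blocked uniform(0,1) draws: one Generator call per 8192 variates."""

    __slots__ = ("rng", "buf", "pos")

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.buf = rng.random(8192)
        self.pos = 0

    def next(self) -> float:
        if self.pos == 8192:
            self.buf = self.rng.random(8192)
            self.pos = 0
        u = self.buf[self.pos]
        self.pos += 1
        return u


class BipartiteSwapChain:
    """Swap chain preserving row and column sums of a bipartite matrix.

    Each :meth:`step` draws two distinct existing links i←j and l←m
    uniformly at random and proposes replacing them with i←m and l←j.  The
    proposal is valid only if i≠l, j≠m and both target cells are empty;
    rejected or invalid proposals leave the state unchanged (self-transition),
    which is what makes the uninformed chain's stationary distribution
    uniform over the fixed-marginal class.
    """

    def __init__(self, values: np.ndarray, P: np.ndarray | None, rng: np.random.Generator):
        self.A = np.array(values, dtype=np.int8)
        self._rows = [list(map(int, row)) for row in self.A]
        self.P = None if P is None else [list(map(float, row)) for row in P]
        self._u = _UniformBuffer(rng)
        rr, cc = np.nonzero(self.A)
        self.links: list[tuple[int, int]] = list(zip(rr.tolist(), cc.tolist()))

    def step(self) -> bool:
        """One swap trial; returns True if a swap was accepted and applied."""
        links = self.links
        L = len(links)
        if L < 2:
            return False
        u = self._u
        k1 = int(u.next() * L)
        k2 = int(u.next() * (L - 1))
        if k2 >= k1:
            k2 += 1
        i, j = links[k1]
        l, m = links[k2]
        rows = self._rows
        if i == l or j == m or rows[i][m] or rows[l][j]:
            return False
        if self.P is not None:
            if u.next() >= self.P[i][m] * self.P[l][j]:
                return False
        rows[i][j] = rows[l][m] = 0
        rows[i][m] = rows[l][j] = 1
        links[k1] = (i, m)
        links[k2] = (l, j)
        return True

    @property
    def values(self) -> np.ndarray:
        return np.array(self._rows, dtype=np.int8)


class FoodWebSwapChain:
    """Swap chain preserving degrees and link classes of a directed web.

    Single links swap only with single links; a proposal is additionally
    invalid if a created link would be a self-loop or the reciprocal of an
    existing link (either would change the class counts).  Double links swap
    as atomic unordered pairs against other double links, each oriented
    uniformly at random per trial; the informed acceptance multiplies the
    probabilities of all four created directed links.  Cannibal self-loops
    never move.  Each trial draws two distinct mobile units (singles and
    double-pairs pooled); drawing units of different classes is an invalid
    trial.
    """

    def __init__(self, values: np.ndarray, P: np.ndarray | None, rng: np.random.Generator):
        A = np.array(values, dtype=np.int8)
        self._rows = [list(map(int, row)) for row in A]
        self.P = None if P is None else [list(map(float, row)) for row in P]
        self._u = _UniformBuffer(rng)
        n = A.shape[0]
        self.singles: list[tuple[int, int]] = []
        self.doubles: list[tuple[int, int]] = []
        for i in range(n):
            for j in range(n):
                if i != j and A[i, j]:
                    if A[j, i]:
                        if i < j:
                            self.doubles.append((i, j))
                    else:
                        self.singles.append((i, j))

    @property
    def values(self) -> np.ndarray:
        return np.array(self._rows, dtype=np.int8)

    def step(self) -> bool:
        ns, nd = len(self.singles), len(self.doubles)
        total = ns + nd
        if total < 2:
            return False
        u = self._u
        u1 = int(u.next() * total)
        u2 = int(u.next() * (total - 1))
        if u2 >= u1:
            u2 += 1
        if u1 < ns and u2 < ns:
            return self._swap_singles(u1, u2)
        if u1 >= ns and u2 >= ns:
            return self._swap_doubles(u1 - ns, u2 - ns)
        return False  # mixed classes: invalid trial

    def _swap_singles(self, k1: int, k2: int) -> bool:
        rows, u = self._rows, self._u
        i, j = self.singles[k1]
        l, m = self.singles[k2]
        if i == l or j == m or i == m or l == j:
            return False
        if rows[i][m] or rows[l][j] or rows[m][i] or rows[j][l]:
            return False
        if self.P is not None:
            if u.next() >= self.P[i][m] * self.P[l][j]:
                return False
        rows[i][j] = rows[l][m] = 0
        rows[i][m] = rows[l][j] = 1
        self.singles[k1] = (i, m)
        self.singles[k2] = (l, j)
        return True

    def _swap_doubles(self, k1: int, k2: int) -> bool:
        rows, u = self._rows, self._u
        a, b = self.doubles[k1]
        c, d = self.doubles[k2]
        # orient each unordered pair uniformly: both rewirings reachable
        i, j = (a, b) if u.next() < 0.5 else (b, a)
        l, m = (c, d) if u.next() < 0.5 else (d, c)
        if i == m or l == j:
            return False
        if rows[i][m] or rows[m][i] or rows[l][j] or rows[j][l]:
            return False
        if self.P is not None:
            p = self.P[i][m] * self.P[m][i] * self.P[l][j] * self.P[j][l]
            if u.next() >= p:
                return False
        rows[i][j] = rows[j][i] = rows[l][m] = rows[m][l] = 0
        rows[i][m] = rows[m][i] = rows[l][j] = rows[j][l] = 1
        self.doubles[k1] = (min(i, m), max(i, m))
        self.doubles[k2] = (min(l, j), max(l, j))
        return True


def _run_chain(chain, budget: SwapBudget) -> tuple[int, int]:
    accepted = trials = 0
    while accepted < budget.target_accepted and trials < budget.max_trials:
        trials += 1
        if chain.step():
            accepted += 1
    if accepted < budget.target_accepted:
        warnings.warn(
            f"trial cap hit: {accepted}/{budget.target_accepted} accepted swaps "
            f"in {trials} trials; the matrix may not be fully randomized",
            stacklevel=3,
        )
    return accepted, trials


def _p_values(P: ProbabilityMatrix | np.ndarray | None) -> np.ndarray | None:
    if P is None:
        return None
    return P.values if isinstance(P, ProbabilityMatrix) else np.asarray(P, dtype=float)


def randomize_bipartite(
    A: IncidenceMatrix,
    P: ProbabilityMatrix | None,
    budget: SwapBudget | None = None,
    seed=None,
) -> IncidenceMatrix:
    """One randomized replicate of a bipartite matrix (row/col sums preserved)."""
    Pv = _p_values(P)
    if Pv is not None and Pv.shape != A.shape:
        raise ValueError("probability matrix shape does not match incidence matrix")
    if budget is None:
        budget = default_swap_budget(A)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chain = BipartiteSwapChain(A.values, Pv, rng)
    _run_chain(chain, budget)
    return IncidenceMatrix(chain.values, list(A.row_labels), list(A.col_labels))


def randomize_foodweb(
    W: FoodWeb,
    P: ProbabilityMatrix | None,
    budget: SwapBudget | None = None,
    seed=None,
) -> FoodWeb:
    """One randomized replicate of a food web (degrees and link classes preserved)."""
    Pv = _p_values(P)
    if Pv is not None and Pv.shape != W.values.shape:
        raise ValueError("probability matrix shape does not match food web")
    if budget is None:
        budget = default_swap_budget(W)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chain = FoodWebSwapChain(W.values, Pv, rng)
    _run_chain(chain, budget)
    return FoodWeb(chain.values, list(W.labels))


@dataclass
class NullEnsemble:
    """Randomized replicates with full provenance."""

    matrices: list
    model: str  # "uninformed" | "informed" | "misinformed"
    seeds: list[int]
    accepted_swaps: list[int]
    trials: list[int]
    probability_provenance: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.matrices)


def build_ensemble(
    source,
    model: str = "uninformed",
    V: CorrelationMatrix | None = None,
    perspective: str = "rows_given_Vcol",
    size: int = 200,
    budget: SwapBudget | None = None,
    seed=None,
) -> NullEnsemble:
    """Generate an ensemble of randomized matrices under one null model.

    ``source`` is an :class:`IncidenceMatrix` or :class:`FoodWeb`.  For the
    informed model the probability matrix is estimated once from (source, V)
    and reused for every replicate; for the misinformed model each replicate
    permutes V afresh, re-estimates the probabilities, and then randomizes.
    Per-replicate seeds are derived deterministically from ``seed``, so the
    same master seed reproduces the ensemble exactly.
    """
    if size < 2:
        raise ValueError("ensemble size must be ≥ 2")
    if model not in ("uninformed", "informed", "misinformed"):
        raise ValueError(f"unknown model {model!r}")
    if model in ("informed", "misinformed") and V is None:
        raise ValueError(f"{model} model requires a correlation matrix")

    is_web = isinstance(source, FoodWeb)
    A_src = source.as_incidence() if is_web else source
    if budget is None:
        budget = default_swap_budget(source)
    master = np.random.default_rng(seed)
    rep_seeds = [int(s) for s in master.integers(2**31, size=size)]
    perm_seeds = [int(s) for s in master.integers(2**31, size=size)]

    provenance: dict = {"model": model}
    P_fixed = None
    if model == "informed":
        P_fixed = estimate_probability_matrix(A_src, V, perspective)
        provenance.update(P_fixed.provenance)
        provenance["perspective"] = perspective
    elif model == "misinformed":
        provenance.update(dict(V.provenance))
        provenance["perspective"] = perspective
        provenance["permuted_per_replicate"] = True

    matrices, accepted, trials = [], [], []
    for r in range(size):
        if model == "misinformed":
            V_star = permute_correlation(V, np.random.default_rng(perm_seeds[r]))
            P_r = estimate_probability_matrix(A_src, V_star, perspective)
        else:
            P_r = P_fixed
        Pv = _p_values(P_r)
        rng = np.random.default_rng(rep_seeds[r])
        if is_web:
            chain = FoodWebSwapChain(source.values, Pv, rng)
        else:
            chain = BipartiteSwapChain(source.values, Pv, rng)
        acc, tri = _run_chain(chain, budget)
        if is_web:
            matrices.append(FoodWeb(chain.values, list(source.labels)))
        else:
            matrices.append(
                IncidenceMatrix(chain.values, list(source.row_labels), list(source.col_labels))
            )
        accepted.append(acc)
        trials.append(tri)

    ens = NullEnsemble(
        matrices=matrices,
        model=model,
        seeds=rep_seeds,
        accepted_swaps=accepted,
        trials=trials,
        probability_provenance=provenance,
    )
    _assert_conserved(source, ens)
    return ens


def _assert_conserved(source, ens: NullEnsemble) -> None:
    """Marginal conservation is asserted for every replicate, not sampled."""
    if isinstance(source, FoodWeb):
        ref = classify_links(source)
        for W in ens.matrices:
            s = classify_links(W)
            if (
                s.n_single != ref.n_single
                or s.n_double != ref.n_double
                or s.n_cannibal != ref.n_cannibal
                or s.in_degree != ref.in_degree
                or s.out_degree != ref.out_degree
            ):
                raise AssertionError("link-class/degree conservation violated")
    else:
        r0 = source.values.sum(axis=1)
        c0 = source.values.sum(axis=0)
        for M in ens.matrices:
            if not (
                np.array_equal(M.values.sum(axis=1), r0)
                and np.array_equal(M.values.sum(axis=0), c0)
            ):
                raise AssertionError("marginal conservation violated")
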
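"""Structural pattern metrics and z-score testing.

Two families of metrics are covered: the census of the 13 connected
three-node directed motif classes (food webs) and NODF nestedness (species
assemblages).  Observed values are compared with a null ensemble through the
z-score z = (k − ⟨{k*}⟩)/σ{k*}; |z| ≥ 1.96 — the two-decimal upper 2.5%
standard-normal quantile — marks significant over- (z > 0) or
under-representation (z < 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .incidence import FoodWeb, IncidenceMatrix
from .nullmodels import NullEnsemble

__all__ = [
    "MOTIF_CLASSES",
    "NAMED_MOTIFS",
    "MotifProfile",
    "MetricResult",
    "motif_census",
    "nodf",
    "zscore",
    "motif_zscore_profile",
    "nodf_zscore",
    "overlap_fraction",
    "Z_THRESHOLD",
]

#: Significance threshold on |z| (upper 2.5% standard-normal quantile, 2 dp).
Z_THRESHOLD = 1.96

#: The 13 connected triad classes in standard triad-census notation
#: (the disconnected classes 003, 012, 102 are excluded).
MOTIF_CLASSES = (
    "021D", "021U", "021C", "111D", "111U", "030T", "030C",
    "201", "120D", "120U", "120C", "210", "300",
)

#: The five named food-web motifs, under the convention that an edge i→j
#: means "consumer i eats resource j" (energy flows against the arrow).
NAMED_MOTIFS = {
    "exploitative_competition": "021D",  # one consumer, two resources
    "apparent_competition": "021U",      # two consumers, one resource
    "food_chain": "021C",                # a eats b eats c
    "omnivory": "030T",                  # chain plus top-to-bottom link
    "three_species_loop": "030C",        # directed 3-cycle
}


@dataclass
class MotifProfile:
    """Counts of connected 3-node induced subgraph classes (self-loops excluded)."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        missing = set(MOTIF_CLASSES) - set(self.counts)
        if missing:
            raise ValueError(f"missing motif classes: {sorted(missing)}")

    def named(self) -> dict[str, int]:
        return {name: self.counts[cls] for name, cls in NAMED_MOTIFS.items()}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_vector(self) -> np.ndarray:
        return np.array([self.counts[c] for c in MOTIF_CLASSES], dtype=int)


def motif_census(W: FoodWeb) -> MotifProfile:
    """Census of the 13 connected three-node motif classes.

    Every triple of species induces a subdigraph; after dropping self-loops
    (cannibalism is handled by the randomization constraints, not the motif
    catalogue), each connected induced triad is classified by isomorphism
    into the standard triad taxonomy.
    """
    if W.n_species < 3:
        raise ValueError("motif census needs at least 3 species")
    off = W.values.copy()
    np.fill_diagonal(off, 0)
    G = nx.DiGraph()
    G.add_nodes_from(range(W.n_species))
    G.add_edges_from(zip(*np.nonzero(off)))
    census = nx.triadic_census(G)
    return MotifProfile({c: int(census[c]) for c in MOTIF_CLASSES})


def nodf(A: IncidenceMatrix) -> float:
    """NODF nestedness (0–100) with the decreasing-fill convention.

    For each ordered pair of rows where the first has a strictly larger
    marginal total, the pair contributes the percentage of the poorer row's
    1s that also appear in the richer row; pairs with equal marginals (and
    pairs involving an empty row) contribute 0.  The same is computed over
    column pairs, and NODF is the mean over all n(n−1)/2 + m(m−1)/2 pairs.
    A perfectly nested matrix with all-distinct marginals scores 100; a
    checkerboard scores 0.
    """
    M = A.values.astype(int)

    def axis_sum(mat: np.ndarray) -> float:
        fills = mat.sum(axis=1)
        overlap = mat @ mat.T  # shared 1-columns for each row pair
        total = 0.0
        k = mat.shape[0]
        for a in range(k):
            for b in range(a + 1, k):
                fa, fb = fills[a], fills[b]
                if fa == fb or min(fa, fb) == 0:
                    continue
                poorer = b if fb < fa else a
                total += 100.0 * overlap[a, b] / fills[poorer]
        return total

    n, m = M.shape
    n_pairs = n * (n - 1) // 2 + m * (m - 1) // 2
    return (axis_sum(M) + axis_sum(M.T)) / n_pairs


@dataclass
class MetricResult:
    """Observed metric, its null distribution, and the z-score."""

    observed: float
    ensemble: np.ndarray
    z: float
    significant: bool

    @property
    def ensemble_mean(self) -> float:
        return float(np.mean(self.ensemble))

    @property
    def ensemble_sd(self) -> float:
        return float(np.std(self.ensemble, ddof=1))


def zscore(k_obs: float, ensemble_values) -> MetricResult:
    """z = (k − ⟨{k*}⟩)/σ{k*} with the sample (n−1) standard deviation.

    A degenerate ensemble (zero spread) yields z = NaN with a warning; such
    a pattern cannot be tested against that null.
    """
    vals = np.asarray(ensemble_values, dtype=float)
    if vals.size < 2:
        raise ValueError("ensemble must contain at least 2 values")
    sd = float(np.std(vals, ddof=1))
    if sd == 0.0:
        warnings.warn("ensemble has zero spread: z undefined", stacklevel=2)
        return MetricResult(float(k_obs), vals, float("nan"), False)
    z = (float(k_obs) - float(np.mean(vals))) / sd
    return MetricResult(float(k_obs), vals, z, abs(z) >= Z_THRESHOLD)


def motif_zscore_profile(W: FoodWeb, ensemble: NullEnsemble) -> dict[str, MetricResult]:
    """z-score per motif class of W against a null ensemble of food webs."""
    obs = motif_census(W)
    null_counts = {c: [] for c in MOTIF_CLASSES}
    for rep in ensemble.matrices:
        prof = motif_census(rep)
        for c in MOTIF_CLASSES:
            null_counts[c].append(prof.counts[c])
    results = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-class zero-spread is routine
        for c in MOTIF_CLASSES:
            results[c] = zscore(obs.counts[c], null_counts[c])
    return results


def nodf_zscore(A: IncidenceMatrix, ensemble: NullEnsemble) -> MetricResult:
    """NODF of A scored against a null ensemble."""
    return zscore(nodf(A), [nodf(rep) for rep in ensemble.matrices])


def overlap_fraction(A, A_star) -> float:
    """Fraction of A's links also present in A_star (same shape and marginals).

    Used to control whether differences between null models stem from how
    many links they leave in place rather than from the null hypotheses
    themselves.
    """
    x = A.values
    y = A_star.values
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if not (
        np.array_equal(x.sum(axis=1), y.sum(axis=1))
        and np.array_equal(x.sum(axis=0), y.sum(axis=0))
    ):
        raise ValueError("matrices do not share marginals")
    n_links = int(x.sum())
    if n_links == 0:
        raise ValueError("empty matrix has no overlap fraction")
    return float((x & y).sum()) / n_links
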
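"""Synthetic structured and random data for benchmarking the null models.

The generators produce data whose structure is (or is not) driven by a known
correlation matrix, so the three null models can be benchmarked against a
ground truth: a matched informed model should explain structure away
(small |z|), while uninformed and misinformed models should behave alike.

``synthetic_foodweb`` draws each consumer's diet from the link model's own
generative direction — b_i ~ Normal(0, β²V) over resources, intercept set so
the expected density hits a target, links Bernoulli(logistic(α_i + b_ij)) —
which makes fit/recovery exact in expectation.  β = 0 gives an
Erdős–Rényi-style control.  ``synthetic_assemblage`` builds sites × species
matrices with a geometric site-richness gradient and rank-weighted species
incidence (nested regime) or uniform incidence (random regime).
"""

from __future__ import annotations

import random as _stdlib_random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .correlation import (
    CorrelationMatrix,
    exponential_correlation,
    phylogenetic_correlation,
    regularize_correlation,
)
from .incidence import FoodWeb, IncidenceMatrix

__all__ = [
    "SyntheticWorld",
    "clade_tree",
    "simulate_tree_and_traits",
    "synthetic_foodweb",
    "synthetic_assemblage",
    "random_binary_matrix",
]


@dataclass
class SyntheticWorld:
    """A generated matrix together with the correlation structure that shaped it."""

    matrix: IncidenceMatrix | FoodWeb
    true_correlation: CorrelationMatrix | None
    params: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def simulate_tree_and_traits(n_tips: int, seed=None) -> tuple[dendropy.Tree, pd.Series]:
    """Pure-birth tree (rate 1) plus one Brownian-motion trait on it.

    The trait evolves with variance 1 per unit branch length, so across
    replicates its covariance between tips converges to the tree's shared
    branch lengths.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    tree_seed, trait_seed = ss.spawn(2)
    py_rng = _stdlib_random.Random(int(tree_seed.generate_state(1)[0]))
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=py_rng,
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1}"
    rng = np.random.default_rng(trait_seed)
    values: dict = {}
    for node in tree.preorder_node_iter():
        parent_val = values.get(node.parent_node, 0.0) if node.parent_node else 0.0
        length = node.edge.length or 0.0
        values[node] = parent_val + rng.normal(0.0, np.sqrt(length)) if length > 0 else parent_val
    traits = pd.Series(
        {leaf.taxon.label: values[leaf] for leaf in tree.leaf_node_iter()},
        name="trait",
    )
    return tree, traits


def _solve_intercept(b: np.ndarray, density: float) -> float:
    """α such that mean(logistic(α + b)) equals the target density."""

    def gap(alpha):
        return float(np.mean(expit(alpha + b))) - density

    return brentq(gap, -40.0, 40.0, xtol=1e-10)


def clade_tree(n_clades: int, tips_per_clade: int, stem: float = 0.85) -> str:
    """Newick for a balanced clade phylogeny of unit depth.

    Each clade is a star of ``tips_per_clade`` tips hanging off a stem of
    length ``stem``; tip branches have length 1−stem, so the phylogenetic
    correlation is ``stem`` within a clade and 0 between clades.  Useful for
    generating data with crisp, easily recoverable correlation structure.
    """
    if n_clades < 2 or tips_per_clade < 2:
        raise ValueError("need at least 2 clades of at least 2 tips")
    if not 0 < stem < 1:
        raise ValueError("stem length must be in (0, 1)")
    parts = []
    k = 0
    for _ in range(n_clades):
        tips = []
        for _ in range(tips_per_clade):
            k += 1
            tips.append(f"t{k}:{1 - stem}")
        parts.append("(" + ",".join(tips) + f"):{stem}")
    return "(" + ",".join(parts) + ");"


def synthetic_foodweb(
    n_species: int = 20,
    beta: float = 2.0,
    density: float = 0.2,
    seed=None,
    tree: dendropy.Tree | str | None = None,
    couple_consumers: bool = True,
) -> SyntheticWorld:
    """Phylogenetically structured food web drawn from the link model itself.

    A pure-birth phylogeny over the species (unless a tree or newick string
    is supplied) yields the correlation V.  The random-effect matrix B is
    drawn matrix-normally with V on both sides (``B = β·L Z Lᵀ`` with
    ``L Lᵀ = V``), so each consumer's effect vector is marginally
    b_i ~ Normal(0, β²V) over resources — the row model's own generative
    direction — while related consumers additionally share correlated diets,
    the way trophic interactions are phylogenetically conserved on the
    consumer side as well.  Row intercepts α_i are solved so each row's
    expected density matches ``density`` given the drawn b_i, and links are
    Bernoulli(logistic(α_i + b_ij)).  The diagonal is kept empty (no
    cannibals).  β = 0 reduces to an Erdős–Rényi-style control.

    ``couple_consumers=False`` draws consumer rows independently
    (``B = β·Z Lᵀ``); row-wise marginals are identical, but all
    cross-consumer structure disappears — conditional on the degree
    sequences such webs are indistinguishable from the uninformed null, so
    they are useful only as a second kind of structureless control.
    """
    if beta < 0:
        raise ValueError("effect strength β must be ≥ 0")
    if not 0 < density < 1:
        raise ValueError("density must be in (0, 1)")
    ss = np.random.SeedSequence(seed)
    tree_ss, draw_ss = ss.spawn(2)
    if tree is None:
        tree, _ = simulate_tree_and_traits(n_species, tree_ss)
    V = phylogenetic_correlation(tree)
    if V.dim != n_species:
        raise ValueError("supplied tree does not have n_species tips")
    labels = list(V.labels)
    rng = np.random.default_rng(draw_ss)
    chol = np.linalg.cholesky(regularize_correlation(V).values)
    Z = rng.standard_normal((n_species, n_species))
    if couple_consumers:
        B = beta * (chol @ Z @ chol.T)
    else:
        B = beta * (Z @ chol.T)
    A = np.zeros((n_species, n_species), dtype=np.int8)
    for i in range(n_species):
        b = B[i]
        alpha = _solve_intercept(b, density)
        p = expit(alpha + b)
        row = (rng.random(n_species) < p).astype(np.int8)
        row[i] = 0
        A[i] = row
    web = FoodWeb(A, labels)
    return SyntheticWorld(
        matrix=web,
        true_correlation=V,
        params={
            "generator": "synthetic_foodweb",
            "n_species": n_species,
            "beta": beta,
            "density": density,
            "couple_consumers": couple_consumers,
            "seed": seed,
        },
        extras={"tree": tree},
    )


def synthetic_assemblage(
    n_sites: int = 15,
    n_species: int = 30,
    gamma: float = 0.85,
    nestedness_strength: float = 5.0,
    base_richness_fraction: float = 0.7,
    seed=None,
) -> SyntheticWorld:
    """Sites × species assemblage with a geometric richness gradient.

    Site richness declines geometrically with site rank (ratio ``gamma``);
    the richest site holds ``base_richness_fraction`` of the species pool.
    Within each site, species are drawn without replacement with weight
    exp(−λ·rank/n_species) where λ = ``nestedness_strength``: large λ makes
    low-rank (widespread) species near-certain members of every site — a
    nested pattern — while λ = 0 gives uniform (random) incidence at the
    same richness gradient.  Site coordinates (uniform on a square) and
    areas (proportional to richness) are emitted for building exponential
    correlation structures over sites.
    """
    if n_sites < 2 or n_species < 2:
        raise ValueError("need at least 2 sites and 2 species")
    if not 0 < gamma <= 1:
        raise ValueError("richness ratio gamma must be in (0, 1]")
    if nestedness_strength < 0:
        raise ValueError("nestedness strength must be ≥ 0")
    rng = np.random.default_rng(seed)
    site_labels = [f"site{s + 1}" for s in range(n_sites)]
    sp_labels = [f"sp{j + 1}" for j in range(n_species)]
    richness = np.maximum(
        1,
        np.round(base_richness_fraction * n_species * gamma ** np.arange(n_sites)).astype(int),
    )
    richness = np.minimum(richness, n_species)
    weights = np.exp(-nestedness_strength * np.arange(n_species) / n_species)
    A = np.zeros((n_sites, n_species), dtype=np.int8)
    for s in range(n_sites):
        chosen = rng.choice(
            n_species, size=richness[s], replace=False, p=weights / weights.sum()
        )
        A[s, chosen] = 1
    coords = pd.DataFrame(
        rng.uniform(0.0, 100.0, size=(n_sites, 2)),
        index=site_labels,
        columns=["x", "y"],
    )
    areas = pd.Series(richness.astype(float), index=site_labels, name="area")
    V_space = exponential_correlation(coords)
    return SyntheticWorld(
        matrix=IncidenceMatrix(A, site_labels, sp_labels),
        true_correlation=V_space,
        params={
            "generator": "synthetic_assemblage",
            "n_sites": n_sites,
            "n_species": n_species,
            "gamma": gamma,
            "nestedness_strength": nestedness_strength,
            "base_richness_fraction": base_richness_fraction,
            "seed": seed,
        },
        extras={"coordinates": coords, "areas": areas, "richness": richness},
    )


def random_binary_matrix(n: int, m: int, fill: float, seed=None) -> IncidenceMatrix:
    """i.i.d. Bernoulli(fill) matrix for oracle and property tests."""
    if not 0 < fill < 1:
        raise ValueError("fill must be in (0, 1)")
    rng = np.random.default_rng(seed)
    values = (rng.random((n, m)) < fill).astype(np.int8)
    return IncidenceMatrix(
        values,
        [f"r{i + 1}" for i in range(n)],
        [f"c{j + 1}" for j in range(m)],
    )
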
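"""Correlation structures that inform the null model.

A correlation matrix ``V`` (symmetric, PSD, unit diagonal) encodes how
similar the columns (or rows) of an incidence matrix are to each other:
constant (uninformative), group membership, exponential decay with trait
distance, or shared phylogenetic history.  The matrix enters the link model
as the correlation of the row-wise Gaussian random effect, so its scale is
irrelevant — the per-row variance σ_i² carries the scale — and phylogenetic
covariances are standardized to correlations here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "CorrelationMatrix",
    "constant_correlation",
    "group_correlation",
    "exponential_correlation",
    "phylogenetic_correlation",
    "permute_correlation",
    "regularize_correlation",
    "DEFAULT_NUGGET",
]

#: Default nugget η applied wherever a nugget is accepted.
DEFAULT_NUGGET = 0.01

_PSD_TOL = 1e-8  # eigenvalues above −_PSD_TOL count as numerically PSD
_INDEFINITE_TOL = 1e-6  # below −_INDEFINITE_TOL the matrix is genuinely indefinite


@dataclass
class CorrelationMatrix:
    """Labelled symmetric PSD matrix with unit diagonal."""

    values: np.ndarray
    labels: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError(f"correlation matrix must be square, got {V.shape}")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(V), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        off = V[~np.eye(V.shape[0], dtype=bool)]
        if off.size and (off.min() < -1 - 1e-10 or off.max() > 1 + 1e-10):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        lam_min = float(np.linalg.eigvalsh(V).min()) if V.size else 0.0
        if lam_min < -_PSD_TOL:
            raise ValueError(
                f"matrix is not positive semi-definite (λ_min = {lam_min:.3g})"
            )
        self.values = V
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != V.shape[0]:
            raise ValueError("label count does not match matrix dimension")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels")

    @property
    def dim(self) -> int:
        return self.values.shape[0]

    def reorder(self, labels: list[str]) -> "CorrelationMatrix":
        """Return a copy with rows/columns permuted into ``labels`` order."""
        missing = set(labels) - set(self.labels)
        if missing:
            raise KeyError(f"labels not in correlation matrix: {sorted(missing)}")
        idx = [self.labels.index(l) for l in labels]
        return CorrelationMatrix(
            self.values[np.ix_(idx, idx)], list(labels), dict(self.provenance)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def constant_correlation(labels) -> CorrelationMatrix:
    """All-ones matrix: no differences across elements.

    This structure is uninformative: probabilities estimated from it are
    constant within each row, and the informed swap model built on it behaves
    like the uninformed one.
    """
    labels = list(labels)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 labels")
    return CorrelationMatrix(
        np.ones((k, k)), labels, {"builder": "constant", "uninformative": True}
    )


def group_correlation(group_labels: dict | pd.Series, nugget: float = DEFAULT_NUGGET) -> CorrelationMatrix:
    """Block structure: 1−η within a group, 0 between groups.

    ``group_labels`` maps element label → group name (dict, or a Series
    indexed by element label).
    """
    if isinstance(group_labels, pd.Series):
        group_labels = group_labels.to_dict()
    labels = [str(k) for k in group_labels]
    groups = np.asarray([group_labels[k] for k in group_labels], dtype=object)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    if not 0 <= nugget < 1:
        raise ValueError(f"nugget must be in [0, 1), got {nugget}")
    same = (groups[:, None] == groups[None, :]).astype(float)
    V = same * (1.0 - nugget)
    np.fill_diagonal(V, 1.0)
    return CorrelationMatrix(
        V, labels, {"builder": "group", "nugget": nugget}
    )


def exponential_correlation(
    traits: pd.DataFrame | np.ndarray,
    labels=None,
    nugget: float = DEFAULT_NUGGET,
) -> CorrelationMatrix:
    """Exponential decay with Euclidean trait distance.

    Off-diagonal ``v_ij = (1−η)·exp(−d_ij / D_max)`` where ``d_ij`` is the
    Euclidean distance between the trait vectors of i and j and ``D_max`` the
    maximum pairwise distance; the diagonal is 1.  Distances are normalized
    by the maximum so the decay scale adapts to the trait cloud; the nugget η
    keeps coincident elements from being perfectly correlated.
    """
    if isinstance(traits, pd.DataFrame):
        if labels is None:
            labels = list(traits.index.astype(str))
        X = traits.to_numpy(dtype=float)
    elif isinstance(traits, pd.Series):
        if labels is None:
            labels = list(traits.index.astype(str))
        X = traits.to_numpy(dtype=float)[:, None]
    else:
        X = np.asarray(traits, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if labels is None:
            raise ValueError("labels required when traits is a bare array")
    labels = [str(x) for x in labels]
    if not np.isfinite(X).all():
        raise ValueError("traits must be finite")
    if not 0 <= nugget < 1:
        raise ValueError(f"nugget must be in [0, 1), got {nugget}")
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff**2).sum(axis=-1))
    d_max = D.max()
    if d_max == 0:
        raise ValueError("all trait vectors identical: degenerate distance matrix")
    V = (1.0 - nugget) * np.exp(-D / d_max)
    np.fill_diagonal(V, 1.0)
    return CorrelationMatrix(
        V,
        labels,
        {
            "builder": "exponential",
            "nugget": nugget,
            "d_max": float(d_max),
            "form": "(1-eta)*exp(-d/Dmax)",
        },
    )


def phylogenetic_correlation(tree, tip_labels=None) -> CorrelationMatrix:
    """Standardized phylogenetic variance–covariance from a rooted tree.

    The covariance between two tips is the branch length they share on the
    path from the root: ``C_ij = depth(MRCA(i, j))``, with ``C_ii`` the
    root-to-tip depth.  The returned matrix is the correlation
    ``V_ij = C_ij / sqrt(C_ii · C_jj)``; the random-effect variance σ² in
    the link model carries the lost scale.

    ``tree`` may be a dendropy Tree, a newick string, or a path to a newick
    file.  ``tip_labels`` selects and orders tips (default: all tips in tree
    order).
    """
    if isinstance(tree, dendropy.Tree):
        t = tree
    else:
        text = str(tree)
        if "(" in text:
            t = dendropy.Tree.get(data=text, schema="newick")
        else:
            t = dendropy.Tree.get(path=text, schema="newick")
    for edge in t.preorder_edge_iter():
        if edge.head_node is t.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has missing branch lengths")
    depths = {}
    for node in t.preorder_node_iter():
        parent_depth = depths.get(node.parent_node, 0.0) if node.parent_node else 0.0
        edge_len = node.edge.length or 0.0
        depths[node] = parent_depth + edge_len
    tips = {leaf.taxon.label: leaf for leaf in t.leaf_node_iter()}
    if tip_labels is None:
        tip_labels = list(tips)
    tip_labels = [str(x) for x in tip_labels]
    missing = [l for l in tip_labels if l not in tips]
    if missing:
        raise KeyError(f"tips not in tree: {missing}")
    pdm = t.phylogenetic_distance_matrix()
    k = len(tip_labels)
    C = np.zeros((k, k))
    for i, a in enumerate(tip_labels):
        C[i, i] = depths[tips[a]]
        for j in range(i + 1, k):
            b = tip_labels[j]
            d = pdm.patristic_distance(tips[a].taxon, tips[b].taxon)
            C[i, j] = C[j, i] = 0.5 * (depths[tips[a]] + depths[tips[b]] - d)
    if np.any(np.diag(C) <= 0):
        raise ValueError("zero root-to-tip depth: tree has no usable branch lengths")
    s = np.sqrt(np.diag(C))
    V = C / np.outer(s, s)
    V = np.clip((V + V.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(V, 1.0)
    return CorrelationMatrix(V, tip_labels, {"builder": "phylogenetic"})


def permute_correlation(V: CorrelationMatrix, rng) -> CorrelationMatrix:
    """Symmetrically permute row and column identities.

    One uniformly random permutation π is applied to both axes:
    ``out[i, j] = V[π(i), π(j)]``, with labels kept in place, so element
    identities are shuffled relative to the correlation structure.  This is
    the 'misinformation' operation: the eigenvalues (and the multiset of
    off-diagonal values) are preserved but the pairing of elements to
    correlations is destroyed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pi = rng.permutation(V.dim)
    prov = dict(V.provenance)
    prov["permuted"] = True
    return CorrelationMatrix(V.values[np.ix_(pi, pi)], list(V.labels), prov)


def regularize_correlation(
    V: CorrelationMatrix, jitter: float = 1e-8
) -> CorrelationMatrix:
    """Make a correlation matrix strictly positive definite.

    Singular structures (constant, group with η = 0) are valid correlations
    but cannot be inverted by the link model.  If the smallest eigenvalue is
    below ``jitter``, eigenvalues are clipped at 0, ``jitter·I`` is added,
    and the diagonal rescaled to 1.  Genuinely indefinite input
    (λ_min < −1e−6) is an error, not repaired.
    """
    W = V.values
    lam, Q = np.linalg.eigh(W)
    if lam.min() < -_INDEFINITE_TOL:
        raise ValueError(
            f"matrix is indefinite (λ_min = {lam.min():.3g}), refusing to repair"
        )
    if lam.min() >= jitter:
        return V
    lam = np.clip(lam, 0.0, None)
    W2 = (Q * lam) @ Q.T + jitter * np.eye(V.dim)
    s = np.sqrt(np.diag(W2))
    W2 = W2 / np.outer(s, s)
    W2 = (W2 + W2.T) / 2.0
    np.fill_diagonal(W2, 1.0)
    prov = dict(V.provenance)
    prov["regularized_jitter"] = jitter
    return CorrelationMatrix(W2, list(V.labels), prov)


def read_correlation(path) -> CorrelationMatrix:
    """Read a labelled correlation matrix from CSV (labels in header + first column)."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("correlation CSV must have identical row and column labels")
    return CorrelationMatrix(
        df.to_numpy(dtype=float), list(df.index.astype(str)), {"builder": "file"}
    )


def write_correlation(V: CorrelationMatrix, path) -> None:
    V.to_frame().to_csv(path)
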
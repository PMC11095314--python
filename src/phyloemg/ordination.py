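"""Principal coordinates of the phase-distance matrix and the phylo-EMG space.

Classical (metric) multidimensional scaling embeds the taxon × taxon MORD
matrix into ``n - 1`` Euclidean axes; when the matrix is non-Euclidean the
Cailliez additive constant (the smallest constant added to all off-diagonal
dissimilarities that makes every eigenvalue nonnegative) is applied first.
Tip coordinates are then combined with a time-calibrated phylogeny: internal
nodes get maximum-likelihood Brownian-motion ancestral estimates per axis,
yielding a table of tip and ancestor positions plus the tree's edges — the
"phylo-EMG space" — ready for external plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import dendropy
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Eigenvalues above this (negative) floor are treated as nonnegative.
EIG_TOL = 1e-8


@dataclass
class PCOEmbedding:
    """Principal-coordinate embedding of a distance matrix."""

    labels: list[str]
    coordinates: np.ndarray  # taxa x k axes, ordered by decreasing eigenvalue
    eigenvalues: np.ndarray
    additive_constant: float = 0.0

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCO{i + 1}" for i in range(self.k)]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def _double_center(A: np.ndarray) -> np.ndarray:
    J = np.eye(A.shape[0]) - np.full(A.shape, 1.0 / A.shape[0])
    return J @ A @ J


def cailliez_constant(D: np.ndarray) -> float:
    """Smallest constant c such that D + c (off-diagonal) is Euclidean.

    Computed as the largest real eigenvalue of the 2n × 2n block matrix
    ``[[0, 2*Δ1], [-I, -4*Δ2]]`` with Δ1 and Δ2 the double-centered
    ``-D²/2`` and ``-D/2``.
    """
    n = D.shape[0]
    d1 = _double_center(-0.5 * D**2)
    d2 = _double_center(-0.5 * D)
    block = np.block(
        [[np.zeros((n, n)), 2.0 * d1], [-np.eye(n), -4.0 * d2]]
    )
    eig = np.linalg.eigvals(block)
    return float(max(eig.real.max(), 0.0))


def pco(D: pd.DataFrame | np.ndarray, correct: bool = True) -> PCOEmbedding:
    """Classical scaling of a symmetric distance matrix into n-1 axes.

    Double-center ``-D²/2``, eigendecompose, and scale eigenvectors by the
    square roots of their eigenvalues.  With ``correct=True`` and a
    non-Euclidean input, the Cailliez additive constant is applied to the
    off-diagonal dissimilarities before scaling (the constant used is
    recorded on the result).  Axes with nonpositive eigenvalues contribute
    zero coordinates.
    """
    if isinstance(D, pd.DataFrame):
        labels = [str(x) for x in D.index]
        M = D.to_numpy(dtype=float)
    else:
        M = np.asarray(D, dtype=float)
        labels = [f"t{i + 1}" for i in range(M.shape[0])]
    n = M.shape[0]
    if n < 2 or M.shape != (n, n):
        raise ValidationError("need a square matrix with at least 2 taxa")
    if np.isnan(M).any():
        raise ValidationError("distance matrix has excluded (NaN) pairs; drop taxa first")
    if not np.allclose(M, M.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    if np.any(np.diag(M) != 0):
        raise ValidationError("distance matrix must have a zero diagonal")
    if np.any(M < 0):
        raise ValidationError("distances must be nonnegative")

    def embed(Dm: np.ndarray):
        B = _double_center(-0.5 * Dm**2)
        w, V = np.linalg.eigh((B + B.T) / 2.0)
        order = np.argsort(w)[::-1]
        return w[order], V[:, order]

    constant = 0.0
    w, V = embed(M)
    if correct and w.min() < -EIG_TOL * max(abs(w).max(), 1.0):
        constant = cailliez_constant(M)
        Mc = M + constant
        np.fill_diagonal(Mc, 0.0)
        w, V = embed(Mc)
    k = n - 1
    w_k, V_k = w[:k], V[:, :k]
    scale = np.sqrt(np.clip(w_k, 0.0, None))
    # axes with (numerically) zero eigenvalues carry no information
    scale[w_k <= EIG_TOL * max(abs(w).max(), 1.0)] = 0.0
    coords = V_k * scale
    return PCOEmbedding(
        labels=labels, coordinates=coords, eigenvalues=w_k, additive_constant=constant
    )


@dataclass
class PhyloTree:
    """A rooted, time-calibrated tree (branch lengths in Ma) with a root stem."""

    tree: dendropy.Tree
    root_length: float = 1.0

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise ValidationError("tip labels must be unique")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise FormatError(
                    f"missing branch length above {edge.head_node.taxon or 'an internal node'}"
                )
            if edge.length <= 0:
                raise ValidationError("branch lengths must be positive")
        # deterministic internal-node labels for unlabeled ancestors
        i = 0
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if node.label is None:
                node.label = f"node{i}"
            i += 1

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def internal_labels(self) -> list[str]:
        return [n.label for n in self.tree.preorder_node_iter() if not n.is_leaf()]


def parse_newick(text: str, root_length: float = 1.0) -> PhyloTree:
    """Parse a Newick string with branch lengths into a rooted tree."""
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise FormatError(
            f"Newick must end with ';' (at position {len(stripped)})"
        )
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"Newick parse error: {exc}") from exc
    return PhyloTree(tree=tree, root_length=root_length)


def write_newick(tree: PhyloTree) -> str:
    return (
        tree.tree.as_string(
            schema="newick", suppress_rooting=True, suppress_internal_node_labels=True
        ).strip()
    )


def load_reference_tree() -> PhyloTree:
    """Packaged four-sauropsid tree with the study topology.

    Topology ((Trachemys,(Alligator,Sturnus)),Varanus) with synthetic
    placeholder branch lengths in Ma and a 1 Ma root stem; ship-with fixture,
    not published divergence times.
    """
    text = resources.files("phyloemg.data").joinpath("sauropsid_tree_synthetic.nwk").read_text()
    return parse_newick(text, root_length=1.0)


def bm_ancestral_states(tree: PhyloTree, tip_values: dict[str, float]) -> dict[str, float]:
    """Maximum-likelihood Brownian-motion ancestral states for every ancestor.

    Equivalent to generalized least squares on the tree covariance: the joint
    ML estimates minimize the branch-length-weighted sum of squared changes
    ``Σ (x_parent − x_child)² / ℓ`` with tips fixed, a sparse linear system
    solved here directly.  Estimates are computed independently per trait.
    """
    tips = tree.tip_labels
    missing = sorted(set(tips) - set(tip_values))
    extra = sorted(set(tip_values) - set(tips))
    if missing or extra:
        raise ValidationError(
            f"tip/value label mismatch: missing values for {missing}, unmatched {extra}"
        )
    internal = [n for n in tree.tree.preorder_node_iter() if not n.is_leaf()]
    index = {id(n): i for i, n in enumerate(internal)}
    m = len(internal)
    A = np.zeros((m, m))
    b = np.zeros(m)
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        w = 1.0 / node.edge.length
        parent = node.parent_node
        i = index[id(parent)]
        if node.is_leaf():
            A[i, i] += w
            b[i] += w * tip_values[node.taxon.label]
        else:
            j = index[id(node)]
            A[i, i] += w
            A[j, j] += w
            A[i, j] -= w
            A[j, i] -= w
    x = np.linalg.solve(A, b)
    return {n.label: float(x[index[id(n)]]) for n in internal}


@dataclass
class PhyloEMGSpace:
    """Tip and ancestral-node coordinates plus the tree's edges."""

    nodes: pd.DataFrame  # label, is_tip, one column per axis
    edges: pd.DataFrame  # parent, child, length


def phylo_emg_space(embedding: PCOEmbedding, tree: PhyloTree) -> PhyloEMGSpace:
    """Project a PCO embedding onto a phylogeny.

    Returns tip coordinates, per-axis BM ancestral estimates for internal
    nodes, and the parent–child edge list — everything an external plotting
    routine needs; no rendering is performed here.
    """
    tips = set(tree.tip_labels)
    if tips != set(embedding.labels):
        raise ValidationError(
            f"embedding labels {sorted(embedding.labels)} do not match "
            f"tree tips {sorted(tips)}"
        )
    axes = [f"PCO{i + 1}" for i in range(embedding.k)]
    coord = embedding.to_frame()
    anc = {
        ax: bm_ancestral_states(tree, coord[ax].to_dict()) for ax in axes
    }
    rows = []
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            lbl = node.taxon.label
            rows.append({"label": lbl, "is_tip": True, **coord.loc[lbl].to_dict()})
        else:
            rows.append(
                {"label": node.label, "is_tip": False, **{ax: anc[ax][node.label] for ax in axes}}
            )
    edges = []
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        parent = node.parent_node
        child_lbl = node.taxon.label if node.is_leaf() else node.label
        edges.append(
            {"parent": parent.label, "child": child_lbl, "length_ma": float(node.edge.length)}
        )
    return PhyloEMGSpace(nodes=pd.DataFrame(rows), edges=pd.DataFrame(edges))
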
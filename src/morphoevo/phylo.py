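"""Tree I/O and phylogenetic machinery.

Wraps :mod:`dendropy` for Newick parsing, polytomy resolution and pruning,
and implements the comparative-methods core on top of it:

* the Brownian-motion phylogenetic covariance matrix ``C`` (shared
  root-to-MRCA path lengths),
* Felsenstein's phylogenetic independent contrasts (PIC),
* branch-length-weighted squared-change parsimony / maximum-likelihood
  ancestral states (the two coincide under Brownian motion).

Traits are always matched to tips by label, never by row order.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .errors import (
    DegenerateGeometryError,
    InvalidArgumentError,
    NewickParseError,
)

__all__ = [
    "PhyloTree",
    "ContrastSet",
    "parse_newick",
    "write_newick",
    "resolve_polytomies",
    "phylo_covariance",
    "pic",
    "ancestral_states",
]

# Zero-length edges (from polytomy resolution) are replaced by this fraction
# of tree depth inside pic/ancestral_states only, so patristic distances stay
# intact while divisions by branch length stay finite.
_ZERO_BRANCH_FRACTION = 1e-8


class PhyloTree:
    """A rooted, branch-length-bearing tree with stable node ids.

    Thin wrapper around a :class:`dendropy.Tree`.  Tips are identified by
    their (unique) taxon labels; internal nodes receive stable ids
    ``node0, node1, ...`` in preorder (``node0`` is the root).
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self._tree = tree
        self._index()

    # -- construction / IO -------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            t = dendropy.Tree.get(
                data=text,
                schema="newick",
                rooting="force-rooted",
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"could not parse Newick: {exc}") from exc
        return cls(t)

    def to_newick(self, annotate_internal: bool = False) -> str:
        t = self._tree.clone(depth=1)
        if annotate_internal:
            for nd in t.preorder_node_iter():
                if not nd.is_leaf() and nd.label is None:
                    nd.label = getattr(nd, "morphoevo_id", None)
        s = t.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".12g",
            unquoted_underscores=True,
        )
        return s.strip() + ("\n" if not s.endswith("\n") else "")

    def _index(self) -> None:
        labels = []
        j = 0
        for nd in self._tree.preorder_node_iter():
            if nd.edge.length is None:
                if nd.parent_node is None:
                    nd.edge.length = 0.0
                else:
                    nd.edge.length = 0.0
            if nd.edge.length < 0:
                raise InvalidArgumentError("negative branch length")
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise InvalidArgumentError("every tip needs a label")
                nd.morphoevo_id = nd.taxon.label
                labels.append(nd.taxon.label)
            else:
                nd.morphoevo_id = f"node{j}"
                j += 1
        if len(set(labels)) != len(labels):
            raise InvalidArgumentError("tip labels are not unique")
        self._tip_labels = labels
        self._n_internal = j

    # -- basic properties --------------------------------------------------
    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    @property
    def internal_ids(self) -> list[str]:
        return [
            nd.morphoevo_id for nd in self._tree.preorder_node_iter() if not nd.is_leaf()
        ]

    @property
    def root_id(self) -> str:
        return self._tree.seed_node.morphoevo_id

    def node_depths(self) -> dict[str, float]:
        """Distance of every node from the root (root edge excluded)."""
        depths: dict[str, float] = {}
        for nd in self._tree.preorder_node_iter():
            if nd.parent_node is None:
                depths[nd.morphoevo_id] = 0.0
            else:
                depths[nd.morphoevo_id] = depths[nd.parent_node.morphoevo_id] + nd.edge.length
        return depths

    @property
    def depth(self) -> float:
        d = self.node_depths()
        return max(d[t] for t in self._tip_labels)

    @property
    def n_edges(self) -> int:
        return sum(1 for nd in self._tree.preorder_node_iter() if nd.parent_node is not None)

    @property
    def is_bifurcating(self) -> bool:
        return all(
            len(nd.child_nodes()) == 2
            for nd in self._tree.preorder_node_iter()
            if not nd.is_leaf()
        )

    @property
    def has_polytomies(self) -> bool:
        return not self.is_bifurcating

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.node_depths()
        tips = np.array([d[t] for t in self._tip_labels])
        T = tips.max()
        return bool(T == 0 or (tips.max() - tips.min()) <= rel_tol * T)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def rescaled(self, factor: float | None = None, depth: float | None = None) -> "PhyloTree":
        """Multiply all branch lengths by ``factor`` (or normalise to ``depth``)."""
        if (factor is None) == (depth is None):
            raise InvalidArgumentError("give exactly one of factor or depth")
        if depth is not None:
            factor = depth / self.depth
        t = self._tree.clone(depth=1)
        for e in t.preorder_edge_iter():
            if e.length is not None:
                e.length *= factor
        return PhyloTree(t)

    def prune_to(self, labels) -> "PhyloTree":
        """Subtree spanning the given tip labels (path lengths preserved)."""
        keep = set(labels)
        missing = keep - set(self._tip_labels)
        if missing:
            raise InvalidArgumentError(f"tips not in tree: {sorted(missing)}")
        t = self._tree.extract_tree_with_taxa_labels(labels=keep)
        return PhyloTree(t)


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (branch lengths required, missing -> 0)."""
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, annotate_internal: bool = False) -> str:
    """Serialise to Newick; lengths printed to 12 significant digits."""
    return tree.to_newick(annotate_internal=annotate_internal)


def resolve_polytomies(tree: PhyloTree, seed: int = 0) -> PhyloTree:
    """Randomly resolve multifurcations with zero-length inserted edges.

    Tip-to-root path lengths (hence the patristic distance matrix) are
    unchanged; the result is deterministic given ``seed``.
    """
    t = tree.dendropy_tree.clone(depth=1)
    t.resolve_polytomies(rng=_random.Random(seed))
    for e in t.preorder_edge_iter():
        if e.length is None:
            e.length = 0.0
    return PhyloTree(t)


def phylo_covariance(tree: PhyloTree) -> pd.DataFrame:
    """Brownian-motion covariance ``C[i, j]`` = root-to-MRCA path length.

    Diagonal entries are the tip depths; the matrix is symmetric PSD.
    """
    labels = tree.tip_labels
    pos = {lab: i for i, lab in enumerate(labels)}
    depths = tree.node_depths()
    n = len(labels)
    C = np.zeros((n, n))
    # accumulate leaf sets postorder; pairs across child subtrees share the node
    leafsets: dict[int, np.ndarray] = {}
    for nd in tree.dendropy_tree.postorder_node_iter():
        if nd.is_leaf():
            leafsets[id(nd)] = np.array([pos[nd.taxon.label]])
            C[pos[nd.taxon.label], pos[nd.taxon.label]] = depths[nd.morphoevo_id]
        else:
            groups = [leafsets.pop(id(c)) for c in nd.child_nodes()]
            d = depths[nd.morphoevo_id]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    C[np.ix_(groups[a], groups[b])] = d
                    C[np.ix_(groups[b], groups[a])] = d
            leafsets[id(nd)] = np.concatenate(groups)
    return pd.DataFrame(C, index=labels, columns=labels)


def _as_trait_frame(tree: PhyloTree, traits) -> pd.DataFrame:
    """Coerce traits to a DataFrame row-matched (by label) to the tree tips."""
    if isinstance(traits, pd.Series):
        traits = traits.to_frame()
    if not isinstance(traits, pd.DataFrame):
        raise InvalidArgumentError(
            "traits must be a pandas DataFrame/Series indexed by tip label"
        )
    have, want = set(traits.index), set(tree.tip_labels)
    if have != want:
        missing = sorted(want - have)[:5]
        extra = sorted(have - want)[:5]
        raise InvalidArgumentError(
            f"trait/tip label mismatch (missing from traits: {missing}, "
            f"not in tree: {extra})"
        )
    return traits.loc[tree.tip_labels].astype(float)


def _effective_length(length: float, floor: float) -> float:
    return length if length > 0.0 else floor


@dataclass
class ContrastSet:
    """Phylogenetic independent contrasts for an N-tip bifurcating tree.

    ``contrasts`` has one row per internal node (N-1 rows) in postorder;
    ``sd_normalizers`` are the ``sqrt(b_l' + b_r')`` scale factors already
    divided out of each contrast.
    """

    contrasts: pd.DataFrame
    sd_normalizers: pd.Series

    @property
    def node_order(self) -> list[str]:
        return list(self.contrasts.index)


def pic(tree: PhyloTree, traits) -> ContrastSet:
    """Felsenstein's pruning algorithm for independent contrasts.

    At each internal node the contrast is ``(x_left - x_right) /
    sqrt(b_l' + b_r')`` with the usual branch-length inflation
    ``b' = b + b_l b_r / (b_l + b_r)`` propagated rootward.  Under Brownian
    motion with rate sigma^2 the contrasts are iid with variance sigma^2
    per trait.
    """
    if tree.has_polytomies:
        raise InvalidArgumentError(
            "tree contains polytomies; call resolve_polytomies() first"
        )
    X = _as_trait_frame(tree, traits)
    floor = _ZERO_BRANCH_FRACTION * max(tree.depth, 1.0)
    vals: dict[int, np.ndarray] = {}
    blen: dict[int, float] = {}
    rows, norms, order = [], [], []
    for nd in tree.dendropy_tree.postorder_node_iter():
        if nd.is_leaf():
            vals[id(nd)] = X.loc[nd.taxon.label].to_numpy()
            blen[id(nd)] = _effective_length(nd.edge.length, floor)
        else:
            l, r = nd.child_nodes()
            vl, vr = vals.pop(id(l)), vals.pop(id(r))
            bl, br = blen.pop(id(l)), blen.pop(id(r))
            s = np.sqrt(bl + br)
            rows.append((vl - vr) / s)
            norms.append(s)
            order.append(nd.morphoevo_id)
            vals[id(nd)] = (br * vl + bl * vr) / (bl + br)
            extra = bl * br / (bl + br)
            b0 = nd.edge.length if nd.parent_node is not None else 0.0
            blen[id(nd)] = _effective_length(b0, floor) + extra if nd.parent_node is not None else extra
    contrasts = pd.DataFrame(np.vstack(rows), index=order, columns=X.columns)
    return ContrastSet(contrasts=contrasts, sd_normalizers=pd.Series(norms, index=order))


def _covariance_with_floor(tree: PhyloTree, weighted: bool) -> tuple[pd.DataFrame, dict]:
    t = tree
    if not weighted:
        u = tree.dendropy_tree.clone(depth=1)
        for e in u.preorder_edge_iter():
            if e.length is not None and e.head_node.parent_node is not None:
                e.length = 1.0
        t = PhyloTree(u)
    floor = _ZERO_BRANCH_FRACTION * max(t.depth, 1.0)
    u = t.dendropy_tree.clone(depth=1)
    for nd in u.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length <= 0.0:
            nd.edge.length = floor
    t2 = PhyloTree(u)
    return phylo_covariance(t2), t2.node_depths()


def ancestral_states(tree: PhyloTree, traits, weighted: bool = True) -> pd.DataFrame:
    """Ancestral states by branch-length-weighted squared-change parsimony.

    The reconstruction minimises ``sum_edges (delta state)^2 / length``, which
    is exactly the maximum-likelihood (GLS) estimate under Brownian motion;
    the root state equals ``(1' C^-1 x) / (1' C^-1 1)`` per trait.  With
    ``weighted=False`` all branches count equally (classic unweighted
    squared-change parsimony).

    Returns a DataFrame of internal-node states (preorder, root ``node0``
    first).  Polytomies are allowed.
    """
    X = _as_trait_frame(tree, traits)
    C_df, depths = _covariance_with_floor(tree, weighted)
    labels = list(C_df.index)
    C = C_df.to_numpy()
    try:
        cf = cho_factor(C)
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError(f"singular phylogenetic covariance: {exc}") from exc
    ones = np.ones(len(labels))
    x = X.to_numpy()
    iC1 = cho_solve(cf, ones)
    root = (iC1 @ x) / (iC1 @ ones)  # GLS root per trait
    resid = x - root[None, :]
    iCr = cho_solve(cf, resid)

    # Shared-depth rows between each internal node n and every tip t:
    # depth(n) for t inside the subtree of n, else C[u, t] for any
    # representative tip u inside (the MRCA of n and t equals MRCA(u, t)).
    # Node ids/orders are identical across the floored clone used for C.
    pos = {lab: i for i, lab in enumerate(labels)}
    mask_of: dict[int, np.ndarray] = {}
    for nd in tree.dendropy_tree.postorder_node_iter():
        if nd.is_leaf():
            mask_of[id(nd)] = np.array([pos[nd.taxon.label]])
        else:
            mask_of[id(nd)] = np.concatenate([mask_of[id(c)] for c in nd.child_nodes()])

    out_ids, out_rows = [], []
    for nd in tree.dendropy_tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        inside = np.zeros(len(labels), dtype=bool)
        inside[mask_of[id(nd)]] = True
        d_node = depths[nd.morphoevo_id]
        rep = int(mask_of[id(nd)][0])
        c_row = np.where(inside, d_node, C[rep, :])
        est = root + c_row @ iCr
        out_ids.append(nd.morphoevo_id)
        out_rows.append(est)
    out = pd.DataFrame(np.vstack(out_rows), index=out_ids, columns=X.columns)
    out.attrs["root_id"] = tree.root_id
    return out
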
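"""Rooted phylogenies, Newick I/O, covariance construction and branch transforms.

Trees are stored in a flat array representation (parent pointers, branch
lengths, postorder) so that likelihood computations and branch-length
transformations are cheap.  Tips occupy node indices ``0 .. n_tips-1``;
internal nodes follow.  Branch lengths are in millions of years (Myr) for
dated trees, although nothing here depends on the unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "DivergenceTable",
    "parse_newick",
    "write_newick",
    "vcv_matrix",
    "transform_lambda",
    "transform_kappa",
    "transform_ou",
    "lambda_tree",
    "kappa_tree",
    "ou_tree",
    "stitch_trees",
]


def _fmt(x) -> str:
    """Exact round-trip branch-length formatting."""
    return repr(float(x))


class NewickError(ValueError):
    """Raised for malformed or inconsistent Newick input."""


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths.

    Attributes
    ----------
    tip_names:
        Labels of the tips, in node-index order (node ``i`` is tip
        ``tip_names[i]`` for ``i < n_tips``).
    parent:
        Parent node index for every node; ``-1`` for the root.
    blen:
        Branch length subtending each node; ``0.0`` for the root.
    children:
        Child index lists per node (empty for tips).
    postorder:
        Node indices in postorder (children before parents; root last).
    """

    tip_names: list[str]
    parent: np.ndarray
    blen: np.ndarray
    children: list[list[int]]
    postorder: np.ndarray

    # -- basic properties -------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        d = np.zeros(self.n_nodes)
        for node in self.postorder[::-1]:
            p = self.parent[node]
            if p >= 0:
                d[node] = d[p] + self.blen[node]
        return d

    def tip_depths(self) -> np.ndarray:
        return self.depths()[: self.n_tips]

    @property
    def height(self) -> float:
        return float(self.tip_depths().max())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.tip_depths()
        h = d.max()
        return bool(h == 0 or np.all(np.abs(d - h) <= rtol * h))

    def copy(self) -> "Phylogeny":
        return Phylogeny(
            list(self.tip_names),
            self.parent.copy(),
            self.blen.copy(),
            [list(c) for c in self.children],
            self.postorder.copy(),
        )

    def with_blen(self, blen: np.ndarray) -> "Phylogeny":
        """Same topology with replacement branch lengths."""
        out = self.copy()
        out.blen = np.asarray(blen, dtype=float).copy()
        out.blen[self.root] = 0.0
        return out

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_newick(text)

    def to_newick(self) -> str:
        return write_newick(self)

    def retain_tips(self, names: Iterable[str]) -> "Phylogeny":
        """Prune to the given tips, suppressing resulting unifurcations.

        The returned tree is rooted at the MRCA of the retained tips, so
        root-to-tip depths may shrink; all pairwise tip distances among
        retained tips are preserved exactly.
        """
        keep = set(names)
        missing = keep - set(self.tip_names)
        if missing:
            raise ValueError(f"tips not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise ValueError("need at least 2 tips to retain")

        def frag(node: int, extra: float) -> str | None:
            if not self.children[node]:
                if self.tip_names[node] in keep:
                    return f"{self.tip_names[node]}:{_fmt(self.blen[node] + extra)}"
                return None
            parts = []
            for c in self.children[node]:
                f = frag(c, 0.0)
                if f is not None:
                    parts.append(f)
            if not parts:
                return None
            if len(parts) == 1:
                # unifurcation: merge this node's branch into the child's
                label, _, rest = parts[0].rpartition(":")
                return f"{label}:{_fmt(float(rest) + self.blen[node] + extra)}"
            return f"({','.join(parts)}):{_fmt(self.blen[node] + extra)}"

        root = self.root
        parts = [f for c in self.children[root] for f in [frag(c, 0.0)] if f]
        if len(parts) == 1:
            # new root is the MRCA below the old root: strip its stem branch
            inner, _, _ = parts[0].rpartition(":")
            if not inner.startswith("("):
                raise ValueError("fewer than 2 tips retained below the root")
            text = inner + ";"
        else:
            text = f"({','.join(parts)});"
        return parse_newick(text)


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required on non-root edges)."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"malformed Newick: {exc}") from exc

    leaves = [lf for lf in dtree.leaf_node_iter()]
    labels = [
        (lf.taxon.label if lf.taxon is not None else lf.label) for lf in leaves
    ]
    if any(lb is None for lb in labels):
        raise NewickError("unlabeled tip in Newick input")
    labels = [lb.replace(" ", "_") for lb in labels]
    if len(set(labels)) != len(labels):
        dupes = sorted({lb for lb in labels if labels.count(lb) > 1})
        raise NewickError(f"duplicate tip labels: {dupes}")

    n_tips = len(leaves)
    index: dict[int, int] = {}
    for i, lf in enumerate(leaves):
        index[id(lf)] = i
    internals = [nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()]
    for j, nd in enumerate(internals):
        index[id(nd)] = n_tips + j

    n_nodes = n_tips + len(internals)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    blen = np.zeros(n_nodes)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for nd in dtree.preorder_node_iter():
        i = index[id(nd)]
        if nd.parent_node is not None:
            p = index[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
            if nd.edge.length is None:
                raise NewickError(f"missing branch length above node {i}")
            blen[i] = float(nd.edge.length)
            if blen[i] < 0:
                raise NewickError(f"negative branch length above node {i}")
    postorder = np.array(
        [index[id(nd)] for nd in dtree.postorder_node_iter()], dtype=np.int64
    )
    tree = Phylogeny(labels, parent, blen, children, postorder)
    if len(tree.children[tree.root]) < 2:
        raise NewickError("root must have degree >= 2")
    return tree


def write_newick(tree: Phylogeny) -> str:
    """Serialize to Newick; branch lengths via ``repr`` (exact round trip)."""

    def frag(node: int) -> str:
        if not tree.children[node]:
            return f"{tree.tip_names[node]}:{_fmt(tree.blen[node])}"
        inner = ",".join(frag(c) for c in tree.children[node])
        if tree.parent[node] < 0:
            return f"({inner})"
        return f"({inner}):{_fmt(tree.blen[node])}"

    return frag(tree.root) + ";"


# ---------------------------------------------------------------------------
# Phylogenetic covariance
# ---------------------------------------------------------------------------


@dataclass
class PhyloCovariance:
    """Tip covariance under Brownian motion: shared root-to-MRCA path lengths."""

    matrix: np.ndarray
    tip_names: list[str]

    def copy(self) -> "PhyloCovariance":
        return PhyloCovariance(self.matrix.copy(), list(self.tip_names))


def vcv_matrix(tree: Phylogeny) -> PhyloCovariance:
    """C_ij = shared path length from root to MRCA(i, j); C_ii = tip depth."""
    n = tree.n_tips
    depth = tree.depths()
    C = np.zeros((n, n))
    tipsets: dict[int, np.ndarray] = {}
    for node in tree.postorder:
        kids = tree.children[node]
        if not kids:
            tipsets[node] = np.array([node])
            continue
        sets = [tipsets.pop(k) for k in kids]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                C[np.ix_(sets[a], sets[b])] = depth[node]
                C[np.ix_(sets[b], sets[a])] = depth[node]
        tipsets[node] = np.concatenate(sets)
    np.fill_diagonal(C, depth[:n])
    return PhyloCovariance(C, list(tree.tip_names))


def transform_lambda(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda: multiply off-diagonal covariances by ``lam``."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    out = C.copy()
    d = np.diag(out.matrix).copy()
    out.matrix *= lam
    np.fill_diagonal(out.matrix, d)
    return out


def transform_kappa(tree: Phylogeny, kappa: float) -> Phylogeny:
    """Pagel's kappa: raise every branch length to the power ``kappa``.

    ``0 ** 0`` is defined as 0, so zero-length branches stay zero in the
    speciational (kappa = 0) limit.
    """
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    b = tree.blen.copy()
    nz = b > 0
    b[nz] = b[nz] ** kappa
    return tree.with_blen(b)


kappa_tree = transform_kappa


def lambda_tree(tree: Phylogeny, lam: float) -> Phylogeny:
    """Tree whose BM covariance equals the lambda-transformed covariance.

    All branches are scaled by lambda and each terminal branch gains
    ``(1 - lambda) * tip_depth`` so tip variances are unchanged.
    """
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    depth = tree.depths()
    b = tree.blen * lam
    tips = np.arange(tree.n_tips)
    b[tips] += (1.0 - lam) * depth[tips]
    return tree.with_blen(b)


def ou_tree(tree: Phylogeny, alpha: float) -> Phylogeny:
    """Tree whose BM covariance equals the stationary OU tip covariance.

    On an ultrametric tree of height T, the OU covariance between tips whose
    MRCA sits at depth s from the root is
    ``(1/(2 alpha)) * exp(-2 alpha (T - s)) * (1 - exp(-2 alpha s))``,
    an increasing function g(s) of s only, so the transformed matrix is the
    BM covariance of a tree whose node depths are g(depth).
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if not tree.is_ultrametric():
        raise ValueError("OU transform requires an ultrametric tree")
    if alpha == 0:
        return tree.copy()
    depth = tree.depths()
    T = tree.height
    g = np.exp(-2.0 * alpha * T) * np.expm1(2.0 * alpha * depth) / (2.0 * alpha)
    b = np.zeros_like(tree.blen)
    for node in range(tree.n_nodes):
        p = tree.parent[node]
        if p >= 0:
            b[node] = g[node] - g[p]
    return tree.with_blen(b)


def transform_ou(tree: Phylogeny, alpha: float) -> PhyloCovariance:
    """Stationary Ornstein–Uhlenbeck tip covariance on an ultrametric tree."""
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if not tree.is_ultrametric():
        raise ValueError("OU covariance requires an ultrametric tree")
    S = vcv_matrix(tree)
    if alpha == 0:
        return S
    T = tree.height
    s = S.matrix
    C = np.exp(-2.0 * alpha * (T - s)) * (-np.expm1(-2.0 * alpha * s)) / (2.0 * alpha)
    return PhyloCovariance(C, S.tip_names)


# ---------------------------------------------------------------------------
# Supertree stitching from divergence dates
# ---------------------------------------------------------------------------


@dataclass
class DivergenceTable:
    """Pairwise clade divergence ages (Myr), symmetric lookup."""

    ages: dict[frozenset, float] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str, float]]) -> "DivergenceTable":
        t = cls()
        for a, b, age in pairs:
            if age <= 0:
                raise ValueError(f"divergence age must be positive: {a}-{b} {age}")
            t.ages[frozenset((a, b))] = float(age)
        return t

    @classmethod
    def from_csv(cls, path) -> "DivergenceTable":
        import pandas as pd

        df = pd.read_csv(path)
        return cls.from_pairs(
            zip(df["cladeA"], df["cladeB"], df["age_myr"].astype(float))
        )

    def age(self, a: str, b: str) -> float:
        key = frozenset((a, b))
        if key not in self.ages:
            raise KeyError(f"no divergence age for pair ({a}, {b})")
        return self.ages[key]


def stitch_trees(
    class_trees: Mapping[str, Phylogeny],
    divergences: DivergenceTable,
    nesting: Sequence[str],
) -> Phylogeny:
    """Join ultrametric clade trees on a ladder backbone of divergence ages.

    ``nesting`` orders the clades outermost first: ``[A, B, C, D]`` yields the
    backbone ``(A, (B, (C, D)))`` with node ages taken from ``divergences``
    (the age of the node joining clade i to the clades after it is the
    divergence age of clade i and clade i+1).  Each clade's stem branch is
    its attachment age minus its crown age; within-clade branch lengths are
    untouched.
    """
    if len(nesting) < 2:
        raise ValueError("need at least two clades to stitch")
    missing = [c for c in nesting if c not in class_trees]
    if missing:
        raise ValueError(f"no tree supplied for clades: {missing}")

    heights = {}
    for name in nesting:
        t = class_trees[name]
        if not t.is_ultrametric():
            raise ValueError(f"clade tree {name!r} is not ultrametric")
        heights[name] = t.height

    ages = [divergences.age(nesting[i], nesting[i + 1]) for i in range(len(nesting) - 1)]
    for i in range(len(ages) - 1):
        if ages[i] <= ages[i + 1]:
            raise ValueError(
                "divergence ages must strictly decrease along the nesting: "
                f"{nesting[i]} at {ages[i]} vs {nesting[i + 1]} at {ages[i + 1]}"
            )

    def subtree(name: str, attach_age: float) -> str:
        stem = attach_age - heights[name]
        if stem < 0:
            raise ValueError(
                f"crown age of clade {name!r} ({heights[name]}) exceeds its "
                f"attachment age ({attach_age})"
            )
        nwk = write_newick(class_trees[name])[:-1]  # strip ';'
        return f"{nwk}:{_fmt(stem)}"

    # innermost pair first, then wrap outwards
    text = f"({subtree(nesting[-2], ages[-1])},{subtree(nesting[-1], ages[-1])})"
    for i in range(len(nesting) - 3, -1, -1):
        inner_stem = ages[i] - ages[i + 1]
        text = f"({subtree(nesting[i], ages[i])},{text}:{_fmt(inner_stem)})"
    return parse_newick(text + ";")
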
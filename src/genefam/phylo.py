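"""Distance and likelihood phylogenetics under the JTT model.

Provides complete-deletion filtering, maximum-likelihood pairwise
distances under the Jones–Taylor–Thornton (JTT) empirical amino-acid
model, Saitou–Nei neighbor joining, Felsenstein-pruning log-likelihoods,
nearest-neighbor-interchange (NNI) hill climbing with per-edge branch
length optimization, and nonparametric bootstrap supports.

No among-site rate heterogeneity is modelled; sites are independent and
identically distributed. Branch lengths are expected substitutions per
site (the JTT rate matrix is normalized to unit mean rate at
equilibrium). Trees are unrooted, represented with a trifurcating root;
the model is time-reversible, so the likelihood does not depend on the
root placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.optimize import minimize_scalar

PAML_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA = {a: i for i, a in enumerate(PAML_ORDER)}


# ---------------------------------------------------------------------------
# JTT model

@lru_cache(maxsize=1)
def _jtt():
    """(eigvals, right, left, freqs) of the normalized JTT rate matrix."""
    text = resources.files("genefam").joinpath("data/jtt.dat").read_text()
    freqs = None
    tri: list[list[float]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("FREQS"):
            freqs = np.array([float(x) for x in line.split()[1:]])
        else:
            tri.append([float(x) for x in line.split()])
    assert freqs is not None and len(tri) == 19
    freqs = freqs / freqs.sum()
    S = np.zeros((20, 20))
    for i, row in enumerate(tri, start=1):
        for j, v in enumerate(row):
            S[i, j] = S[j, i] = v
    Q = S * freqs[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    Q /= -(freqs * np.diag(Q)).sum()  # unit substitutions/site at equilibrium
    d = np.sqrt(freqs)
    B = (Q * d[:, None]) / d[None, :]
    B = 0.5 * (B + B.T)  # symmetric up to rounding
    w, U = np.linalg.eigh(B)
    return w, U / d[:, None], (U.T * d[None, :]), freqs


def jtt_frequencies() -> np.ndarray:
    return _jtt()[3].copy()


def jtt_transition(t: float) -> np.ndarray:
    """P(t) = exp(Qt) for the JTT model (rows: from, cols: to)."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    w, right, left, _ = _jtt()
    P = (right * np.exp(w * t)[None, :]) @ left
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def encode_protein(residues: str) -> np.ndarray:
    try:
        return np.array([_AA[a] for a in residues], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"non-standard residue {e.args[0]!r}") from None


# ---------------------------------------------------------------------------
# Alignments

@dataclass
class MultipleAlignment:
    """An ordered set of equal-length gapped sequences (gap symbol '-')."""

    rows: list[tuple[str, str]]

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("alignment row ids must be unique")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def has_gaps(self) -> bool:
        return any("-" in s or "X" in s for _, s in self.rows)


def complete_deletion(aln: MultipleAlignment) -> MultipleAlignment:
    """Drop every column containing a gap or a missing residue ('X')."""
    seqs = [s for _, s in aln.rows]
    keep = [k for k in range(aln.n_sites)
            if all(s[k] not in "-X" for s in seqs)]
    if not keep:
        raise ValueError(
            "complete deletion removed every column; a pairwise-deletion "
            "strategy would be required for this alignment"
        )
    return MultipleAlignment(
        [(i, "".join(s[k] for k in keep)) for i, s in aln.rows]
    )


def write_alignment_fasta(aln: MultipleAlignment, path) -> None:
    with open(path, "w") as fh:
        for name, seq in aln.rows:
            fh.write(f">{name}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k:k + 60] + "\n")


def read_alignment_fasta(path) -> MultipleAlignment:
    from .seqio import read_fasta

    return MultipleAlignment([(r.id, r.residues) for r in read_fasta(path)])


# ---------------------------------------------------------------------------
# Pairwise ML distance

def _golden_min(f, lo: float, hi: float, tol: float = 1e-7) -> float:
    """Golden-section minimization of a unimodal function on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1) / 2
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def jtt_distance(a: str, b: str, t_max: float = 10.0) -> float:
    """ML evolutionary distance (substitutions/site) between two gapless
    protein sequences under JTT, by golden-section search on [0, t_max]."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if len(a) == 0:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 0.0
    ia, ib = encode_protein(a), encode_protein(b)
    counts = np.zeros((20, 20))
    np.add.at(counts, (ia, ib), 1.0)
    freqs = jtt_frequencies()
    logpi = np.log(freqs)

    def neg_loglik(t):
        if t <= 0:
            t = 1e-9
        P = jtt_transition(t)
        with np.errstate(divide="ignore"):
            ll = counts * (logpi[:, None] + np.log(np.maximum(P, 1e-300)))
        return -ll.sum()

    return _golden_min(neg_loglik, 0.0, t_max)


def distance_matrix(aln: MultipleAlignment) -> tuple[np.ndarray, list[str]]:
    """Pairwise JTT distances after complete deletion."""
    clean = complete_deletion(aln) if aln.has_gaps() else aln
    n = len(clean.rows)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = jtt_distance(clean.rows[i][1], clean.rows[j][1])
    return D, clean.ids


# ---------------------------------------------------------------------------
# Trees

class Node:
    __slots__ = ("name", "children", "parent", "length", "support")

    def __init__(self, name=None, length=0.0):
        self.name = name
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.support: float | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """An (un)rooted tree with branch lengths in substitutions/site.

    Unrooted trees carry a trifurcating root. ``supports`` (bootstrap
    percentages) live on internal nodes; ``loglik`` is set by the
    likelihood routines.
    """

    def __init__(self, root: Node, loglik: float | None = None):
        self.root = root
        self.loglik = loglik

    # -- traversal ---------------------------------------------------------
    def postorder(self):
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf()]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_edges(self) -> list[Node]:
        """Child endpoints of internal edges (non-leaf, non-root nodes)."""
        return [n for n in self.postorder()
                if not n.is_leaf() and n.parent is not None]

    def copy(self) -> "PhyloTree":
        def clone(n):
            c = Node(n.name, n.length)
            c.support = n.support
            for ch in n.children:
                c.add(clone(ch))
            return c

        return PhyloTree(clone(self.root), self.loglik)

    # -- splits ------------------------------------------------------------
    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions, canonicalized to the side not
        containing the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out = set()
        below: dict[int, frozenset] = {}
        for n in self.postorder():
            if n.is_leaf():
                below[id(n)] = frozenset([n.name])
            else:
                s = frozenset().union(*(below[id(c)] for c in n.children))
                below[id(n)] = s
                if n.parent is not None and 2 <= len(s) <= len(all_leaves) - 2:
                    out.add(s if ref not in s else all_leaves - s)
        return out

    def split_below(self, node: Node) -> frozenset:
        names = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf():
                names.append(n.name)
            stack.extend(n.children)
        return frozenset(names)

    # -- newick ------------------------------------------------------------
    def newick(self, support_labels: bool = True) -> str:
        def fmt(n):
            if n.is_leaf():
                return f"{n.name}:{n.length:.6g}"
            inner = ",".join(fmt(c) for c in n.children)
            label = ""
            if support_labels and n.support is not None:
                label = str(int(round(n.support)))
            elif n.name:
                label = n.name
            if n.parent is None:
                return f"({inner}){label}"
            return f"({inner}){label}:{n.length:.6g}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        import dendropy

        dt = dendropy.Tree.get(data=text, schema="newick",
                               suppress_internal_node_taxa=True)

        def convert(dn):
            name = dn.taxon.label if dn.taxon is not None else None
            node = Node(name, dn.edge.length or 0.0)
            if dn.label is not None and not dn.is_leaf():
                try:
                    node.support = float(dn.label)
                except ValueError:
                    node.name = dn.label
            for ch in dn.child_nodes():
                node.add(convert(ch))
            return node

        return cls(convert(dt.seed_node))


# ---------------------------------------------------------------------------
# Neighbor joining

def neighbor_joining(D: np.ndarray, labels: list[str]) -> PhyloTree:
    """Classic Saitou–Nei neighbor joining.

    Negative intermediate branch lengths are clamped to zero with the
    deficit transferred to the sister edge (their sum is preserved).
    Ties in the Q criterion resolve to the smallest (row, column) pair.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if len(labels) != n:
        raise ValueError("label count must match matrix size")

    nodes = [Node(name) for name in labels]
    D = D.copy()
    while len(nodes) > 2:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)  # row-major: min (i,j)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = max(li + lj, 0.0), 0.0
        parent = Node()
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = li, lj
        parent.add(ni)
        parent.add(nj)
        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = du[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]

    a, b = nodes
    final = D[0, 1]
    if not b.is_leaf():
        root, other = b, a
    else:
        root, other = a, b
    if root.is_leaf():  # only possible for n == 2 input, excluded above
        raise AssertionError
    other.length = max(final, 0.0)
    root.add(other)
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Likelihood

def _encode_alignment(aln: MultipleAlignment) -> dict[str, np.ndarray]:
    return {name: encode_protein(seq) for name, seq in aln.rows}


def tree_loglik(tree: PhyloTree, aln: MultipleAlignment) -> float:
    """Felsenstein-pruning log-likelihood under JTT.

    The alignment must be gap-free (apply :func:`complete_deletion`
    first). Equilibrium frequencies are applied at the root; by
    time-reversibility the result is invariant to root placement.
    """
    if aln.has_gaps():
        raise ValueError("alignment contains gaps/missing data; apply "
                         "complete_deletion first")
    leaf_names = set(tree.leaf_names())
    if leaf_names != set(aln.ids):
        raise ValueError("tree leaves do not match alignment ids")
    codes = _encode_alignment(aln)
    n_sites = aln.n_sites
    freqs = jtt_frequencies()
    partial: dict[int, np.ndarray] = {}
    logscale = 0.0
    for node in tree.postorder():
        if node.is_leaf():
            p = np.zeros((n_sites, 20))
            p[np.arange(n_sites), codes[node.name]] = 1.0
        else:
            p = np.ones((n_sites, 20))
            for child in node.children:
                P = jtt_transition(child.length)
                p *= partial.pop(id(child)) @ P.T
            mx = p.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            p /= mx[:, None]
            logscale += np.log(mx).sum()
        partial[id(node)] = p
    site_lik = partial[id(tree.root)] @ freqs
    if np.any(site_lik <= 0):
        return -np.inf
    return float(np.log(site_lik).sum() + logscale)


def optimize_branch_lengths(tree: PhyloTree, aln: MultipleAlignment,
                            tol: float = 1e-6, max_rounds: int = 5
                            ) -> PhyloTree:
    """Round-robin per-edge optimization with Brent's method."""
    tree = tree.copy()
    edges = [n for n in tree.postorder() if n.parent is not None]
    prev = tree_loglik(tree, aln)
    for _ in range(max_rounds):
        for node in edges:
            def neg(t, node=node):
                node.length = t
                return -tree_loglik(tree, aln)

            res = minimize_scalar(neg, bounds=(0.0, 10.0), method="bounded",
                                  options={"xatol": tol})
            node.length = float(res.x)
        cur = tree_loglik(tree, aln)
        if cur - prev < tol:
            break
        prev = cur
    tree.loglik = tree_loglik(tree, aln)
    return tree


def _swap_subtrees(v: Node, a: Node, c: Node) -> None:
    """Exchange subtree ``a`` (a child of v) with ``c`` (a child of
    v's parent). Calling again with (v, c, a) reverts the swap."""
    u = v.parent
    vi, ui = v.children.index(a), u.children.index(c)
    v.children[vi], u.children[ui] = c, a
    c.parent, a.parent = v, u


def _nni_moves(edge_child: Node):
    """The two NNI rearrangements around the edge above ``edge_child``.

    The edge joins v = edge_child to its parent u. Subtrees A, B hang
    from v; C is another child of u. Swapping C with A, and C with B,
    realizes both alternative topologies around the edge.
    """
    v = edge_child
    others = [c for c in v.parent.children if c is not v]
    if not others or len(v.children) < 2:
        return []
    c = others[0]
    return [(v, v.children[0], c), (v, v.children[1], c)]


def ml_search(aln: MultipleAlignment, start: PhyloTree,
              seed: int = 0, tol: float = 1e-6) -> PhyloTree:
    """NNI hill climbing with per-edge branch-length optimization.

    Returns when no rearrangement improves the log-likelihood by more
    than ``tol``. The returned tree's ``loglik`` is set.
    """
    current = optimize_branch_lengths(start, aln, tol=tol)
    while True:
        improved = False
        for v in current.internal_edges():
            best_alt = None
            for v_, a, c in _nni_moves(v):
                _swap_subtrees(v_, a, c)
                cand = optimize_branch_lengths(current, aln, tol=tol,
                                               max_rounds=2)
                _swap_subtrees(v_, c, a)  # revert
                if cand.loglik > current.loglik + tol and (
                        best_alt is None or cand.loglik > best_alt.loglik):
                    best_alt = cand
            if best_alt is not None:
                current = best_alt
                improved = True
                break
        if not improved:
            return optimize_branch_lengths(current, aln, tol=tol)


def nj_tree(aln: MultipleAlignment) -> PhyloTree:
    """Neighbor-joining tree from JTT distances (complete deletion)."""
    D, labels = distance_matrix(aln)
    return neighbor_joining(D, labels)


# ---------------------------------------------------------------------------
# Bootstrap

def _resample_columns(aln: MultipleAlignment, rng) -> MultipleAlignment:
    idx = rng.integers(0, aln.n_sites, size=aln.n_sites)
    return MultipleAlignment(
        [(name, "".join(seq[k] for k in idx)) for name, seq in aln.rows]
    )


def bootstrap_support(aln: MultipleAlignment, n_reps: int = 1000,
                      seed: int = 0, use_ml: bool = False,
                      point_tree: PhyloTree | None = None) -> PhyloTree:
    """Column-resampling bootstrap.

    Rebuilds a tree per replicate (NJ on JTT distances by default; full
    NNI maximum likelihood when ``use_ml``) and annotates each internal
    edge of the point-estimate tree with the percentage of replicates
    containing that split.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    clean = complete_deletion(aln) if aln.has_gaps() else aln
    if point_tree is None:
        point_tree = nj_tree(clean)
        if use_ml:
            point_tree = ml_search(clean, point_tree)
    point_tree = point_tree.copy()
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    replicate_splits: list[set[frozenset]] = []
    for _ in range(n_reps):
        rep = _resample_columns(clean, rng)
        t = nj_tree(rep)
        if use_ml:
            t = ml_search(rep, t)
        s = t.splits()
        replicate_splits.append(s)
        for sp in s:
            counts[sp] = counts.get(sp, 0) + 1
    all_leaves = frozenset(point_tree.leaf_names())
    ref = min(all_leaves)
    for node in point_tree.internal_edges():
        s = point_tree.split_below(node)
        if not (2 <= len(s) <= len(all_leaves) - 2):
            continue
        canon = s if ref not in s else all_leaves - s
        node.support = 100.0 * counts.get(canon, 0) / n_reps
    point_tree._replicate_splits = replicate_splits  # for consensus building
    return point_tree


def majority_rule_consensus(split_sets: list[set[frozenset]],
                            leaf_names: list[str]) -> PhyloTree:
    """Greedy majority-rule consensus from replicate split sets."""
    n = len(split_sets)
    counts: dict[frozenset, int] = {}
    for s in split_sets:
        for sp in s:
            counts[sp] = counts.get(sp, 0) + 1
    majority = sorted(
        (sp for sp, c in counts.items() if c > n / 2),
        key=lambda sp: (-counts[sp], -len(sp), sorted(sp)),
    )
    accepted: list[frozenset] = []
    for sp in majority:
        if all(sp <= q or q <= sp or not (sp & q) for q in accepted):
            accepted.append(sp)
    root = Node()
    node_for: dict[frozenset, Node] = {}
    for sp in sorted(accepted, key=len, reverse=True):
        node_for[sp] = Node()
        node_for[sp].support = 100.0 * counts[sp] / n
    def owner(item_set):
        best = None
        for sp in accepted:
            if item_set <= sp and (best is None or len(sp) < len(best)):
                best = sp
        return node_for[best] if best is not None else root
    for sp in sorted(accepted, key=len, reverse=True):
        parent_candidates = [q for q in accepted if sp < q]
        parent = (node_for[min(parent_candidates, key=len)]
                  if parent_candidates else root)
        parent.add(node_for[sp])
    for name in leaf_names:
        owner(frozenset([name])).add(Node(name))
    return PhyloTree(root)
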
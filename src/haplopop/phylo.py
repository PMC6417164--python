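"""Haplotype phylogeny.

Hamming distances between haplotype strings, neighbor-joining, Jukes-Cantor
maximum likelihood via Felsenstein's pruning algorithm with a small-scale
topology search (exhaustive enumeration up to 7 taxa, NJ + nearest-neighbor
interchange above), and ancestral-state annotation rooted by the designated
ancestral population's most frequent haplotype.

Trees are lightweight ``Node`` structures; the root of an unrooted tree is a
trifurcation whose own branch length is ignored.  Newick text is produced
directly and parsed back through dendropy.
"""

from __future__ import annotations

import itertools
from copy import deepcopy
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .hapfreq import HaplotypeFrequencyTable
from .panel import SnpPanel

#: branch lengths are bounded away from zero to keep log-probabilities finite
MIN_BRANCH = 1e-9
MAX_BRANCH = 20.0

_STATES = "ACGT"
_STATE_INDEX = {c: i for i, c in enumerate(_STATES)}


class Node:
    """Tree node; ``length`` is the branch above the node (ignored at root)."""

    __slots__ = ("name", "length", "children", "state", "changes")

    def __init__(self, name: Optional[str] = None, length: float = 0.0,
                 children: Optional[list["Node"]] = None):
        self.name = name
        self.length = length
        self.children: list[Node] = children if children is not None else []
        self.state: Optional[str] = None      # filled by ancestral annotation
        self.changes: Optional[list[int]] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def leaves(self) -> list["Node"]:
        return [n for n in self.walk() if n.is_leaf]

    def newick(self, lengths: bool = True) -> str:
        return self._nwk(lengths) + ";"

    def _nwk(self, lengths: bool) -> str:
        if self.is_leaf:
            body = self.name or ""
        else:
            body = "(" + ",".join(c._nwk(lengths) for c in self.children) + ")"
            if self.name:
                body += self.name
        if lengths and self.length is not None:
            body += f":{self.length:.10g}"
        return body


@dataclass
class HaplotypeTree:
    """A haplotype phylogeny plus optional annotations.

    ``leaf_annotations`` maps leaf name -> {"frequencies": {unit: f},
    "risk_load": int}; ``branch_changes`` maps leaf-set keys (sorted tuple of
    the clade's leaf names) -> list of panel positions inferred to change on
    the branch above that clade.
    """

    root: Node
    rooted: bool = False
    leaf_annotations: dict = field(default_factory=dict)
    branch_changes: dict = field(default_factory=dict)

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def newick(self) -> str:
        return self.root.newick()

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions; both sides of each split are included,
        so membership can be tested with either leaf set."""
        all_leaves = frozenset(self.leaf_names)
        out = set()
        for n in self.root.walk():
            if n is self.root or n.is_leaf:
                continue
            side = frozenset(l.name for l in n.leaves())
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
                out.add(all_leaves - side)
        return out

    def path_lengths(self) -> pd.DataFrame:
        """Leaf-to-leaf path-length matrix (sums of branch lengths)."""
        names = sorted(self.leaf_names)
        paths: dict[str, dict[str, float]] = {}

        def walk(node: Node, depth: float, acc: dict):
            if node.is_leaf:
                acc[node.name] = depth
            for c in node.children:
                walk(c, depth + c.length, acc)

        depths: dict[str, float] = {}
        walk(self.root, 0.0, depths)
        D = pd.DataFrame(0.0, index=names, columns=names)

        def lca_fill(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            below: list[dict[str, float]] = []
            for c in node.children:
                sub = lca_fill(c)
                below.append({k: v + c.length for k, v in sub.items()})
            for a, b in itertools.combinations(range(len(below)), 2):
                for la, da in below[a].items():
                    for lb, db in below[b].items():
                        D.loc[la, lb] = D.loc[lb, la] = da + db
            merged: dict[str, float] = {}
            for sub in below:
                merged.update(sub)
            return merged

        lca_fill(self.root)
        return D


def hamming_distance_matrix(
    haplotypes: Sequence[str], normalized: bool = False
) -> pd.DataFrame:
    """Pairwise count (optionally per-site fraction) of differing positions."""
    haps = list(haplotypes)
    if len(haps) < 2:
        raise ValueError("need at least 2 haplotypes")
    if len({len(h) for h in haps}) != 1:
        raise ValueError("haplotypes must have equal length")
    arr = np.frombuffer("".join(haps).encode(), dtype=np.uint8).reshape(len(haps), -1)
    D = (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(float)
    if normalized:
        D /= arr.shape[1]
    return pd.DataFrame(D, index=haps, columns=haps)


def neighbor_joining(distances: pd.DataFrame) -> HaplotypeTree:
    """Saitou-Nei neighbor joining.

    Exact on additive matrices.  A negative pendant length is clamped to zero
    with the deficit moved onto the sibling branch, preserving the pair's
    summed length.
    """
    labels = list(distances.index)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = distances.to_numpy(dtype=float).copy()
    nodes: list[Node] = [Node(name=l) for l in labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = Node(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        dnew = (D[i, :] + D[j, :] - D[i, j]) / 2.0
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = max((dab + dac - dbc) / 2.0, 0.0)
    b.length = max((dab + dbc - dac) / 2.0, 0.0)
    c.length = max((dac + dbc - dab) / 2.0, 0.0)
    return HaplotypeTree(root=Node(children=[a, b, c]), rooted=False)


# ---------------------------------------------------------------------------
# Jukes-Cantor likelihood


def _jc_transition(t: float) -> np.ndarray:
    """JC69 transition matrix: P_same = 1/4 + 3/4 e^{-4t/3}."""
    e = np.exp(-4.0 * max(t, 0.0) / 3.0)
    same = 0.25 + 0.75 * e
    diff = 0.25 - 0.25 * e
    P = np.full((4, 4), diff)
    np.fill_diagonal(P, same)
    return P


def _seq_array(seq: str) -> np.ndarray:
    try:
        codes = [_STATE_INDEX[c] for c in seq]
    except KeyError as exc:
        raise ValueError(f"non-ACGT character in haplotype: {exc}") from exc
    arr = np.zeros((len(seq), 4))
    arr[np.arange(len(seq)), codes] = 1.0
    return arr


def jc_log_likelihood(tree: HaplotypeTree, haplotypes: Union[dict, Sequence[str]]) -> float:
    """Log-likelihood of the haplotype alignment on the tree under JC69.

    Sites are independent with equal base frequencies; the pruning recursion
    runs from the (tri- or bifurcating) root, whose own branch is ignored, so
    the value is invariant to re-rooting.
    """
    seqs = _as_seq_dict(haplotypes)
    leaf_names = set(tree.leaf_names)
    if leaf_names != set(seqs):
        raise ValueError("tree leaves and haplotype set differ")

    def partial(node: Node) -> np.ndarray:
        if node.is_leaf:
            return _seq_array(seqs[node.name])
        M: Optional[np.ndarray] = None
        for c in node.children:
            msg = partial(c) @ _jc_transition(c.length)
            M = msg if M is None else M * msg
        return M

    site_l = (partial(tree.root) * 0.25).sum(axis=1)
    if np.any(site_l <= 0):
        return -np.inf
    return float(np.log(site_l).sum())


def _as_seq_dict(haplotypes: Union[dict, Sequence[str]]) -> dict[str, str]:
    if isinstance(haplotypes, dict):
        return dict(haplotypes)
    return {h: h for h in haplotypes}


def optimize_branch_lengths(
    tree: HaplotypeTree, haplotypes: Union[dict, Sequence[str]], tol: float = 1e-6
) -> float:
    """Coordinate-wise branch-length maximization of the JC likelihood.

    Each branch is optimized in turn by bounded scalar search; passes repeat
    until the likelihood improves by less than ``tol``.  Returns the final
    log-likelihood; the tree is modified in place.
    """
    seqs = _as_seq_dict(haplotypes)
    branches = [n for n in tree.root.walk() if n is not tree.root]
    best = jc_log_likelihood(tree, seqs)
    for _ in range(50):
        for node in branches:
            def neg(t: float, node=node) -> float:
                node.length = t
                return -jc_log_likelihood(tree, seqs)

            res = minimize_scalar(neg, bounds=(MIN_BRANCH, MAX_BRANCH),
                                  method="bounded", options={"xatol": 1e-8})
            node.length = float(res.x)
        new = jc_log_likelihood(tree, seqs)
        if new - best < tol:
            best = max(new, best)
            break
        best = new
    return best


# ---------------------------------------------------------------------------
# topology search


def _enumerate_topologies(names: Sequence[str]) -> Iterator[Node]:
    """All unrooted binary topologies over the taxa, by stepwise insertion."""
    base = Node(children=[Node(name=names[0]), Node(name=names[1]), Node(name=names[2])])

    def insert(root: Node, k: int) -> Iterator[Node]:
        if k == len(names):
            yield root
            return
        edges = [n for n in root.walk() if n is not root]
        for e_idx in range(len(edges)):
            t = deepcopy(root)
            target = [n for n in t.walk() if n is not t][e_idx]
            parent = next(n for n in t.walk() if target in n.children)
            new_internal = Node(children=[target, Node(name=names[k])])
            parent.children[parent.children.index(target)] = new_internal
            yield from insert(t, k + 1)

    yield from insert(base, 3)


def _init_lengths(root: Node, value: float = 0.1) -> None:
    for n in root.walk():
        if n is not root:
            n.length = value


def _nni_neighbors(tree: HaplotypeTree) -> Iterator[HaplotypeTree]:
    """The two nearest-neighbor-interchange rearrangements per internal edge."""
    nodes = list(tree.root.walk())
    for c_idx, cand in enumerate(nodes):
        if cand is tree.root or cand.is_leaf:
            continue
        for a_pos in range(len(cand.children)):
            t = deepcopy(tree.root)
            tnodes = list(t.walk())
            child = tnodes[c_idx]
            parent = next(n for n in t.walk() if child in n.children)
            sibling = next(ch for ch in parent.children if ch is not child)
            a = child.children[a_pos]
            parent.children[parent.children.index(sibling)] = a
            child.children[a_pos] = sibling
            yield HaplotypeTree(root=t, rooted=tree.rooted)


def ml_tree(
    haplotypes: Union[dict, Sequence[str]],
    tol: float = 1e-6,
    exhaustive_limit: int = 7,
) -> HaplotypeTree:
    """Maximum-likelihood JC tree over the haplotypes.

    Up to ``exhaustive_limit`` taxa every unrooted topology is scored after
    branch-length optimization; beyond that an NJ starting tree is improved by
    NNI hill climbing.  Ties in likelihood (within 1e-9) break toward the
    lexicographically smallest Newick string, making the result deterministic.
    """
    seqs = _as_seq_dict(haplotypes)
    names = sorted(seqs)
    if not 3 <= len(names) <= 12:
        raise ValueError("ml_tree supports 3..12 haplotypes")

    def canon(tree: HaplotypeTree) -> str:
        return _canonical_newick(tree.root)

    if len(names) <= exhaustive_limit:
        best: Optional[HaplotypeTree] = None
        best_lnl = -np.inf
        best_key = ""
        for topo in _enumerate_topologies(names):
            _init_lengths(topo)
            tree = HaplotypeTree(root=topo, rooted=False)
            lnl = optimize_branch_lengths(tree, seqs, tol=tol)
            key = canon(tree)
            if lnl > best_lnl + 1e-9 or (abs(lnl - best_lnl) <= 1e-9 and key < best_key):
                best, best_lnl, best_key = tree, lnl, key
        assert best is not None
        return best

    dm = hamming_distance_matrix(
        [seqs[n] for n in names]
    )
    dm.index = dm.columns = names
    tree = neighbor_joining(dm)
    best_lnl = optimize_branch_lengths(tree, seqs, tol=tol)
    improved = True
    while improved:
        improved = False
        for cand in _nni_neighbors(tree):
            _init_lengths(cand.root)
            lnl = optimize_branch_lengths(cand, seqs, tol=tol)
            if lnl > best_lnl + 1e-9:
                tree, best_lnl = cand, lnl
                improved = True
                break
    return tree


def _canonical_newick(root: Node) -> str:
    def render(n: Node) -> str:
        if n.is_leaf:
            return n.name or ""
        parts = sorted(render(c) for c in n.children)
        return "(" + ",".join(parts) + ")"

    return render(root) + ";"


# ---------------------------------------------------------------------------
# rooting and ancestral states


def _adjacency(root: Node) -> dict[int, list[tuple[Node, float]]]:
    adj: dict[int, list[tuple[Node, float]]] = {}

    def add(a: Node, b: Node, w: float) -> None:
        adj.setdefault(id(a), []).append((b, w))
        adj.setdefault(id(b), []).append((a, w))

    def walk(n: Node) -> None:
        for c in n.children:
            add(n, c, c.length)
            walk(c)

    walk(root)
    return adj


def reroot_on_leaf_branch(tree: HaplotypeTree, leaf_name: str) -> HaplotypeTree:
    """Root the tree at the midpoint of the named leaf's pendant branch."""
    leaf = next((n for n in tree.root.leaves() if n.name == leaf_name), None)
    if leaf is None:
        raise ValueError(f"leaf {leaf_name!r} not in tree")
    adj = _adjacency(tree.root)
    (attach, w) = adj[id(leaf)][0]

    def build(node: Node, prev: Node) -> Node:
        fresh = Node(name=node.name)
        for nbr, length in adj[id(node)]:
            if nbr is prev:
                continue
            child = build(nbr, node)
            child.length = max(length, 0.0) + child.length
            fresh.children.append(child)
        # collapse unary pass-through nodes created by removing the old root
        if len(fresh.children) == 1 and fresh.name is None:
            only = fresh.children[0]
            return only
        return fresh

    new_root = Node()
    left = Node(name=leaf.name, length=w / 2.0)
    right = build(attach, leaf)
    right.length = w / 2.0 + right.length  # includes any collapsed unary edge
    new_root.children = [left, right]
    return HaplotypeTree(root=new_root, rooted=True,
                         leaf_annotations=dict(tree.leaf_annotations))


def _fitch(tree: HaplotypeTree, seqs: dict[str, str], prefer_root: str) -> None:
    """Fitch parsimony ancestral states; ties resolve toward the parent state
    (at the root, toward ``prefer_root``, else lexicographically)."""
    L = len(next(iter(seqs.values())))
    sets: dict[int, list[set]] = {}

    def up(node: Node) -> list[set]:
        if node.is_leaf:
            s = [{c} for c in seqs[node.name]]
        else:
            children_sets = [up(c) for c in node.children]
            s = []
            for i in range(L):
                inter = set.intersection(*(cs[i] for cs in children_sets))
                s.append(inter if inter else set.union(*(cs[i] for cs in children_sets)))
        sets[id(node)] = s
        return s

    up(tree.root)

    def pick(options: set, preferred: str) -> str:
        return preferred if preferred in options else min(options)

    root_state = "".join(
        pick(sets[id(tree.root)][i], prefer_root[i]) for i in range(L)
    )
    tree.root.state = root_state

    def down(node: Node) -> None:
        for c in node.children:
            if c.is_leaf:
                c.state = seqs[c.name]
            else:
                c.state = "".join(
                    pick(sets[id(c)][i], node.state[i]) for i in range(L)
                )
            down(c)

    down(tree.root)


def annotate_ancestral(
    tree: HaplotypeTree,
    table: HaplotypeFrequencyTable,
    ancestral_unit: str,
    panel: Optional[SnpPanel] = None,
) -> HaplotypeTree:
    """Root on the haplotype most frequent in the ancestral unit and annotate.

    Internal states come from Fitch parsimony (ties resolved toward the
    parent, and at the root toward the ancestral-unit leaf); every branch is
    annotated with the panel positions whose state changes along it, and every
    leaf with its per-unit frequencies (plus risk load when a panel is given).
    Ties in the ancestral frequency break to the lexicographically smallest
    haplotype.
    """
    if ancestral_unit not in table.units:
        raise ValueError(f"ancestral unit {ancestral_unit!r} not in table")
    leaf_names = set(tree.leaf_names)
    freqs = table.freq.loc[[h for h in table.haplotypes if h in leaf_names], ancestral_unit]
    if freqs.empty:
        raise ValueError("no tree leaf appears in the frequency table")
    top = freqs[freqs == freqs.max()].index.min()

    rooted = reroot_on_leaf_branch(tree, top)
    seqs = {name: name for name in rooted.leaf_names}
    _fitch(rooted, seqs, prefer_root=top)

    positions = table.positions
    branch_changes = {}
    for node in rooted.root.walk():
        if node is rooted.root:
            continue
        parent = next(n for n in rooted.root.walk() if node in n.children)
        node.changes = [
            positions[i] for i in range(len(positions))
            if parent.state is not None and node.state[i] != parent.state[i]
        ]
        key = tuple(sorted(l.name for l in node.leaves()))
        branch_changes[key] = list(node.changes)

    recs = panel.subset(positions) if panel is not None else None
    leaf_ann = {}
    for name in rooted.leaf_names:
        ann = {"frequencies": (
            table.freq.loc[name].to_dict() if name in table.freq.index else {}
        )}
        if recs is not None:
            ann["risk_load"] = sum(1 for r, c in zip(recs, name) if c == r.risk_allele)
        leaf_ann[name] = ann

    rooted.branch_changes = branch_changes
    rooted.leaf_annotations = leaf_ann
    return rooted


# ---------------------------------------------------------------------------
# Newick I/O


def tree_from_newick(text: str) -> HaplotypeTree:
    """Parse Newick via dendropy into the local node structure."""
    import dendropy

    dtree = dendropy.Tree.get(data=text, schema="newick")

    def convert(dnode) -> Node:
        n = Node(
            name=dnode.taxon.label if dnode.taxon else None,
            length=dnode.edge.length if dnode.edge.length is not None else 0.0,
        )
        n.children = [convert(c) for c in dnode.child_nodes()]
        return n

    root = convert(dtree.seed_node)
    return HaplotypeTree(root=root, rooted=len(root.children) == 2)


def write_newick(tree: HaplotypeTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")
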
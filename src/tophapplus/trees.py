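"""Rooted clone trees, maximum-parsimony inference and mutation events.

A :class:`CloneTree` is a rooted tree whose root is the germline (all
wild-type) state.  Nodes may carry binary genotype vectors over a shared
site list, and each edge (identified by its child node) carries the list of
:class:`MutationEvent` objects — gains (wild -> mutant) or losses
(mutant -> wild) — that separate child from parent.  The same class serves
as the "mutation tree" view after zero-event edges are contracted.

Topology inference is plain maximum parsimony: stepwise addition of
haplotypes in decreasing support order scored by the Fitch algorithm,
followed by nearest-neighbour-interchange hill climbing.  Ancestral states
are reconstructed by Fitch with the root clamped to the germline state and
ties in the top-down pass resolved toward the parent's state, which avoids
spurious event toggling along root-to-tip paths.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .genotype_io import MUT, WILD

GAIN = "GAIN"
LOSS = "LOSS"

GERMLINE = "germline"


@dataclass(frozen=True)
class MutationEvent:
    """A state change at one site on one edge of the clone tree."""

    site_id: str
    direction: str  # GAIN or LOSS

    def __post_init__(self) -> None:
        if self.direction not in (GAIN, LOSS):
            raise ValueError(f"direction must be GAIN or LOSS, got {self.direction!r}")


class CloneTree:
    """Rooted tree with per-node genotypes and per-edge mutation events.

    ``events[child]`` holds the events on the edge parent -> child.
    Node order in ``preorder()`` is deterministic (children keep insertion
    order), which downstream tie-breaking relies on.
    """

    def __init__(self, root: str, site_ids: list[str]):
        self.root = root
        self.site_ids = list(site_ids)
        self.parent: dict[str, str | None] = {root: None}
        self.children: dict[str, list[str]] = {root: []}
        self.genotypes: dict[str, np.ndarray] = {}
        self.events: dict[str, list[MutationEvent]] = {}

    # -- construction ------------------------------------------------------
    def add_node(self, node: str, parent: str, genotype: np.ndarray | None = None,
                 events: list[MutationEvent] | None = None) -> None:
        if node in self.parent:
            raise ValueError(f"node {node!r} already in tree")
        if parent not in self.parent:
            raise ValueError(f"parent {parent!r} not in tree")
        self.parent[node] = parent
        self.children[node] = []
        self.children[parent].append(node)
        if genotype is not None:
            self.genotypes[node] = np.asarray(genotype, dtype=np.int8)
        self.events[node] = list(events or [])

    def remove_subtree(self, node: str) -> list[str]:
        """Detach and delete the subtree rooted at ``node``; returns removed ids."""
        if node == self.root:
            raise ValueError("cannot remove the root")
        removed = list(self.subtree(node))
        self.children[self.parent[node]].remove(node)
        for n in removed:
            self.parent.pop(n)
            self.children.pop(n)
            self.genotypes.pop(n, None)
            self.events.pop(n, None)
        return removed

    def copy(self) -> "CloneTree":
        t = CloneTree(self.root, self.site_ids)
        t.parent = dict(self.parent)
        t.children = {k: list(v) for k, v in self.children.items()}
        t.genotypes = {k: v.copy() for k, v in self.genotypes.items()}
        t.events = {k: list(v) for k, v in self.events.items()}
        return t

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[str]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(self.children[n]))

    def postorder(self) -> Iterator[str]:
        out = list(self.preorder())
        return iter(reversed(out))

    def subtree(self, node: str) -> Iterator[str]:
        stack = [node]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(self.children[n]))

    def tips(self) -> list[str]:
        return [n for n in self.preorder() if not self.children[n]]

    def depth(self, node: str) -> int:
        d = 0
        while self.parent[node] is not None:
            node = self.parent[node]
            d += 1
        return d

    def path_from_root(self, node: str) -> list[str]:
        path = []
        while node is not None:
            path.append(node)
            node = self.parent[node]
        return path[::-1]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def validate(self) -> None:
        """Check rootedness, acyclicity and genotype/event consistency."""
        seen = list(self.preorder())
        if len(seen) != len(self.parent) or len(set(seen)) != len(seen):
            raise ValueError("tree is not a single connected rooted tree")
        g_root = self.genotypes.get(self.root)
        if g_root is not None and np.any(g_root != WILD):
            raise ValueError("root genotype must be all wild-type")
        for child, evs in self.events.items():
            if child == self.root:
                continue
            gp = self.genotypes.get(self.parent[child])
            gc = self.genotypes.get(child)
            if gp is None or gc is None:
                continue
            expect = gp.copy()
            for e in evs:
                j = self.site_ids.index(e.site_id)
                if e.direction == GAIN:
                    if expect[j] != WILD:
                        raise ValueError(f"GAIN at {e.site_id} but parent not wild")
                    expect[j] = MUT
                else:
                    if expect[j] != MUT:
                        raise ValueError(f"LOSS at {e.site_id} but parent not mutant")
                    expect[j] = WILD
            if not np.array_equal(expect, gc):
                raise ValueError(f"genotype of {child!r} inconsistent with edge events")

    def total_events(self) -> int:
        return sum(len(v) for v in self.events.values())


# ---------------------------------------------------------------------------
# Fitch small parsimony on binary characters
# ---------------------------------------------------------------------------

_WILD_BIT = 1
_MUT_BIT = 2
_BOTH = 3


def _tip_masks(genotype: np.ndarray) -> np.ndarray:
    """State-set bitmasks for one tip: wild->{W}, mut->{M}, missing->{W,M}."""
    m = np.full(genotype.shape, _BOTH, dtype=np.uint8)
    m[genotype == WILD] = _WILD_BIT
    m[genotype == MUT] = _MUT_BIT
    return m


def fitch_score(children: dict[str, list[str]], root: str,
                tip_sets: dict[str, np.ndarray]) -> int:
    """Parsimony score (number of state changes) of a rooted tree.

    ``tip_sets`` maps each tip to its bitmask vector.  The germline
    constraint is honoured by including the germline as a tip; the Fitch
    union count equals the minimum number of changes.
    """
    score = 0
    sets: dict[str, np.ndarray] = {}
    order = []
    stack = [root]
    while stack:
        n = stack.pop()
        order.append(n)
        stack.extend(children.get(n, ()))
    for n in reversed(order):
        kids = children.get(n, ())
        if not kids:
            sets[n] = tip_sets[n]
            continue
        inter = sets[kids[0]].copy()
        union = sets[kids[0]].copy()
        for k in kids[1:]:
            inter &= sets[k]
            union |= sets[k]
        empty = inter == 0
        score += int(empty.sum())
        inter[empty] = union[empty]
        sets[n] = inter
    return score


def fitch_reconstruct(tree: CloneTree, tip_genotypes: dict[str, np.ndarray]) -> None:
    """Assign parsimonious ancestral genotypes in place; populate edge events.

    Exact min-change dynamic programming (unit-cost Sankoff on the two
    states, valid on multifurcating trees), with the root clamped to all
    wild-type.  In the top-down pass, whenever keeping the parent's state is
    as parsimonious as switching, the parent's state is kept — this
    parent-preference tie-break minimises spurious event toggling along
    root-to-tip paths, e.g. preferring two independent gains over a gain
    followed by a loss when both are equally parsimonious.
    """
    n_sites = len(tree.site_ids)
    BIG = np.float32(1e9)
    cost: dict[str, np.ndarray] = {}  # node -> (n_sites, 2) subtree cost per state
    for n in tree.postorder():
        kids = tree.children[n]
        if not kids:
            g = tip_genotypes.get(n)
            if g is None:
                raise ValueError(f"tip {n!r} has no genotype")
            g = np.asarray(g, dtype=np.int8)
            c = np.zeros((n_sites, 2), dtype=np.float32)
            c[g == WILD, 1] = BIG
            c[g == MUT, 0] = BIG
            cost[n] = c
            continue
        c = np.zeros((n_sites, 2), dtype=np.float32)
        for k in kids:
            ck = cost[k]
            c[:, 0] += np.minimum(ck[:, 0], ck[:, 1] + 1)
            c[:, 1] += np.minimum(ck[:, 1], ck[:, 0] + 1)
        cost[n] = c

    states: dict[str, np.ndarray] = {}
    states[tree.root] = np.full(n_sites, WILD, dtype=np.int8)
    for n in tree.preorder():
        if n == tree.root:
            continue
        p_state = states[tree.parent[n]]
        c = cost[n]
        # cost of taking state s here, given the parent's state
        keep_cost = np.take_along_axis(c, p_state[:, None].astype(np.intp), 1)[:, 0]
        switch_state = (1 - p_state).astype(np.intp)
        switch_cost = np.take_along_axis(c, switch_state[:, None], 1)[:, 0] + 1
        out = np.where(switch_cost < keep_cost, 1 - p_state, p_state).astype(np.int8)
        states[n] = out

    for n in tree.preorder():
        tree.genotypes[n] = states[n]
        if n == tree.root:
            continue
        p_state = states[tree.parent[n]]
        evs: list[MutationEvent] = []
        diff = np.nonzero(states[n] != p_state)[0]
        for j in diff:
            if p_state[j] == WILD:
                evs.append(MutationEvent(tree.site_ids[j], GAIN))
            else:
                evs.append(MutationEvent(tree.site_ids[j], LOSS))
        tree.events[n] = evs
    tree.events[tree.root] = []


# ---------------------------------------------------------------------------
# Topology search: stepwise addition + NNI, scored by Fitch
# ---------------------------------------------------------------------------


class _SearchTree:
    """Mutable rooted binary tree used only during topology search."""

    def __init__(self) -> None:
        self.children: dict[int, list[int]] = {}
        self.parent: dict[int, int | None] = {}
        self.label: dict[int, str] = {}
        self._next = 0

    def new_node(self, label: str | None = None) -> int:
        n = self._next
        self._next += 1
        self.children[n] = []
        self.parent[n] = None
        if label is not None:
            self.label[n] = label
        return n

    def edges(self) -> list[tuple[int, int]]:
        return [(self.parent[c], c) for c in self.parent if self.parent[c] is not None]


def _score_search_tree(st: _SearchTree, root: int, tip_sets: dict[str, np.ndarray]) -> int:
    sets = {n: tip_sets[lbl] for n, lbl in st.label.items()}
    return fitch_score(st.children, root, sets)


def infer_topology(haplotypes: dict[str, np.ndarray], supports: dict[str, int] | None = None,
                   nni: bool = True, site_ids: list[str] | None = None) -> CloneTree:
    """Maximum-parsimony topology over haplotypes, rooted at the germline.

    Parameters
    ----------
    haplotypes : dict
        Haplotype id -> binary genotype vector.  Must contain the germline
        (all wild-type) haplotype under the id ``"germline"``.
    supports : dict, optional
        Cell support per haplotype; tips are added in decreasing support
        order (ties broken by genotype bytes then id) so the search is
        deterministic.  Defaults to equal supports.
    nni : bool
        Run nearest-neighbour-interchange hill climbing after stepwise
        addition.

    Returns
    -------
    CloneTree
        Rooted at ``germline``; internal nodes are named ``anc<k>`` and carry
        no genotypes yet (see :func:`fitch_reconstruct`).
    """
    if GERMLINE not in haplotypes:
        raise ValueError("haplotypes must include the germline")
    if site_ids is None:
        site_ids = [f"s{j}" for j in range(len(next(iter(haplotypes.values()))))]
    names = list(haplotypes)
    if supports is None:
        supports = {h: 1 for h in names}
    order = sorted(
        (h for h in names if h != GERMLINE),
        key=lambda h: (-supports.get(h, 0), haplotypes[h].tobytes(), h),
    )
    order = [GERMLINE] + order
    tip_sets = {h: _tip_masks(np.asarray(haplotypes[h], dtype=np.int8)) for h in names}

    st = _SearchTree()
    if len(order) == 1:
        raise ValueError("need at least two haplotypes (germline plus one)")
    if len(order) == 2:
        ct = CloneTree(GERMLINE, site_ids)
        ct.add_node(order[1], GERMLINE)
        ct.genotypes[GERMLINE] = np.full(len(site_ids), WILD, dtype=np.int8)
        return ct

    root = st.new_node()
    a = st.new_node(order[0])
    b = st.new_node(order[1])
    for c in (a, b):
        st.children[root].append(c)
        st.parent[c] = root

    for tip_name in order[2:]:
        best = None
        for (u, v) in st.edges():
            # splice: u -> w -> {v, new tip}
            w = st.new_node()
            t = st.new_node(tip_name)
            st.children[u][st.children[u].index(v)] = w
            st.parent[w] = u
            st.children[w] = [v, t]
            st.parent[v] = w
            st.parent[t] = w
            s = _score_search_tree(st, root, tip_sets)
            if best is None or s < best[0]:
                best = (s, u, v)
            # undo
            st.children[u][st.children[u].index(w)] = v
            st.parent[v] = u
            for n in (w, t):
                st.children.pop(n)
                st.parent.pop(n)
                st.label.pop(n, None)
        _, u, v = best
        w = st.new_node()
        t = st.new_node(tip_name)
        st.children[u][st.children[u].index(v)] = w
        st.parent[w] = u
        st.children[w] = [v, t]
        st.parent[v] = w
        st.parent[t] = w

    if nni:
        _nni_hill_climb(st, root, tip_sets)

    return _reroot_at_germline(st, root, site_ids)


def _nni_hill_climb(st: _SearchTree, root: int, tip_sets: dict[str, np.ndarray],
                    max_rounds: int = 50) -> None:
    """Accept strictly score-improving NNI moves until none remains."""
    cur = _score_search_tree(st, root, tip_sets)
    for _ in range(max_rounds):
        improved = False
        for (u, v) in list(st.edges()):
            if v not in st.children or not st.children.get(v):
                continue  # v is a tip
            if u == root and len(st.children[root]) < 2:
                continue
            sibs = [c for c in st.children[u] if c != v]
            if not sibs:
                continue
            c_node = sibs[0]
            for child in list(st.children[v]):
                # swap child <-> c_node
                st.children[v][st.children[v].index(child)] = c_node
                st.children[u][st.children[u].index(c_node)] = child
                st.parent[c_node] = v
                st.parent[child] = u
                s = _score_search_tree(st, root, tip_sets)
                if s < cur:
                    cur = s
                    improved = True
                    break
                # undo
                st.children[v][st.children[v].index(c_node)] = child
                st.children[u][st.children[u].index(child)] = c_node
                st.parent[c_node] = u
                st.parent[child] = v
            if improved:
                break
        if not improved:
            return


def _reroot_at_germline(st: _SearchTree, old_root: int, site_ids: list[str]) -> CloneTree:
    """Orient edges away from the germline tip and suppress degree-2 nodes."""
    adj: dict[int, list[int]] = {n: [] for n in st.parent}
    for (u, v) in st.edges():
        adj[u].append(v)
        adj[v].append(u)
    germ_node = next(n for n, lbl in st.label.items() if lbl == GERMLINE)

    ct = CloneTree(GERMLINE, site_ids)
    counter = itertools.count(1)

    def name_of(n: int) -> str:
        return st.label.get(n) or f"anc{next(counter)}"

    names: dict[int, str] = {germ_node: GERMLINE}

    def build(n: int, prev: int, parent_name: str) -> None:
        nbrs = [x for x in adj[n] if x != prev]
        # suppress degree-2 unlabeled nodes (the old pseudo-root)
        while n not in st.label and len(nbrs) == 1:
            prev, n = n, nbrs[0]
            nbrs = [x for x in adj[n] if x != prev]
        nm = names.setdefault(n, name_of(n))
        ct.add_node(nm, parent_name)
        for x in nbrs:
            build(x, n, nm)

    first = adj[germ_node][0]
    build(first, germ_node, GERMLINE)
    return ct


# ---------------------------------------------------------------------------
# Mutation-tree view
# ---------------------------------------------------------------------------


def induced_mutation_tree(tree: CloneTree) -> CloneTree:
    """Contract zero-event edges to obtain the mutation tree.

    Internal zero-event edges are contracted (children reattach to the
    grandparent).  A tip whose incoming edge carries no events is genotype-
    identical to its parent: its label is merged onto the parent node (the
    clone is a sampled ancestor), keeping clone sequences unique.
    """
    t = tree.copy()
    changed = True
    while changed:
        changed = False
        for n in list(t.preorder()):
            if n == t.root or t.events.get(n):
                continue
            parent = t.parent[n]
            kids = list(t.children[n])
            if kids:
                # internal zero-event edge: contract, keep the more
                # informative (labeled haplotype) name if present
                keep_name = n if not n.startswith("anc") else parent
                for k in kids:
                    t.children[n].remove(k)
                    t.children[parent].append(k)
                    t.parent[k] = parent
                t.children[parent].remove(n)
                t.parent.pop(n)
                t.children.pop(n)
                g = t.genotypes.pop(n, None)
                t.events.pop(n, None)
                if keep_name == n and parent != t.root:
                    _rename_node(t, parent, n, g)
                changed = True
                break
            else:
                # zero-event tip: merge label into parent
                if parent == t.root:
                    # all-wild haplotype duplicates the germline root; drop it
                    t.remove_subtree(n)
                    changed = True
                    break
                g = t.genotypes.get(n)
                t.remove_subtree(n)
                if parent.startswith("anc"):
                    _rename_node(t, parent, n, g)
                changed = True
                break
    return t


def _rename_node(t: CloneTree, old: str, new: str, genotype: np.ndarray | None) -> None:
    if new in t.parent:
        return
    p = t.parent.pop(old)
    t.parent[new] = p
    if p is not None:
        t.children[p][t.children[p].index(old)] = new
    else:
        t.root = new
    t.children[new] = t.children.pop(old)
    for k in t.children[new]:
        t.parent[k] = new
    if old in t.genotypes:
        t.genotypes[new] = t.genotypes.pop(old)
    elif genotype is not None:
        t.genotypes[new] = genotype
    if old in t.events:
        t.events[new] = t.events.pop(old)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def _quote(label: str) -> str:
    if any(c in label for c in "():;, \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: CloneTree, branch_lengths: str = "events") -> str:
    """Serialize to Newick; branch length = number of events on the edge."""

    def rec(n: str) -> str:
        kids = tree.children[n]
        inner = "(" + ",".join(rec(k) for k in kids) + ")" if kids else ""
        bl = ""
        if branch_lengths == "events" and tree.parent[n] is not None:
            bl = f":{len(tree.events.get(n, []))}"
        return f"{inner}{_quote(n)}{bl}"

    return rec(tree.root) + ";"


def read_newick(text_or_path: str) -> CloneTree:
    """Parse a single rooted Newick tree into a bare CloneTree (no genotypes)."""
    import dendropy

    s = str(text_or_path)
    if "(" not in s:  # looks like a path
        s = open(s).read()
    dt = dendropy.Tree.get(data=s, schema="newick", rooting="force-rooted")
    counter = itertools.count(1)

    def node_name(nd) -> str:
        if nd.taxon is not None and nd.taxon.label:
            return nd.taxon.label
        if nd.label:
            return nd.label
        return f"anc{next(counter)}"

    root_name = node_name(dt.seed_node)
    ct = CloneTree(root_name, [])
    def build(nd, parent_name):
        for ch in nd.child_nodes():
            nm = node_name(ch)
            ct.add_node(nm, parent_name)
            build(ch, nm)
    build(dt.seed_node, root_name)
    return ct


def edge_list(tree: CloneTree) -> list[tuple[str, str, str]]:
    """(parent, child, comma-joined events) rows for TSV export."""
    rows = []
    for n in tree.preorder():
        if n == tree.root:
            continue
        evs = ";".join(f"{e.direction}:{e.site_id}" for e in tree.events.get(n, []))
        rows.append((tree.parent[n], n, evs))
    return rows
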
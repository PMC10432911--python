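"""Accuracy metrics: Robinson-Foulds distance with clone pairing.

Simulated and inferred clone phylogenies rarely share a tip set: clones can
be missed, split, merged or invented.  The evaluation therefore (1) pairs
each true clone with the inferred clone holding the plurality of its cells
(an inferred clone may absorb several true clones), (2) duplicates inferred
tips involved in many-to-one pairings as zero-length cherries so both trees
have the same tips, (3) prunes unpaired tips from both trees, and
(4) computes the bipartition symmetric difference, adding one penalty per
true clone left without an inferred pair (its partition is "not found" in
the inferred phylogeny).  The clone-count error — inferred clones with at
least one cell minus simulated clones — is reported alongside, since RF
alone cannot express size errors.
"""

from __future__ import annotations

from dataclasses import dataclass

from .trees import CloneTree

NONE_PAIR = "NONE"


@dataclass(frozen=True)
class CladeMetrics:
    rf_distance: int
    n_true_partitions: int
    n_inferred_partitions: int
    unpaired_true_clones: int
    clone_count_error: int
    degenerate: bool = False


def pair_clones(true_assignment: dict[str, str],
                inferred_assignment: dict[str, str]) -> dict[str, str]:
    """Map each true clone to the inferred clone holding most of its cells.

    Ties break toward the larger inferred clone, then lexicographic id.
    True clones none of whose cells appear in the inferred assignment map
    to ``NONE``.
    """
    inf_sizes: dict[str, int] = {}
    for c in inferred_assignment.values():
        inf_sizes[c] = inf_sizes.get(c, 0) + 1

    by_true: dict[str, dict[str, int]] = {}
    for cell, tc in true_assignment.items():
        by_true.setdefault(tc, {})
        ic = inferred_assignment.get(cell)
        if ic is not None:
            by_true[tc][ic] = by_true[tc].get(ic, 0) + 1

    pairing: dict[str, str] = {}
    for tc, counts in by_true.items():
        if not counts:
            pairing[tc] = NONE_PAIR
            continue
        best = sorted(counts, key=lambda ic: (-counts[ic], -inf_sizes.get(ic, 0), ic))[0]
        pairing[tc] = best
    return pairing


def _bipartitions(parent: dict[str, str | None], children: dict[str, list[str]],
                  root: str, tips: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, each as the smaller-canonical side."""
    out: set[frozenset[str]] = set()

    tipsets: dict[str, frozenset[str]] = {}
    order = []
    stack = [root]
    while stack:
        n = stack.pop()
        order.append(n)
        stack.extend(children.get(n, ()))
    for n in reversed(order):
        kids = children.get(n, [])
        if not kids:
            tipsets[n] = frozenset([n])
        else:
            s: set[str] = set()
            for k in kids:
                s |= tipsets[k]
            tipsets[n] = frozenset(s)
    for n in order:
        if parent.get(n) is None:
            continue
        side = tipsets[n]
        if len(side) < 2 or len(tips - side) < 2:
            continue  # trivial split
        other = tips - side
        out.add(min(side, other, key=lambda x: (len(x), sorted(x))))
    return out


def _prune_to_tips(tree: CloneTree, keep_tips: set[str]) -> tuple[dict, dict, str]:
    """Topology restricted to ``keep_tips`` with degree-2 nodes suppressed."""
    parent: dict[str, str | None] = {}
    children: dict[str, list[str]] = {}

    def build(n: str) -> str | None:
        kids = [build(k) for k in tree.children[n]]
        kids = [k for k in kids if k is not None]
        is_tip = not tree.children[n]
        if is_tip:
            if n in keep_tips:
                parent[n] = None
                children[n] = []
                return n
            return None
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]  # suppress degree-2
        children[n] = kids
        parent[n] = None
        for k in kids:
            parent[k] = n
        return n

    root = build(tree.root)
    if root is None:
        raise ValueError("no tips left after pruning")
    return parent, children, root


def clone_tree_with_tip_clones(tree: CloneTree, clone_ids: set[str]) -> CloneTree:
    """Represent internal sampled clones as pendant tips.

    RF compares tip partitions, so a clone sitting at an internal node gets
    a zero-length pendant tip carrying its id (sampled-ancestor
    convention); the internal node is renamed to an anonymous ancestor.
    """
    t = tree.copy()
    for n in list(t.preorder()):
        if n in clone_ids and t.children[n]:
            tip = f"{n}"
            anon = f"int_{n}"
            # rename internal node, then hang the labeled tip below it
            from .trees import _rename_node
            _rename_node(t, n, anon, t.genotypes.get(n))
            t.add_node(tip, anon)
    return t


def rf_with_pairing(true_tree: CloneTree, inferred_tree: CloneTree,
                    pairing: dict[str, str],
                    n_inferred_clones: int | None = None) -> CladeMetrics:
    """Paired Robinson-Foulds distance between true and inferred clone trees.

    Both trees must present clones as tips (see
    :func:`clone_tree_with_tip_clones`).  ``pairing`` maps true clone ids to
    inferred tip ids (or ``NONE``).
    """
    unpaired = [tc for tc, ic in pairing.items() if ic == NONE_PAIR]
    paired = {tc: ic for tc, ic in pairing.items() if ic != NONE_PAIR}

    # true tree: keep paired true clones
    keep_true = set(paired)
    tp, tc_, troot = _prune_to_tips(true_tree, keep_true)
    true_tips = frozenset(keep_true)

    # inferred tree: expand many-to-one tips into cherries labeled by the
    # paired true clones, drop unpaired inferred tips
    by_inferred: dict[str, list[str]] = {}
    for t_clone, i_clone in paired.items():
        by_inferred.setdefault(i_clone, []).append(t_clone)
    inf = inferred_tree.copy()
    for i_clone, t_clones in sorted(by_inferred.items()):
        t_clones = sorted(t_clones)
        if len(t_clones) == 1 and t_clones[0] == i_clone:
            continue
        if len(t_clones) == 1:
            from .trees import _rename_node
            _rename_node(inf, i_clone, t_clones[0], inf.genotypes.get(i_clone))
        else:
            from .trees import _rename_node
            holder = f"dup_{i_clone}"
            _rename_node(inf, i_clone, holder, inf.genotypes.get(i_clone))
            for tcl in t_clones:
                inf.add_node(tcl, holder)
    ip, ic_, iroot = _prune_to_tips(inf, set(keep_true))

    degenerate = len(keep_true) < 3
    b_true = _bipartitions(tp, tc_, troot, true_tips)
    b_inf = _bipartitions(ip, ic_, iroot, true_tips)
    rf = len(b_true ^ b_inf) + len(unpaired)

    if n_inferred_clones is None:
        n_inferred_clones = len({ic for ic in pairing.values() if ic != NONE_PAIR})
    return CladeMetrics(
        rf_distance=rf,
        n_true_partitions=len(b_true),
        n_inferred_partitions=len(b_inf),
        unpaired_true_clones=len(unpaired),
        clone_count_error=n_inferred_clones - len(pairing),
        degenerate=degenerate,
    )


def clone_count_error(n_true_clones: int, inferred_assignment: dict[str, str]) -> int:
    """Inferred clones with at least one assigned cell, minus true clones."""
    return len(set(inferred_assignment.values())) - n_true_clones


def spurious_clone_count(true_assignment: dict[str, str],
                         inferred_assignment: dict[str, str]) -> int:
    """Inferred clones not paired with any simulated clone."""
    pairing = pair_clones(true_assignment, inferred_assignment)
    paired_inferred = {ic for ic in pairing.values() if ic != NONE_PAIR}
    all_inferred = set(inferred_assignment.values())
    return len(all_inferred - paired_inferred)
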
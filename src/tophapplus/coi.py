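"""Mutation co-occurrence scoring, pruning and reattachment.

The co-occurrence index (COI) of an (ancestor, descendant) mutation pair is
the fraction of descendant-mutation carriers that also carry the ancestral
mutation:

    COI = C_ad / C_*d

where ``C_*d`` counts cells observed mutant at the descendant site (with a
non-missing call at the ancestor site) and ``C_ad`` counts those among them
also mutant at the ancestor site.  If the mutation tree places ``d`` below
``a`` correctly, COI should be near 1; a low COI flags a spuriously placed
branch.  All COI values are computed on the originally observed matrix —
never on refined or imputed calls — so imputation bias cannot leak into the
ordering assessment.

Branches whose (event-averaged) COI against their parent branch falls below
a prune cutoff (default 0.3) are removed with their whole subtree; the
removed mutations, together with every mutation absent from the tree (down
to a two-carrier floor, including sites below the original VAF threshold),
re-enter as candidates and are attached back greedily — highest carrier
count first, each at the deepest position whose COI exceeds the attach
cutoff (default 0.4).  This is how low-frequency clones excluded by the
haplotype-frequency filter are recovered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeMatrix, MISSING, MUT, WILD
from .trees import CloneTree, GAIN, LOSS, MutationEvent

DEFAULT_PRUNE_CUTOFF = 0.3
DEFAULT_ATTACH_CUTOFF = 0.4
DEFAULT_ATTACH_FLOOR = 2


@dataclass(frozen=True)
class COIRecord:
    """COI for one (ancestor, descendant) mutation pair with its counts.

    ``no_support`` marks pairs with zero scoreable descendant carriers;
    such a record fails any threshold and contributes 0 to averages.
    """

    ancestor: str
    descendant: str
    c_ad: int
    c_star_d: int

    @property
    def no_support(self) -> bool:
        return self.c_star_d == 0

    @property
    def coi(self) -> float:
        if self.no_support:
            return 0.0
        return self.c_ad / self.c_star_d


def _event_masks(event: MutationEvent, tree: CloneTree | None, branch: str | None,
                 raw: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(carriers, observed) cell masks for an event on the raw matrix.

    For a GAIN, carriers are cells called mutant at the site.  For a LOSS,
    carrying the event means showing the derived (wild-type) state at the
    lost site while being mutant at a context marker — a gain on the same
    branch, or failing that on the parent branch — so reversal carriers are
    distinguished from never-mutated cells.
    """
    j = raw.site_ids.index(event.site_id)
    col = raw.data[:, j]
    if event.direction == GAIN:
        return col == MUT, col != MISSING
    # LOSS: need a gain context
    context = None
    if tree is not None and branch is not None:
        node = branch
        while node is not None and context is None:
            for e in tree.events.get(node, []):
                if e.direction == GAIN and e.site_id != event.site_id:
                    context = e.site_id
                    break
            node = tree.parent.get(node)
    if context is None:
        n = raw.n_cells
        return np.zeros(n, bool), np.zeros(n, bool)
    jc = raw.site_ids.index(context)
    ctx_col = raw.data[:, jc]
    carriers = (col == WILD) & (ctx_col == MUT)
    observed = (col != MISSING) & (ctx_col != MISSING)
    return carriers, observed


def compute_coi(a: str, d: str, raw: GenotypeMatrix) -> COIRecord:
    """COI of descendant site ``d`` given ancestor site ``a`` (both gains).

    Cells missing at either site are excluded from numerator and
    denominator; counting missing-ancestor carriers in the denominator would
    systematically deflate COI under heavy missingness.
    """
    ja = raw.site_ids.index(a)
    jd = raw.site_ids.index(d)
    col_a = raw.data[:, ja]
    col_d = raw.data[:, jd]
    scoreable = (col_d == MUT) & (col_a != MISSING)
    c_star_d = int(scoreable.sum())
    c_ad = int((scoreable & (col_a == MUT)).sum())
    return COIRecord(a, d, c_ad, c_star_d)


def _coi_events(a_ev: MutationEvent, a_branch: str | None,
                d_ev: MutationEvent, d_branch: str | None,
                tree: CloneTree | None, raw: GenotypeMatrix) -> COIRecord:
    """COI generalized to gain/loss events via carrier masks."""
    if a_ev.direction == GAIN and d_ev.direction == GAIN:
        return compute_coi(a_ev.site_id, d_ev.site_id, raw)
    car_a, obs_a = _event_masks(a_ev, tree, a_branch, raw)
    car_d, obs_d = _event_masks(d_ev, tree, d_branch, raw)
    scoreable = car_d & obs_a
    c_star_d = int(scoreable.sum())
    c_ad = int((scoreable & car_a).sum())
    return COIRecord(f"{a_ev.direction}:{a_ev.site_id}", f"{d_ev.direction}:{d_ev.site_id}",
                     c_ad, c_star_d)


def branch_coi(tree: CloneTree, raw: GenotypeMatrix) -> dict[str, float]:
    """Average COI of each branch's events against the parent branch's events.

    Each event on the branch is scored against every event on the
    immediately ancestral branch and the scores averaged (per event, then
    over events).  Branches directly under the root — no ancestral
    mutation — score 1 by convention, as do branches without events.
    """
    scores: dict[str, float] = {}
    for n in tree.preorder():
        if n == tree.root:
            continue
        d_events = tree.events.get(n, [])
        parent = tree.parent[n]
        a_events = tree.events.get(parent, []) if parent != tree.root else []
        if not d_events or not a_events:
            scores[n] = 1.0
            continue
        per_event = []
        for de in d_events:
            vals = [_coi_events(ae, parent, de, n, tree, raw).coi for ae in a_events]
            per_event.append(float(np.mean(vals)))
        scores[n] = float(np.mean(per_event))
    return scores


def prune_low_coi(tree: CloneTree, raw: GenotypeMatrix,
                  cutoff: float = DEFAULT_PRUNE_CUTOFF) -> tuple[CloneTree, list[MutationEvent]]:
    """Remove every maximal branch scoring below the cutoff, with its subtree.

    Descendant branches of a removed branch are removed regardless of their
    own scores; all removed events enter the returned candidate pool.
    """
    t = tree.copy()
    scores = branch_coi(t, raw)
    pool: list[MutationEvent] = []
    removed_any = True
    while removed_any:
        removed_any = False
        for n in list(t.preorder()):
            if n == t.root:
                continue
            if scores.get(n, 1.0) < cutoff:
                for r in t.subtree(n):
                    pool.extend(t.events.get(r, []))
                t.remove_subtree(n)
                removed_any = True
                break
    if len(list(t.preorder())) == 1 and pool:
        raise ValueError(
            "COI pruning removed every branch; review the prune cutoff or thresholds"
        )
    return t, pool


@dataclass
class Candidate:
    site_id: str
    n_carriers: int


def candidate_pool(tree: CloneTree, raw: GenotypeMatrix,
                   floor: int = DEFAULT_ATTACH_FLOOR,
                   extra_sites: list[str] | None = None) -> list[Candidate]:
    """Sites absent from the tree with at least ``floor`` mutant carriers.

    ``extra_sites`` (e.g. sites freed by pruning) are included subject to
    the same floor; singleton mutations are uninformative for COI and stay
    out.  Sorted by decreasing carrier count, ties lexicographic.
    """
    on_tree = {e.site_id for evs in tree.events.values() for e in evs}
    wanted = set(raw.site_ids) - on_tree
    if extra_sites is not None:
        wanted |= set(extra_sites) - on_tree
    out = []
    for s in wanted:
        n_car = int((raw.data[:, raw.site_ids.index(s)] == MUT).sum())
        if n_car >= floor:
            out.append(Candidate(s, n_car))
    out.sort(key=lambda c: (-c.n_carriers, c.site_id))
    return out


def reattach_candidates(tree: CloneTree, pool: list[Candidate], raw: GenotypeMatrix,
                        cutoff: float = DEFAULT_ATTACH_CUTOFF) -> tuple[CloneTree, list[str], list[str]]:
    """Attach candidates at the deepest position with COI above the cutoff.

    Candidates are processed in decreasing carrier-count order.  For each,
    COI (candidate as descendant) is computed against every event currently
    on the tree; among qualifying ancestors the deepest (greatest root
    distance in branches, ties toward the earlier-attached branch) wins and
    the candidate becomes a new child branch below that ancestor's node.
    Newly attached events are immediately eligible as ancestors for later
    candidates.  Returns (tree, attached site ids, unattached site ids).
    """
    t = tree.copy()
    attached: list[str] = []
    unattached: list[str] = []
    order_index = {n: i for i, n in enumerate(t.preorder())}
    next_order = len(order_index)
    for cand in pool:
        best = None  # (depth, order, branch_node)
        for n in t.preorder():
            if n == t.root:
                continue
            for ev in t.events.get(n, []):
                rec = _coi_events(ev, n, MutationEvent(cand.site_id, GAIN), None, t, raw)
                if rec.no_support or rec.coi <= cutoff:
                    continue
                key = (t.depth(n), -order_index[n])
                if best is None or key > best[0]:
                    best = (key, n)
        if best is None:
            unattached.append(cand.site_id)
            continue
        host = best[1]
        new_node = f"r_{cand.site_id}"
        if new_node in t.parent:
            new_node = f"r_{cand.site_id}_{next_order}"
        t.add_node(new_node, host, events=[MutationEvent(cand.site_id, GAIN)])
        order_index[new_node] = next_order
        next_order += 1
        attached.append(cand.site_id)
    return t, attached, unattached
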
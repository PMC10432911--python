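"""Clone sequences, cell assignment, error rates, Fisher ordering test and
doublet detection.

Once a mutation tree is in hand, every node defines a candidate clone
sequence (the accumulation of gains and losses along its root path).  Cells
are assigned to the most similar clone; comparing observed cells with their
matched clone sequences yields plug-in estimates of the false-negative rate
(FNR: predicted-mutant positions observed wild-type, i.e. allele dropout)
and false-positive rate (FPR: predicted-wild-type positions observed
mutant).

Two statistical refinements follow.

*Sequential-order test.*  If mutations a and d truly occurred in sequence,
cells carrying only a (``C_a-``) must exceed what allele dropout of d alone
would fabricate.  With ``E_a- = (C_a- + C_ad) * FNR`` and
``E_ad = (C_a- + C_ad) - E_a-``, a two-sided Fisher exact test on
``[[C_a-, C_ad], [E_a-, E_ad]]`` (expected counts rounded to integers)
decides: a significant p (< 0.01 by default) supports sequential order;
otherwise the intermediate clone is dissolved and the two mutations are
treated as co-occurring.

*Doublet test.*  Each cell is also paired with the second clone covering
the most of its observed mutations absent from the assigned clone; the
doublet expectation is the union of the two clone genotypes.  Under the
error model P(observed | expected) per site is (1-FPR, FPR, FNR, 1-FNR) for
the four wild/mutant combinations; the likelihood-ratio statistic
``LR = 2 (lnL_doublet - lnL_singleton)`` is referred to chi-square with one
degree of freedom, and cells with p < 0.01 are flagged as doublets and
removed from the clone annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix, MISSING, MUT, WILD
from .trees import CloneTree, GAIN, LOSS

DOUBLET = "DOUBLET"
UNINFORMATIVE = "UNINFORMATIVE"

_RATE_FLOOR = 1e-6  # clamp for logs; estimated 0/1 rates stay reported as-is


@dataclass(frozen=True)
class ErrorRates:
    """Estimated false-negative and false-positive mutation-call rates."""

    fnr: float
    fpr: float
    fnr_denominator: int = 0
    fpr_denominator: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fnr <= 1.0 and 0.0 <= self.fpr <= 1.0):
            raise ValueError("rates must be in [0, 1]")


@dataclass(frozen=True)
class SequentialTest:
    """One ancestor-descendant ordering test (observed vs expected counts)."""

    ancestor: str
    descendant: str
    c_a_minus: int
    c_ad: int
    e_a_minus: float
    e_ad: float
    p_value: float


def derive_clone_sequences(tree: CloneTree) -> dict[str, np.ndarray]:
    """Genotype of every node by applying events along its root path."""
    n_sites = len(tree.site_ids)
    idx = {s: j for j, s in enumerate(tree.site_ids)}
    out: dict[str, np.ndarray] = {}
    for n in tree.preorder():
        if n == tree.root:
            out[n] = np.full(n_sites, WILD, dtype=np.int8)
            continue
        g = out[tree.parent[n]].copy()
        for e in tree.events.get(n, []):
            j = idx[e.site_id]
            if e.direction == GAIN:
                if g[j] != WILD:
                    raise ValueError(f"GAIN of {e.site_id} on edge to {n!r} but state already mutant")
                g[j] = MUT
            else:
                if g[j] != MUT:
                    raise ValueError(f"LOSS of {e.site_id} on edge to {n!r} but mutation never gained")
                g[j] = WILD
        out[n] = g
    return out


def assign_cells(raw: GenotypeMatrix, clones: dict[str, np.ndarray],
                 clone_site_ids: list[str]) -> pd.DataFrame:
    """Assign each cell to the clone with the highest call similarity.

    Similarity is the fraction of matching calls over the cell's non-missing
    sites (restricted to the clone-sequence site set).  Ties break toward
    the clone with fewer mutations, then lexicographic clone id.  Cells with
    no informative site are labeled UNINFORMATIVE.
    """
    site_idx = [raw.site_ids.index(s) for s in clone_site_ids]
    sub = raw.data[:, site_idx]
    clone_ids = sorted(clones, key=lambda c: (int((clones[c] == MUT).sum()), c))
    clone_mat = np.stack([clones[c] for c in clone_ids])  # K x S

    rows = []
    obs = sub != MISSING
    for i, cell in enumerate(raw.cell_ids):
        o = obs[i]
        n_obs = int(o.sum())
        if n_obs == 0:
            rows.append((cell, UNINFORMATIVE, np.nan))
            continue
        matches = (clone_mat[:, o] == sub[i, o]).sum(axis=1)
        best = int(np.argmax(matches))  # first max wins: fewest-mutation, lex order
        rows.append((cell, clone_ids[best], matches[best] / n_obs))
    return pd.DataFrame(rows, columns=["cell", "clone", "similarity"])


def estimate_error_rates(raw: GenotypeMatrix, assignment: pd.DataFrame,
                         clones: dict[str, np.ndarray],
                         clone_site_ids: list[str]) -> ErrorRates:
    """Pooled FNR/FPR from observed cells vs their matched clone sequences.

    Missing observations are excluded from numerator and denominator; a zero
    denominator yields a 0 rate (flagged by the zero denominator field).
    """
    site_idx = [raw.site_ids.index(s) for s in clone_site_ids]
    sub = raw.data[:, site_idx]
    cell_pos = {c: i for i, c in enumerate(raw.cell_ids)}

    fn_num = fn_den = fp_num = fp_den = 0
    for _, row in assignment.iterrows():
        if row["clone"] in (UNINFORMATIVE, DOUBLET):
            continue
        g = clones[row["clone"]]
        d = sub[cell_pos[row["cell"]]]
        obs = d != MISSING
        pred_mut = obs & (g == MUT)
        pred_wild = obs & (g == WILD)
        fn_den += int(pred_mut.sum())
        fn_num += int((pred_mut & (d == WILD)).sum())
        fp_den += int(pred_wild.sum())
        fp_num += int((pred_wild & (d == MUT)).sum())
    fnr = fn_num / fn_den if fn_den else 0.0
    fpr = fp_num / fp_den if fp_den else 0.0
    return ErrorRates(fnr, fpr, fn_den, fp_den)


# ---------------------------------------------------------------------------
# Fisher sequential-order refinement
# ---------------------------------------------------------------------------


def sequential_test(a: str, d: str, raw: GenotypeMatrix, fnr: float) -> SequentialTest | None:
    """Fisher exact test of sequential vs co-occurring order for (a, d).

    Counts use cells non-missing at both sites.  Returns None for the
    degenerate all-zero table (pair not scoreable).
    """
    ja = raw.site_ids.index(a)
    jd = raw.site_ids.index(d)
    col_a = raw.data[:, ja]
    col_d = raw.data[:, jd]
    both_obs = (col_a != MISSING) & (col_d != MISSING)
    c_ad = int((both_obs & (col_a == MUT) & (col_d == MUT)).sum())
    c_a_minus = int((both_obs & (col_a == MUT) & (col_d == WILD)).sum())
    total = c_a_minus + c_ad
    e_a_minus = total * fnr
    e_ad = total - e_a_minus
    table = [[c_a_minus, c_ad], [int(round(e_a_minus)), int(round(e_ad))]]
    if sum(table[0]) + sum(table[1]) == 0:
        return None
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return SequentialTest(a, d, c_a_minus, c_ad, e_a_minus, e_ad, float(p))


def fisher_refine(tree: CloneTree, raw: GenotypeMatrix, rates: ErrorRates,
                  alpha: float = 0.01) -> tuple[CloneTree, list[SequentialTest], int, int]:
    """Dissolve intermediate clones whose sequential order is unsupported.

    For each branch pair (parent edge events A, child edge events D), every
    (a in A, d in D) gain pair is tested; unless a majority of the pairs is
    significant at ``alpha`` the intermediate node is dissolved — the parent
    edge's events move down onto the child edge, and the two event sets
    co-occur.  (With a single event per edge this is exactly the
    per-pair rule; on multi-event edges single pairs can be confounded by
    mutations shared with clades not represented on the tree, so the
    branch-level decision aggregates across pairs.)  A node
    with several children is never dissolved (a merge would detach the other
    subtrees); such candidate merges are counted as skipped.  One
    root-downward pass with counts refreshed after each merge.

    Returns (tree, all tests, n_merges, n_skipped_merges).
    """
    t = tree.copy()
    tests: list[SequentialTest] = []
    n_merge = 0
    n_skip = 0

    def gains(evs) -> list[str]:
        return [e.site_id for e in evs if e.direction == GAIN]

    progress = True
    tested: set[tuple[str, str]] = set()
    while progress:
        progress = False
        for u in list(t.preorder()):
            if u == t.root or u not in t.parent:
                continue
            a_sites = gains(t.events.get(u, []))
            if not a_sites:
                continue
            for v in list(t.children[u]):
                d_sites = gains(t.events.get(v, []))
                if not d_sites:
                    continue
                key = (u, v)
                if key in tested:
                    continue
                pair_tests = []
                for a in a_sites:
                    for d in d_sites:
                        st = sequential_test(a, d, raw, rates.fnr)
                        if st is not None:
                            pair_tests.append(st)
                tests.extend(pair_tests)
                tested.add(key)
                if not pair_tests:
                    continue
                n_sig = sum(st.p_value < alpha for st in pair_tests)
                sequential_supported = 2 * n_sig > len(pair_tests)
                if sequential_supported:
                    continue
                if len(t.children[u]) > 1:
                    n_skip += 1
                    continue
                # dissolve u: v inherits u's events and parent
                parent = t.parent[u]
                t.events[v] = list(t.events[u]) + list(t.events[v])
                t.children[parent][t.children[parent].index(u)] = v
                t.parent[v] = parent
                t.parent.pop(u)
                t.children.pop(u)
                t.events.pop(u)
                t.genotypes.pop(u, None)
                n_merge += 1
                progress = True
                break
            if progress:
                break
    return t, tests, n_merge, n_skip


# ---------------------------------------------------------------------------
# Doublet detection
# ---------------------------------------------------------------------------


def sequence_log_likelihood(observed: np.ndarray, expected: np.ndarray,
                            fnr: float, fpr: float) -> float:
    """Log-likelihood of an observed call vector given an expected clone.

    Per-site factors: 1-FPR (wild|wild), FPR (mutant|wild), FNR
    (wild|mutant), 1-FNR (mutant|mutant).  Missing observations contribute
    no factor.  Rates are clamped away from 0/1 to keep logs finite.
    """
    fnr = min(max(fnr, _RATE_FLOOR), 1 - _RATE_FLOOR)
    fpr = min(max(fpr, _RATE_FLOOR), 1 - _RATE_FLOOR)
    obs = observed != MISSING
    d = observed[obs]
    t = expected[obs]
    ll = 0.0
    ll += math.log(1 - fpr) * int(((t == WILD) & (d == WILD)).sum())
    ll += math.log(fpr) * int(((t == WILD) & (d == MUT)).sum())
    ll += math.log(fnr) * int(((t == MUT) & (d == WILD)).sum())
    ll += math.log(1 - fnr) * int(((t == MUT) & (d == MUT)).sum())
    return ll


@dataclass(frozen=True)
class DoubletResult:
    cell: str
    partner_clone: str | None
    lnl_singleton: float
    lnl_doublet: float
    lr: float
    p_value: float
    is_doublet: bool


def doublet_test(cell_obs: np.ndarray, assigned_clone: str,
                 clones: dict[str, np.ndarray], rates: ErrorRates,
                 alpha: float = 0.01, cell_id: str = "") -> DoubletResult | None:
    """Likelihood-ratio doublet test for one assigned cell.

    The partner is the clone covering the most observed mutant calls absent
    from the assigned clone (ties: higher similarity to the cell); the
    doublet expectation is the union of the two clone genotypes.  Returns
    None when the test is skipped (no partner adds coverage, or rates sit on
    the 0/1 boundary, where the likelihood model is degenerate).
    """
    if not (0.0 < rates.fnr < 1.0) or not (0.0 < rates.fpr < 1.0):
        return None
    t1 = clones[assigned_clone]
    obs = cell_obs != MISSING
    extra = obs & (cell_obs == MUT) & (t1 == WILD)
    if not extra.any():
        return None
    best_partner = None
    best_key = None
    n_obs = int(obs.sum())
    for c in sorted(clones):
        if c == assigned_clone:
            continue
        g = clones[c]
        coverage = int((extra & (g == MUT)).sum())
        if coverage == 0:
            continue
        sim = float((g[obs] == cell_obs[obs]).sum()) / max(n_obs, 1)
        key = (coverage, sim, c)
        if best_key is None or key > best_key:
            best_key = key
            best_partner = c
    if best_partner is None:
        return None
    union = np.where((t1 == MUT) | (clones[best_partner] == MUT), MUT, WILD).astype(np.int8)
    lnl_s = sequence_log_likelihood(cell_obs, t1, rates.fnr, rates.fpr)
    lnl_d = sequence_log_likelihood(cell_obs, union, rates.fnr, rates.fpr)
    lr = 2.0 * (lnl_d - lnl_s)
    p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return DoubletResult(cell_id, best_partner, lnl_s, lnl_d, lr, p, p < alpha)


def run_doublet_tests(raw: GenotypeMatrix, assignment: pd.DataFrame,
                      clones: dict[str, np.ndarray], clone_site_ids: list[str],
                      rates: ErrorRates, alpha: float = 0.01) -> pd.DataFrame:
    """Apply the doublet test to every informative cell; update the table.

    Adds lnL_singleton / lnL_doublet / lr / doublet_p columns and rewrites
    the clone label of flagged cells to DOUBLET.
    """
    site_idx = [raw.site_ids.index(s) for s in clone_site_ids]
    sub = raw.data[:, site_idx]
    cell_pos = {c: i for i, c in enumerate(raw.cell_ids)}
    out = assignment.copy()
    for col in ("lnL_singleton", "lnL_doublet", "lr", "doublet_p"):
        out[col] = np.nan
    out["partner_clone"] = None
    for k, row in out.iterrows():
        if row["clone"] in (UNINFORMATIVE, DOUBLET):
            continue
        res = doublet_test(sub[cell_pos[row["cell"]]], row["clone"], clones, rates,
                           alpha=alpha, cell_id=row["cell"])
        if res is None:
            continue
        out.loc[k, ["lnL_singleton", "lnL_doublet", "lr", "doublet_p"]] = (
            res.lnl_singleton, res.lnl_doublet, res.lr, res.p_value)
        out.loc[k, "partner_clone"] = res.partner_clone
        if res.is_doublet:
            out.loc[k, "clone"] = DOUBLET
    return out


def finalize_clone_phylogeny(tree: CloneTree, assignment: pd.DataFrame) -> tuple[CloneTree, dict[str, int]]:
    """Drop unsupported tip clones and report per-clone cell counts.

    Clones with at least one assigned non-doublet cell are the final clones;
    zero-cell internal nodes are retained as unlabeled ancestors, while
    zero-cell tips are removed iteratively (their events are thereby
    reported as unsupported by the caller).
    """
    counts = assignment[~assignment["clone"].isin([DOUBLET, UNINFORMATIVE])]["clone"].value_counts().to_dict()
    t = tree.copy()
    changed = True
    while changed:
        changed = False
        for n in list(t.preorder()):
            if n == t.root:
                continue
            if not t.children[n] and counts.get(n, 0) == 0:
                t.remove_subtree(n)
                changed = True
                break
    clone_counts = {n: int(counts.get(n, 0)) for n in t.preorder()}
    return t, clone_counts
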
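"""The TopHapPlus estimator: genotype matrix in, clone phylogeny out.

Organised as a scikit-learn-style estimator so it composes with sklearn
tooling: hyperparameters are constructor arguments, :meth:`fit` consumes a
cells x sites matrix (ternary 0/1/3 codes or a :class:`GenotypeMatrix`) and
exposes fitted state through trailing-underscore attributes
(``tree_``, ``labels_``, ``clone_genotypes_``, ``error_rates_`` ...), and
:meth:`predict` assigns new cells to the fitted clones.

The fit runs the full inference chain:

1. optional majority-vote refinement (haplotype construction only);
2. VAF site filter, haplotype collapse, HF haplotype filter;
3. maximum-parsimony topology + ancestral reconstruction -> mutation tree;
4. co-occurrence (COI) pruning and candidate reattachment on the raw calls;
5. clone sequences, cell assignment, FNR/FPR estimation;
6. Fisher sequential-order refinement of adjacent mutation pairs;
7. re-assignment, likelihood-ratio doublet flagging, final clone phylogeny.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import coi as coi_mod
from . import refine as refine_mod
from .genotype_io import GenotypeMatrix
from .haplotypes import (collapse_haplotypes, filter_haplotypes, filter_sites,
                         parse_threshold)
from .impute import majority_impute
from .trees import CloneTree, fitch_reconstruct, induced_mutation_tree, infer_topology


class TopHapPlus(BaseEstimator):
    """Clone-phylogeny inference from error-prone single-cell genotypes.

    Parameters
    ----------
    vaf : str, int or float, default 5
        Variant-frequency threshold for site retention; strict.  Integers
        (or ``"5cells"``) are absolute mutant-cell counts, fractions (or
        ``"5%"``) are mutant fractions among non-missing calls.
    hf : str, int or float, default 5
        Haplotype-frequency threshold for haplotype retention; strict.
    coi_prune : float, default 0.3
        Branches with average co-occurrence below this are pruned.
    coi_attach : float, default 0.4
        Candidate mutations attach where their co-occurrence exceeds this.
    attach_floor : int, default 2
        Minimum mutant-cell count for a reattachment candidate.
    fisher_alpha : float, default 0.01
        Significance level of the sequential-order exact test.
    doublet_alpha : float, default 0.01
        Significance level of the doublet likelihood-ratio test; ``None``
        disables the test.
    imputation : {"none", "majority"}, default "none"
        Optional refinement pass before haplotype construction.  All
        statistics (COI, error rates, doublet test) still use raw calls.
    impute_k : int, default 40
        Neighbourhood size of the majority refinement; must exceed the
        expected dropout subclique of a typical clone (see the imputation
        module).

    Attributes
    ----------
    tree_ : CloneTree
        Final clone phylogeny (germline-rooted; edges carry mutation events).
    mutation_tree_ : CloneTree
        Refined mutation tree before unsupported-tip removal.
    clone_genotypes_ : pandas.DataFrame
        Binary genotype per final clone over ``site_ids_``.
    labels_ : ndarray of str
        Per-cell clone label, ``"DOUBLET"`` or ``"UNINFORMATIVE"``.
    assignment_ : pandas.DataFrame
        Per-cell clone, similarity and doublet-test statistics.
    error_rates_ : ErrorRates
        Estimated FNR and FPR.
    clone_counts_ : dict
        Assigned non-doublet cells per final clone.
    n_clones_ : int
        Number of clones with at least one assigned cell.
    report_ : dict
        Stage-by-stage counts (sites kept, haplotypes kept, branches pruned,
        candidates attached, merges, doublets).
    """

    def __init__(self, vaf=5, hf=5, coi_prune=coi_mod.DEFAULT_PRUNE_CUTOFF,
                 coi_attach=coi_mod.DEFAULT_ATTACH_CUTOFF,
                 attach_floor=coi_mod.DEFAULT_ATTACH_FLOOR,
                 fisher_alpha=0.01, doublet_alpha=0.01,
                 imputation="none", impute_k=40):
        self.vaf = vaf
        self.hf = hf
        self.coi_prune = coi_prune
        self.coi_attach = coi_attach
        self.attach_floor = attach_floor
        self.fisher_alpha = fisher_alpha
        self.doublet_alpha = doublet_alpha
        self.imputation = imputation
        self.impute_k = impute_k

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _as_matrix(X) -> GenotypeMatrix:
        if isinstance(X, GenotypeMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            return GenotypeMatrix([str(i) for i in X.index],
                                  [str(c) for c in X.columns],
                                  X.to_numpy(dtype=np.int8))
        arr = np.asarray(X, dtype=np.int8)
        if arr.ndim != 2:
            raise ValueError("X must be a 2-D cells x sites matrix")
        return GenotypeMatrix([f"cell{i + 1}" for i in range(arr.shape[0])],
                              [f"s{j + 1}" for j in range(arr.shape[1])], arr)

    # -- core --------------------------------------------------------------
    def fit(self, X, y=None):
        """Infer the clone phylogeny of the cells in ``X``."""
        raw = self._as_matrix(X)
        report: dict = {"n_cells": raw.n_cells, "n_sites": raw.n_sites,
                        "thresholds": {"vaf": str(self.vaf), "hf": str(self.hf),
                                       "coi_prune": self.coi_prune,
                                       "coi_attach": self.coi_attach,
                                       "fisher_alpha": self.fisher_alpha,
                                       "doublet_alpha": self.doublet_alpha}}
        if self.imputation not in ("none", "majority"):
            raise ValueError(f"unknown imputation mode {self.imputation!r}")
        hap_input = majority_impute(raw, k=self.impute_k) if self.imputation == "majority" else raw

        # 1-2. frequency filtering and haplotype selection
        vaf = parse_threshold(self.vaf)
        hf = parse_threshold(self.hf)
        filtered = filter_sites(hap_input, vaf)
        report["sites_kept"] = filtered.n_sites
        table = collapse_haplotypes(filtered)
        report["haplotypes_total"] = table.n_haplotypes
        table = filter_haplotypes(table, hf)
        report["haplotypes_kept"] = table.n_haplotypes

        # 3. parsimony phylogeny of major haplotypes -> mutation tree
        topo = infer_topology(
            {h: table.genotypes[h] for h in table.haplotype_ids},
            supports=table.support, site_ids=list(table.site_ids))
        fitch_reconstruct(topo, {h: table.genotypes[h] for h in table.haplotype_ids})
        mut_tree = induced_mutation_tree(topo)

        # 4. co-occurrence assessment on the raw observed matrix
        n_before = mut_tree.n_nodes
        mut_tree, removed = coi_mod.prune_low_coi(mut_tree, raw, cutoff=self.coi_prune)
        report["branches_pruned"] = n_before - mut_tree.n_nodes
        report["pruned_events"] = len(removed)
        # candidates are enumerated (and VAF-ordered) on the refined
        # alignment when refinement is on — isolated false positives do not
        # nominate candidates — while COI itself always uses raw calls
        pool = coi_mod.candidate_pool(mut_tree, hap_input, floor=self.attach_floor,
                                      extra_sites=[e.site_id for e in removed])
        report["candidates_considered"] = len(pool)
        mut_tree, att, unatt = coi_mod.reattach_candidates(mut_tree, pool, raw,
                                                           cutoff=self.coi_attach)
        report["candidates_attached"] = len(att)
        report["candidates_unattached"] = unatt

        # 5. clone sequences over the sites on the tree; assignment; rates
        tree_sites = sorted({e.site_id for evs in mut_tree.events.values() for e in evs},
                            key=raw.site_ids.index)
        mut_tree = _restrict_tree_sites(mut_tree, tree_sites)
        clones = refine_mod.derive_clone_sequences(mut_tree)
        assignment = refine_mod.assign_cells(raw, clones, tree_sites)
        rates = refine_mod.estimate_error_rates(raw, assignment, clones, tree_sites)

        # 6. sequential-order refinement
        mut_tree, tests, n_merge, n_skip = refine_mod.fisher_refine(
            mut_tree, raw, rates, alpha=self.fisher_alpha)
        report["fisher_tests"] = len(tests)
        report["fisher_merges"] = n_merge
        report["fisher_skipped_merges"] = n_skip

        # 7. re-derive, re-assign, doublet test, finalize
        clones = refine_mod.derive_clone_sequences(mut_tree)
        assignment = refine_mod.assign_cells(raw, clones, tree_sites)
        rates = refine_mod.estimate_error_rates(raw, assignment, clones, tree_sites)
        if self.doublet_alpha is not None:
            assignment = refine_mod.run_doublet_tests(raw, assignment, clones,
                                                      tree_sites, rates,
                                                      alpha=self.doublet_alpha)
        report["doublets_flagged"] = int((assignment["clone"] == refine_mod.DOUBLET).sum())
        final_tree, clone_counts = refine_mod.finalize_clone_phylogeny(mut_tree, assignment)
        for n in final_tree.preorder():
            final_tree.genotypes[n] = clones[n]
        n_clones = sum(1 for c in clone_counts.values() if c > 0)
        if 0 < 2 * n_clones < report["haplotypes_kept"] - 1:
            report["warning"] = ("more than half of the initial clones were removed by "
                                 "the mutation ordering analysis; consider higher VAF/HF thresholds")

        self.raw_ = raw
        self.site_ids_ = tree_sites
        self.haplotype_table_ = table
        self.mutation_tree_ = mut_tree
        self.tree_ = final_tree
        self.sequential_tests_ = tests
        self.clone_genotypes_ = pd.DataFrame(
            {c: clones[c] for c in final_tree.preorder()}, index=tree_sites).T.astype(int)
        self.assignment_ = assignment
        self.labels_ = assignment["clone"].to_numpy()
        self.error_rates_ = rates
        self.clone_counts_ = clone_counts
        self.n_clones_ = n_clones
        report["estimated_fnr"] = rates.fnr
        report["estimated_fpr"] = rates.fpr
        report["n_clones"] = n_clones
        report["clone_counts"] = {k: v for k, v in clone_counts.items() if v > 0}
        self.report_ = report
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def predict(self, X):
        """Assign new cells to the fitted clones (no doublet testing)."""
        self._check_fitted()
        m = self._as_matrix(X)
        clones = {c: self.clone_genotypes_.loc[c].to_numpy(dtype=np.int8)
                  for c in self.clone_genotypes_.index}
        assignment = refine_mod.assign_cells(m, clones, self.site_ids_)
        return assignment["clone"].to_numpy()

    def _check_fitted(self):
        if not hasattr(self, "tree_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    # sklearn clusterer-flavored alias
    @property
    def cluster_centers_(self):
        self._check_fitted()
        return self.clone_genotypes_.to_numpy()


def _restrict_tree_sites(tree: CloneTree, site_ids: list[str]) -> CloneTree:
    """Re-scope node genotypes/site list to the sites carried by the tree."""
    t = tree.copy()
    t.site_ids = list(site_ids)
    t.genotypes = {}
    return t
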
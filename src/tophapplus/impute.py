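"""Optional majority-vote genotype refinement.

Single-cell genotype matrices carry heavy allele dropout and missingness;
haplotype collapsing on raw calls is then uninformative because almost no
cell has a complete, error-free profile.  This pass refines each cell by
per-site majority vote over its nearest-neighbour cells (agreement fraction
on mutually observed calls), producing a complete matrix used *only* for
haplotype construction — co-occurrence scoring, error-rate estimation and
the doublet test always run on the original observed matrix.

It is a deliberately simple, deterministic refinement pass and is off by
default.
"""

from __future__ import annotations

import numpy as np

from .genotype_io import GenotypeMatrix, MISSING, MUT, WILD

DEFAULT_K = 40
DEFAULT_N_ITER = 2


def majority_impute(m: GenotypeMatrix, k: int = DEFAULT_K,
                    n_iter: int = DEFAULT_N_ITER) -> GenotypeMatrix:
    """Refine calls by iterated per-site majority over the k most similar cells.

    Similarity between two cells is the fraction of agreeing calls over
    mutually non-missing sites (cells with no overlap score 0).  For each
    cell, the k highest-similarity cells (plus the cell itself) vote per
    site among their non-missing calls; the majority call wins, ties going
    to the cell's own call when observed and to wild-type otherwise.

    The vote is iterated ``n_iter`` times, recomputing similarities on the
    refined matrix.  A single round can preserve shared-dropout echoes —
    cells sharing a false-negative at a site rank each other as nearest
    neighbours precisely because of that shared error — so the
    neighbourhood must be larger than the dropout subclique of a clone
    (k of about twice the expected dropout count per typical clone) and a
    second consensus round lets the cleaned profiles overrule the echo.
    """
    n, s = m.data.shape
    k = min(k, n - 1)
    cur = m.data
    out = cur.copy()
    for _ in range(max(n_iter, 1)):
        obs = cur != MISSING
        is_wild = ((cur == WILD) & obs).astype(np.float32)
        is_mut = ((cur == MUT) & obs).astype(np.float32)
        obs_f = obs.astype(np.float32)

        agree = is_wild @ is_wild.T + is_mut @ is_mut.T
        overlap = obs_f @ obs_f.T
        with np.errstate(divide="ignore", invalid="ignore"):
            sim = np.where(overlap > 0, agree / np.maximum(overlap, 1), 0.0)
        np.fill_diagonal(sim, -1.0)

        out = np.empty_like(cur)
        order = np.argsort(-sim, axis=1, kind="stable")
        for i in range(n):
            nbrs = order[i, :k]
            votes_idx = np.concatenate(([i], nbrs))
            w = is_wild[votes_idx].sum(axis=0)
            u = is_mut[votes_idx].sum(axis=0)
            row = np.where(u > w, MUT, WILD).astype(np.int8)
            tie = u == w
            own = m.data[i]
            row[tie] = np.where((own[tie] != MISSING), own[tie], WILD).astype(np.int8)
            out[i] = row
        cur = out
    return GenotypeMatrix(list(m.cell_ids), list(m.site_ids), out)
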
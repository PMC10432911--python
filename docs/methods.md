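# Methods

This note documents the model and procedure implemented in `tophapplus`,
the choices made where the design was genuinely open, and what the test
suite does and does not demonstrate.

## Data model

The observation is a cells × sites matrix D with ternary entries: wild-type
(0), mutant (1), missing (3).  Sites are binary somatic characters (SNVs,
or presence/absence of a lineage-tracing indel allele).  The generative
picture is a rooted clone tree whose root is the germline (no somatic
mutations); each clone's genotype is the union of the mutations gained on
its root path.  Observed cells are noisy copies of clone genotypes with
four error processes: doublet formation (two cells sequenced together carry
the union of their mutations), allele dropout (mutant observed wild-type,
rate FNR), false positives (wild-type observed mutant, rate FPR) and
missingness.

## Pipeline stages and parameters

| parameter | default | meaning |
|---|---|---|
| `vaf` | `>5` cells | strict minimum mutant-cell support to retain a site; `"5%"` form uses the mutant fraction among non-missing calls |
| `hf` | `>5` cells | strict minimum cell support to retain a haplotype |
| `coi_prune` | 0.3 | branches with event-averaged COI below this are pruned with their subtree |
| `coi_attach` | 0.4 | a candidate mutation attaches where its COI strictly exceeds this |
| `attach_floor` | 2 cells | minimum carrier count for a reattachment candidate; singletons carry no co-occurrence signal |
| `fisher_alpha` | 0.01 | significance level of the sequential-order exact test |
| `doublet_alpha` | 0.01 | significance level of the doublet likelihood-ratio test |
| `imputation` | `none` | optional majority-vote refinement before haplotype construction |
| `impute_k` | 40 | neighbourhood size of that refinement |

Both frequency thresholds are strict inequalities.  For the fraction form
of the VAF threshold the denominator is the number of non-missing calls at
the site, not the number of cells: under 20% missingness a per-cell
denominator would systematically understate variant frequencies.

**Haplotype collapse with missing data.**  Cells with complete calls over
the retained sites define the haplotypes; a cell with missing calls joins a
haplotype only when it conflicts with exactly one complete haplotype
nowhere.  Cells compatible with several haplotypes (or none) contribute no
support but remain available for clone assignment.  This conservative rule
never fabricates support from unobserved calls.  The germline haplotype is
always retained (and appended with zero support when absent): the phylogeny
is rooted on the normal-cell sequence.

**Topology search.**  Maximum parsimony by stepwise addition (tips in
decreasing support order, germline first; ties by genotype bytes then id)
scored with the Fitch union count, followed by nearest-neighbour-interchange
hill climbing that accepts only strictly better trees — together with the
fixed addition order this makes the search deterministic and guarantees
termination.  The backend is deliberately pluggable: nothing downstream
depends on how the initial topology was obtained, and the ordering analysis
can assess mutation trees from other tools.

**Ancestral reconstruction.**  Exact min-change dynamic programming
(unit-cost Sankoff on two states, valid on multifurcations) with the root
clamped to all-wild-type.  Top-down ties keep the parent's state; in
particular, where two independent gains and a gain-plus-loss are equally
parsimonious, the reconstruction prefers the two gains.  This
parent-preference minimises spurious event toggling along root-to-tip
paths, which matters because downstream ordering statistics are computed
per edge event.  Zero-event internal edges are contracted; a zero-event
*tip* is genotype-identical to its parent and its label is merged onto that
node (sampled-ancestor representation), keeping clone sequences unique.

**Co-occurrence index.**  COI(a, d) = C_ad / C_\*d where C_\*d counts cells
observed mutant at d with a non-missing call at a, and C_ad those among
them also mutant at a.  Cells missing at the ancestor site are excluded
from the denominator; including them would deflate COI by roughly the
missing rate.  COI is always computed on the originally observed matrix —
refinement or imputation output is never used here, so imputation bias
cannot leak into the ordering assessment.  A pair with no scoreable carrier
is reported as a no-support record that fails every threshold and
contributes 0 to branch averages.  For a loss event, "carrying" the event
means showing the derived (wild-type) state at the lost site while being
mutant at the nearest gain on the same branch or an ancestral branch; this
keeps the index well-defined for reversals.

Branch scores average over all (ancestor event, descendant event) pairs of
an edge and its parent edge; branches directly under the root score 1 by
convention (there is no ancestral mutation to co-occur with), as do
edges without events.

**Candidate reattachment.**  Candidates are every mutation absent from the
current tree with at least `attach_floor` carriers — including sites below
the original VAF threshold and events freed by pruning.  They are processed
in decreasing carrier count (ties lexicographic); each attaches below the
deepest tree event whose COI against the candidate strictly exceeds
`coi_attach` (ties toward the earlier-attached branch), and newly attached
events immediately serve as ancestors for later candidates, so chains of
co-occurring low-frequency mutations assemble incrementally.  Attachment is
judged against the chosen ancestor only; consistency along the whole chain
is enforced afterwards by the sequential-order test.  When the refinement
pre-step is enabled, candidate *enumeration and ordering* use the refined
matrix (isolated false-positive calls then nominate no candidates), while
the COI values deciding placement still come from raw calls.

**Error-rate estimation.**  FNR = observed-wild-type among predicted-mutant
positions, FPR = observed-mutant among predicted-wild-type positions,
pooled over all informative cells against their assigned clone sequences,
missing observations excluded from numerator and denominator.  With
doublets present the FPR estimate absorbs unflagged doublets' second-clone
mutations and is biased upward by roughly one percentage point at the
reference protocol settings; with doublets absent both estimators are
nearly unbiased (the FNR retains a small downward bias, about 1.5
percentage points at 20% dropout, because cells are assigned to the clone
they best match, which preferentially explains some dropout as clone
membership).

**Sequential-order refinement.**  For each edge pair (parent events A,
child events D), every gain pair (a ∈ A, d ∈ D) yields the 2×2 table
[[C_a−, C_ad], [round(E_a−), round(E_ad)]] with E_a− = (C_a− + C_ad)·FNR
and E_ad the complement; rounding is required because the exact test needs
integer tables, and the unrounded expectations are kept in the report.  The
two-sided p-value comes from `scipy.stats.fisher_exact` (validated against
exhaustive hypergeometric enumeration in the tests).  The intermediate node
is dissolved unless a **majority** of the pairs is significant: with one
event per edge this is exactly the per-pair rule, while on multi-event
edges a single pair can be confounded by mutations shared with clades not
represented on the tree, so the branch-level decision aggregates across
pairs.  A node with several children is never dissolved (the merge would
detach its other subtrees); such skipped merges are counted in the report.
One root-downward pass is made with counts refreshed after each merge; no
multiple-testing correction is applied by default, matching the observation
that false clone detections are not elevated at these settings.

**Doublet test.**  The partner clone maximises the number of the cell's
observed mutant calls absent from its assigned clone (ties: higher overall
similarity to the cell, then lexicographic id); the doublet expectation is
the union genotype.  Log-likelihoods use the per-site emission model
(1−FPR, FPR, FNR, 1−FNR) over the cell's non-missing sites; missing sites
contribute no factor.  Rates are clamped to [1e−6, 1−1e−6] inside the
likelihood to keep logarithms finite; rates estimated at exactly 0 or 1
skip the test entirely (the model is degenerate there, and on error-free
data no doublet call should be made).  LR = 2(lnL_doublet − lnL_singleton)
is referred to χ² with one degree of freedom.  Because the partner is
chosen adaptively over clones, the realized false-flag rate among true
singletons exceeds the nominal level by up to the clone count (about 6% at
α = 0.01 with six clones in the test fixture); the recall on doublets
merging well-separated clones exceeds 80%.

**Finalization.**  Clones with at least one assigned non-doublet cell are
the final clones.  Zero-cell internal nodes remain as unlabeled ancestors;
zero-cell tips are removed iteratively and their events reported as
unsupported.  Reported per-clone counts are post-doublet-removal.

## Majority-vote refinement (optional pre-step)

Under the reference noise protocol almost no cell has a complete,
error-free profile, so haplotype collapse on raw calls is uninformative.
The optional refinement replaces each cell by the per-site majority call of
its `impute_k` most similar cells (agreement fraction over mutually
observed calls), iterated twice with similarities recomputed on the refined
matrix.  The neighbourhood must be larger than the shared-dropout subclique
of a clone — cells sharing a dropout at a site rank each other highly
*because* of the shared error, and a small neighbourhood then preserves the
error as a phantom haplotype one mutation away from the real clone.  With
dropout around 20% and protocol-scale clones, k = 40 with a second
consensus round dissolves these echoes.  Ties go to the cell's own observed
call, then wild-type.  The refined matrix is used only to build haplotypes
and enumerate candidates; every statistic (COI, error rates, ordering
tests, doublet likelihoods) is computed on raw calls.  This pass is a
simple deterministic consensus filter, off by default; clones much smaller
than k lose their private mutations to the neighbourhood vote and must be
recovered by COI reattachment, which succeeds when their mutations retain
at least `attach_floor` raw carriers.

## Simulator

The generator reproduces the benchmark protocol the method targets: a
random rooted clone tree (each new clone attaches as a child of a uniformly
chosen existing node, so clones may be ancestral to other clones, as in
real tumors where persisting ancestral clones are sampled), 100 SNVs placed
one-per-branch first and then uniformly (infinite sites: every SNV gains
exactly once, no losses), 5–50 clones, 100–2000 cells with symmetric
Dirichlet(1) clone frequencies by default (producing both common and rare
clones; a uniform scheme is available), every clone guaranteed one cell.
Error injection order is doublet → false negative → false positive →
missing: errors act on the merged molecule and masking happens last,
mirroring the physics of sequencing.  Default rates are the protocol's 10%
doublets, 1% FPR, 20% FNR, 20% missing.  All randomness derives from one
seed through independent spawned streams, and a fixed seed reproduces the
observed matrix bitwise.

What the simulator does **not** emulate: copy-number events, site- or
cell-specific error rates, read counts or VAF-level evidence, and clone
frequencies tied to a growth model.  Passing tests on simulated data
therefore demonstrate correctness of the inference machinery under the
stated error model, not robustness to systematic artifacts absent from it.

## Evaluation

True and inferred clusterings rarely share a clone set, so the
Robinson–Foulds comparison first pairs each true clone with the inferred
clone holding the plurality of its cells (ties: larger inferred clone, then
lexicographic id; many-to-one allowed).  Inferred tips paired with several
true clones are duplicated as zero-length cherries; unpaired tips are
pruned from both trees; clones sitting at internal nodes are represented as
zero-length pendant tips on both sides.  RF is the bipartition symmetric
difference plus one penalty per true clone with no inferred pair.  The
signed clone-count error (inferred clones with ≥1 cell minus simulated
clones) is reported alongside, since RF cannot express size errors.  With a
bijective pairing and no pruning the metric equals the textbook RF
(checked against an independent bipartition implementation).

## Numerical and degenerate-input choices

- Thresholds are strict everywhere; `"N"`/`"Ncells"` parse as absolute,
  `"P%"` as fractions, bare floats below 1 as fractions.
- Fisher tables: expectations rounded half-away-from-zero to integers;
  all-zero tables skip the pair with a warning count.
- Negative LR statistics (doublet fitting worse) map to p = 1.
- An empty site or haplotype filter result raises an error that names the
  threshold to lower rather than returning an empty object.
- Pruning that would leave only the root raises an error advising threshold
  review.  When the ordering analysis removes more than half of the initial
  clones the run report carries a warning suggesting higher VAF/HF
  thresholds; no automatic re-run is attempted.
- Cells with no informative site are labeled `UNINFORMATIVE` and excluded
  from rate estimation and clone counts.

## Problem sizes used in the test and acceptance runs

Unit fixtures are tens of cells; end-to-end checks use 100–1000 cells ×
30–100 SNVs with 5–20 clones, and the acceptance script runs the reference
scale (10 clones, 100 SNVs, 1000 cells) over five seeds for rate
estimation plus one full-protocol matrix for the missingness check.  These
sizes give per-clone cell counts comfortably above the frequency
thresholds while keeping a full suite run in tens of seconds.

## Known limitations

- The refinement stand-in is a consensus filter, not a model-based
  genotype refiner; clones smaller than the neighbourhood rely entirely on
  COI reattachment for recovery, and clones below the candidate floor
  (fewer than two raw carriers per private mutation) are unrecoverable.
- Loss events inferred on tips can be dropout echoes; the ordering
  analysis flags unsupported intermediates but a tip loss supported by a
  coherent carrier set is retained, so inferred mutation losses warrant
  manual inspection, especially under high dropout.
- VAF and HF thresholds are user-specified; datasets with many
  low-frequency variants may need stricter settings (the run report warns
  when the ordering analysis removes most clones).
- The doublet test's adaptive partner choice inflates its nominal level;
  interpret the doublet rate it reports as approximate.
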
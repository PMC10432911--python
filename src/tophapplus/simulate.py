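"""Ground-truthed synthetic single-cell genotype datasets.

The generator follows the benchmark protocol the method was designed for:
a random rooted clone tree under the infinite-sites model (each SNV gains
on exactly one branch and never reverts), 100 SNVs over 5-50 clones,
100-2000 sampled cells, then four error processes applied to the observed
matrix in sequence — doublet merging (10% of cells union their mutation set
with a second, uniformly chosen cell), false negatives (each mutant call
flips to wild-type with probability 20%, emulating allele dropout), false
positives (each wild-type call flips to mutant with probability 1%), and
missing entries (each call masked with probability 20%).

Clone topologies are random recursive trees: each new clone attaches as a
child of a uniformly chosen existing node (germline or clone), so clones
may be ancestral to other clones, as in real tumor phylogenies where
persisting ancestral clones are sampled alongside their descendants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix, MISSING, MUT, WILD
from .trees import CloneTree, GAIN, GERMLINE, MutationEvent

#: error rates of the reference simulation protocol
PROTOCOL_DOUBLET_RATE = 0.10
PROTOCOL_FPR = 0.01
PROTOCOL_FNR = 0.20
PROTOCOL_MISSING_RATE = 0.20


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dataset.

    ``clone_frequency_scheme`` is ``"uniform"`` (equal expected clone sizes)
    or ``"dirichlet"`` (symmetric Dirichlet(alpha) frequencies, producing a
    realistic mix of common and rare clones; alpha defaults to 1).
    """

    n_clones: int = 10
    n_snvs: int = 100
    n_cells: int = 1000
    doublet_rate: float = PROTOCOL_DOUBLET_RATE
    fpr: float = PROTOCOL_FPR
    fnr: float = PROTOCOL_FNR
    missing_rate: float = PROTOCOL_MISSING_RATE
    seed: int = 0
    clone_frequency_scheme: str = "dirichlet"
    dirichlet_alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.n_clones < 2:
            raise ValueError("need at least 2 clones")
        if self.n_snvs < 1:
            raise ValueError("need at least 1 SNV")
        if self.n_cells < self.n_clones:
            raise ValueError("need at least one cell per clone")
        for name in ("doublet_rate", "fpr", "fnr", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_snvs < self.n_clones - 1:
            raise ValueError("n_snvs must be >= n_clones - 1")
        if self.clone_frequency_scheme not in ("uniform", "dirichlet"):
            raise ValueError(f"unknown scheme {self.clone_frequency_scheme!r}")


@dataclass
class GroundTruth:
    """The simulated truth every downstream stage is scored against."""

    true_tree: CloneTree
    true_cell_genotypes: GenotypeMatrix  # post-doublet, error-free, no missing
    cell_to_clone: dict[str, str]
    doublet_cells: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def clone_ids(self) -> list[str]:
        return [n for n in self.true_tree.preorder() if n != GERMLINE]


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_clone_tree(config: SimulationConfig) -> CloneTree:
    """Random rooted clone tree with infinite-sites mutation placement.

    Every clone has one incoming branch; each branch carries at least one
    of the ``n_snvs`` gain events and each SNV is placed on exactly one
    branch, so clone genotypes (root-path unions) are pairwise distinct.
    """
    rng = _rng_streams(config.seed, 4)[0]
    tree = CloneTree(GERMLINE, [f"s{j + 1}" for j in range(config.n_snvs)])
    clones = [f"C{i + 1}" for i in range(config.n_clones)]
    nodes = [GERMLINE]
    for c in clones:
        parent = nodes[int(rng.integers(len(nodes)))]
        tree.add_node(c, parent)
        nodes.append(c)

    branches = clones  # one incoming branch per clone
    if config.n_snvs < len(branches):
        raise ValueError(
            f"n_snvs={config.n_snvs} is smaller than the number of branches "
            f"({len(branches)}); every branch needs at least one mutation"
        )
    site_order = rng.permutation(config.n_snvs)
    placement: dict[str, list[int]] = {b: [] for b in branches}
    for k, j in enumerate(site_order):
        if k < len(branches):
            placement[branches[k]].append(int(j))
        else:
            placement[branches[int(rng.integers(len(branches)))]].append(int(j))

    tree.genotypes[GERMLINE] = np.full(config.n_snvs, WILD, dtype=np.int8)
    for n in tree.preorder():
        if n == GERMLINE:
            continue
        g = tree.genotypes[tree.parent[n]].copy()
        evs = [MutationEvent(tree.site_ids[j], GAIN) for j in sorted(placement[n])]
        for j in sorted(placement[n]):
            g[j] = MUT
        tree.genotypes[n] = g
        tree.events[n] = evs
    tree.validate()
    return tree


def sample_cells(tree: CloneTree, config: SimulationConfig) -> GroundTruth:
    """Assign cells to clones and copy clone genotypes onto cells.

    Every clone receives one guaranteed cell; the remaining
    ``n_cells - n_clones`` cells are multinomial with clone frequencies
    drawn per the configured scheme.
    """
    rng = _rng_streams(config.seed, 4)[1]
    clones = [n for n in tree.preorder() if n != GERMLINE]
    k = len(clones)
    if config.clone_frequency_scheme == "uniform":
        p = np.full(k, 1.0 / k)
    else:
        p = rng.dirichlet(np.full(k, config.dirichlet_alpha))
    counts = np.ones(k, dtype=int)
    extra = config.n_cells - k
    if extra > 0:
        counts += rng.multinomial(extra, p)

    cell_ids, cell_to_clone = [], {}
    rows = []
    i = 0
    for c, n in zip(clones, counts):
        for _ in range(int(n)):
            cid = f"cell{i + 1}"
            i += 1
            cell_ids.append(cid)
            cell_to_clone[cid] = c
            rows.append(tree.genotypes[c].copy())
    gm = GenotypeMatrix(cell_ids, list(tree.site_ids), np.stack(rows))
    return GroundTruth(tree, gm, cell_to_clone)


def inject_errors(gt: GroundTruth, config: SimulationConfig) -> GenotypeMatrix:
    """Apply doublet merging, false negatives, false positives and missingness.

    The order is fixed — doublets first (errors act on the merged molecule),
    then allele dropout (mutant -> wild), then false positives
    (wild -> mutant), then masking — and the doublet membership is recorded
    on ``gt.doublet_cells``.
    """
    rng = _rng_streams(config.seed, 4)[2]
    data = gt.true_cell_genotypes.data.copy()
    n, s = data.shape
    cell_ids = gt.true_cell_genotypes.cell_ids

    if config.doublet_rate > 0 and n > 1:
        is_doublet = rng.random(n) < config.doublet_rate
        pristine = gt.true_cell_genotypes.data.copy()
        for i in np.nonzero(is_doublet)[0]:
            j = int(rng.integers(n - 1))
            if j >= i:
                j += 1
            merged = np.where((pristine[i] == MUT) | (pristine[j] == MUT), MUT, WILD).astype(np.int8)
            data[i] = merged
            # the doublet's error-free genotype is the merged molecule
            gt.true_cell_genotypes.data[i] = merged
            gt.doublet_cells[cell_ids[i]] = (
                gt.cell_to_clone[cell_ids[i]],
                gt.cell_to_clone[cell_ids[j]],
            )

    if config.fnr > 0:
        flip = (data == MUT) & (rng.random((n, s)) < config.fnr)
        data[flip] = WILD
    if config.fpr > 0:
        flip = (data == WILD) & (rng.random((n, s)) < config.fpr)
        data[flip] = MUT
    if config.missing_rate > 0:
        mask = rng.random((n, s)) < config.missing_rate
        data[mask] = MISSING

    return GenotypeMatrix(list(cell_ids), list(gt.true_cell_genotypes.site_ids), data)


def simulate_dataset(config: SimulationConfig) -> tuple[GenotypeMatrix, GroundTruth]:
    """Full protocol: tree -> cells -> error injection."""
    tree = simulate_clone_tree(config)
    gt = sample_cells(tree, config)
    observed = inject_errors(gt, config)
    return observed, gt


def subsample_snvs(m: GenotypeMatrix, n: int, seed: int = 0) -> GenotypeMatrix:
    """Randomly keep ``n`` SNVs (used when a dataset carries more than profiled)."""
    if m.n_sites <= n:
        return m
    rng = np.random.default_rng(seed)
    keep_idx = sorted(rng.choice(m.n_sites, size=n, replace=False))
    return m.subset_sites([m.site_ids[j] for j in keep_idx])
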
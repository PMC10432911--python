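"""High-frequency SNV and haplotype selection.

The first stage of the pipeline separates phylogenetic signal from
sequencing noise by frequency filtering: sites whose mutant-cell count (the
variant allele frequency, VAF, in the cell-count sense used for binary
single-cell genotypes) does not exceed a threshold are dropped, cells are
collapsed to distinct haplotypes over the retained sites, and haplotypes
whose cell support (haplotype frequency, HF) does not exceed a second
threshold are dropped.  Surviving haplotypes correspond to major tumor
clones.  Both thresholds are strict: the default ``>5 cells`` keeps a site
observed mutant in 6 cells and drops one observed in 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix, MISSING, MUT, WILD
from .trees import GERMLINE


class EmptyResultError(ValueError):
    """Filtering removed everything; advises revisiting the threshold."""


@dataclass(frozen=True)
class Threshold:
    """A strict frequency cutoff, in absolute cells or as a fraction.

    ``absolute_cells``: keep items with count strictly greater than
    ``value`` cells.  ``fraction``: keep items whose mutant fraction among
    non-missing calls strictly exceeds ``value`` (in (0, 1]).
    """

    kind: str  # "absolute_cells" | "fraction"
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("absolute_cells", "fraction"):
            raise ValueError(f"unknown threshold kind {self.kind!r}")
        if self.value < 0:
            raise ValueError("threshold value must be non-negative")
        if self.kind == "fraction" and not (0 <= self.value <= 1):
            raise ValueError("fraction threshold must be in [0, 1]")


def parse_threshold(text: str | int | float | Threshold) -> Threshold:
    """Parse ``"5"``/``"5cells"`` (absolute) or ``"5%"``/``"0.05f"`` (fraction).

    Bare numbers < 1 are read as fractions, >= 1 as absolute cell counts.
    """
    if isinstance(text, Threshold):
        return text
    if isinstance(text, (int, float)):
        if 0 < text < 1:
            return Threshold("fraction", float(text))
        return Threshold("absolute_cells", float(text))
    s = str(text).strip().lower()
    if s.endswith("%"):
        return Threshold("fraction", float(s[:-1]) / 100.0)
    if s.endswith("cells"):
        return Threshold("absolute_cells", float(s[:-5]))
    if s.endswith("c"):
        return Threshold("absolute_cells", float(s[:-1]))
    if s.endswith("f"):
        return Threshold("fraction", float(s[:-1]))
    v = float(s)
    return parse_threshold(v)


@dataclass
class HaplotypeTable:
    """Distinct haplotypes over the retained sites, with cell support.

    ``unassigned_cells`` holds cells whose missing calls left them compatible
    with zero or several haplotypes; they contribute no support but remain
    available for clone assignment downstream.
    """

    site_ids: list[str]
    haplotype_ids: list[str]
    genotypes: dict[str, np.ndarray]
    support: dict[str, int]
    member_cells: dict[str, list[str]]
    unassigned_cells: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for h in self.haplotype_ids:
            key = self.genotypes[h].tobytes()
            if key in seen:
                raise ValueError("haplotypes must be pairwise distinct")
            seen.add(key)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)


def filter_sites(m: GenotypeMatrix, vaf: Threshold) -> GenotypeMatrix:
    """Retain sites whose mutant support strictly exceeds the VAF threshold.

    For the fraction form the mutant fraction is computed over non-missing
    calls at the site.  Column order is preserved.  Raises
    :class:`EmptyResultError` when nothing survives.
    """
    muts = m.mut_counts().astype(float)
    if vaf.kind == "absolute_cells":
        keep = muts > vaf.value
    else:
        nonmiss = m.nonmissing_counts().astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(nonmiss > 0, muts / np.maximum(nonmiss, 1), 0.0)
        keep = frac > vaf.value
    kept = [s for s, k in zip(m.site_ids, keep) if k]
    if not kept:
        raise EmptyResultError(
            "no site passed the VAF threshold; lower --vaf and rerun"
        )
    return m.subset_sites(kept)


def collapse_haplotypes(m: GenotypeMatrix) -> HaplotypeTable:
    """Group cells into distinct haplotypes over the retained sites.

    Cells with complete calls define the haplotypes.  A cell with missing
    calls joins a haplotype when its observed calls conflict with exactly
    one complete haplotype nowhere; cells compatible with several (or no)
    haplotypes are held out as unassigned rather than fabricating support.
    """
    complete = ~np.any(m.data == MISSING, axis=1)
    groups: dict[bytes, list[int]] = {}
    for i in np.nonzero(complete)[0]:
        groups.setdefault(m.data[i].tobytes(), []).append(int(i))

    # deterministic haplotype order: decreasing complete-cell support,
    # then genotype bytes
    keys = sorted(groups, key=lambda k: (-len(groups[k]), k))
    hap_ids = [f"H{i + 1}" for i in range(len(keys))]
    genotypes = {h: np.frombuffer(k, dtype=np.int8).copy() for h, k in zip(hap_ids, keys)}
    members = {h: [m.cell_ids[i] for i in groups[k]] for h, k in zip(hap_ids, keys)}

    unassigned: list[str] = []
    if keys:
        hap_mat = np.stack([genotypes[h] for h in hap_ids])  # H x S
        for i in np.nonzero(~complete)[0]:
            row = m.data[i]
            obs = row != MISSING
            if not obs.any():
                unassigned.append(m.cell_ids[i])
                continue
            compat = np.all(hap_mat[:, obs] == row[obs], axis=1)
            hits = np.nonzero(compat)[0]
            if len(hits) == 1:
                members[hap_ids[hits[0]]].append(m.cell_ids[i])
            else:
                unassigned.append(m.cell_ids[i])
    else:
        unassigned = list(m.cell_ids)

    support = {h: len(members[h]) for h in hap_ids}
    return HaplotypeTable(list(m.site_ids), hap_ids, genotypes, support, members, unassigned)


def filter_haplotypes(t: HaplotypeTable, hf: Threshold,
                      ensure_germline: bool = True) -> HaplotypeTable:
    """Retain haplotypes whose support strictly exceeds the HF threshold.

    The germline (all wild-type) haplotype is always retained when present,
    and appended with zero support when absent and ``ensure_germline`` is
    set — the phylogeny is rooted on the normal-cell sequence.
    """
    n_contrib = sum(t.support.values())
    keep = []
    for h in t.haplotype_ids:
        is_germ = not np.any(t.genotypes[h] == MUT)
        if is_germ:
            keep.append(h)
            continue
        if hf.kind == "absolute_cells":
            ok = t.support[h] > hf.value
        else:
            ok = n_contrib > 0 and t.support[h] / n_contrib > hf.value
        if ok:
            keep.append(h)

    # the all-wild haplotype, if retained, takes the canonical germline id
    renamed = {h: (GERMLINE if not np.any(t.genotypes[h] == MUT) else h) for h in keep}
    genotypes = {renamed[h]: t.genotypes[h] for h in keep}
    support = {renamed[h]: t.support[h] for h in keep}
    members = {renamed[h]: list(t.member_cells[h]) for h in keep}
    hap_ids = [renamed[h] for h in keep]

    has_germ = any(not np.any(genotypes[h] == MUT) for h in hap_ids)
    if ensure_germline and not has_germ:
        g = GERMLINE
        hap_ids.append(g)
        genotypes[g] = np.full(len(t.site_ids), WILD, dtype=np.int8)
        support[g] = 0
        members[g] = []

    if len(hap_ids) < 2:
        raise EmptyResultError(
            "fewer than two haplotypes passed the HF threshold; lower --hf and rerun"
        )
    dropped = [c for h in t.haplotype_ids if h not in keep for c in t.member_cells[h]]
    return HaplotypeTable(list(t.site_ids), hap_ids, genotypes, support, members,
                          list(t.unassigned_cells) + dropped)
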
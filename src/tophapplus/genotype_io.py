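"""Reading, writing and validation of single-cell genotype data.

The central container is :class:`GenotypeMatrix`, a cells x sites grid of
ternary calls: wild-type (0), mutant (1) or missing (3).  The 0/1/3 integer
convention follows the de-facto standard of single-cell mutation-tree tools
(SCITE and its descendants), so matrices written by those tools load without
re-encoding.  CRISPR lineage-tracing indel matrices are supported through
:func:`binarize_indel_matrix`, which expands each (target site, indel allele)
pair into one presence/absence character.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

WILD: int = 0
MUT: int = 1
MISSING: int = 3

#: default token -> state map used by :func:`read_genotype_matrix`
DEFAULT_ENCODING: dict[str, int] = {
    "0": WILD,
    "1": MUT,
    "3": MISSING,
    "?": MISSING,
    "NA": MISSING,
    "-": MISSING,
}

_VALID_STATES = frozenset({WILD, MUT, MISSING})


class GenotypeParseError(ValueError):
    """A token in the input file could not be mapped to a genotype state."""


def _check_ids(ids: list[str], what: str) -> None:
    if len(ids) == 0:
        raise ValueError(f"{what} list must be non-empty")
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what} ids: {dupes[:5]}")


@dataclass
class GenotypeMatrix:
    """Cells x sites ternary observation matrix.

    Parameters
    ----------
    cell_ids : list of str
        Unique row labels.
    site_ids : list of str
        Unique column labels.
    data : ndarray of int8, shape (n_cells, n_sites)
        Entries in {0 (wild-type), 1 (mutant), 3 (missing)}.
    """

    cell_ids: list[str]
    site_ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.site_ids = [str(s) for s in self.site_ids]
        _check_ids(self.cell_ids, "cell")
        _check_ids(self.site_ids, "site")
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.shape != (len(self.cell_ids), len(self.site_ids)):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"({len(self.cell_ids)}, {len(self.site_ids)}) ids"
            )
        bad = set(np.unique(self.data)) - _VALID_STATES
        if bad:
            raise ValueError(f"invalid genotype states {sorted(bad)}; expected 0/1/3")

    # -- basic views -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.cell_ids, columns=self.site_ids)

    def subset_sites(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.site_ids.index(s) for s in keep]
        return GenotypeMatrix(list(self.cell_ids), list(keep), self.data[:, idx])

    def mut_counts(self) -> np.ndarray:
        """Number of cells called mutant at each site."""
        return (self.data == MUT).sum(axis=0)

    def nonmissing_counts(self) -> np.ndarray:
        return (self.data != MISSING).sum(axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.cell_ids == other.cell_ids
            and self.site_ids == other.site_ids
            and np.array_equal(self.data, other.data)
        )


@dataclass
class IndelMatrix:
    """Cells x target-sites grid of indel-allele labels (or MISSING).

    Allele labels are opaque strings compared only for equality; the special
    value ``None`` marks a missing observation at that target site.
    """

    cell_ids: list[str]
    target_sites: list[str]
    entries: list[list[str | None]] = field(repr=False)

    def __post_init__(self) -> None:
        _check_ids(self.cell_ids, "cell")
        _check_ids(self.target_sites, "target site")
        if len(self.entries) != len(self.cell_ids) or any(
            len(row) != len(self.target_sites) for row in self.entries
        ):
            raise ValueError("entries shape does not match id lists")


def read_genotype_matrix(
    path: str | Path,
    dialect: str = "cells-as-rows",
    encoding_map: dict[str, int] | None = None,
    sep: str | None = None,
) -> GenotypeMatrix:
    """Read a delimited genotype matrix.

    Parameters
    ----------
    path : path
        TSV/CSV file with a header row and a leading id column.
    dialect : {"cells-as-rows", "sites-as-rows"}
        ``sites-as-rows`` is the SCITE orientation; the matrix is transposed
        to cells x sites on load.
    encoding_map : dict, optional
        Token to state map; defaults to 0/1 with 3, "?", "NA", "-" missing.
    sep : str, optional
        Field separator; sniffed from the extension when omitted
        (.csv -> comma, otherwise tab).
    """
    path = Path(path)
    if encoding_map is None:
        encoding_map = DEFAULT_ENCODING
    if dialect not in ("cells-as-rows", "sites-as-rows"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"duplicate header ids in {path}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    data = np.empty(df.shape, dtype=np.int8)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            tok = str(raw[i, j]).strip()
            try:
                data[i, j] = encoding_map[tok]
            except KeyError:
                raise GenotypeParseError(
                    f"unmappable token {tok!r} at row {df.index[i]!r}, "
                    f"column {df.columns[j]!r} in {path}"
                ) from None
    if dialect == "sites-as-rows":
        return GenotypeMatrix(list(df.columns), list(df.index), data.T)
    return GenotypeMatrix(list(df.index), list(df.columns), data)


def write_genotype_matrix(m: GenotypeMatrix, path: str | Path, sep: str = "\t") -> None:
    m.to_frame().to_csv(path, sep=sep)


def read_indel_matrix(path: str | Path, missing_tokens: tuple[str, ...] = ("NA", "?", "-", "")) -> IndelMatrix:
    """Read a cells x target-sites table of indel-allele labels."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    entries: list[list[str | None]] = []
    for _, row in df.iterrows():
        entries.append([None if str(v).strip() in missing_tokens else str(v).strip() for v in row])
    return IndelMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), entries)


def binarize_indel_matrix(m: IndelMatrix) -> GenotypeMatrix:
    """Expand an indel matrix into binary presence/absence characters.

    One output site is created per distinct (target site, allele) pair,
    named ``<target_site>:<allele>``.  A cell is mutant at that site iff it
    carries that allele at that target site, wild-type if it carries a
    different observed allele there, and missing if the target site itself
    is missing for the cell.
    """
    alleles_per_site: list[list[str]] = []
    any_allele = False
    for j in range(len(m.target_sites)):
        seen: list[str] = []
        for row in m.entries:
            a = row[j]
            if a is not None and a not in seen:
                seen.append(a)
        seen.sort()
        alleles_per_site.append(seen)
        any_allele = any_allele or bool(seen)
    if not any_allele:
        raise ValueError("indel matrix contains no observed alleles")
    site_ids = [
        f"{m.target_sites[j]}:{a}" for j in range(len(m.target_sites)) for a in alleles_per_site[j]
    ]
    data = np.full((len(m.cell_ids), len(site_ids)), MISSING, dtype=np.int8)
    col = 0
    for j in range(len(m.target_sites)):
        for a in alleles_per_site[j]:
            for i, row in enumerate(m.entries):
                obs = row[j]
                if obs is None:
                    data[i, col] = MISSING
                elif obs == a:
                    data[i, col] = MUT
                else:
                    data[i, col] = WILD
            col += 1
    return GenotypeMatrix(list(m.cell_ids), site_ids, data)


def write_outputs(tree, assignment: pd.DataFrame, rates, outdir: str | Path, report: dict | None = None) -> dict[str, str]:
    """Write the standard result bundle; returns a manifest of paths.

    Files: ``clone_tree.nwk`` (Newick, germline-rooted), ``clone_sequences.tsv``
    (binary genotype per clone), ``cell_assignments.tsv`` (per-cell clone label,
    similarity, doublet statistics), ``run_report.json``.
    """
    from .trees import write_newick  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    nwk = outdir / "clone_tree.nwk"
    nwk.write_text(write_newick(tree) + "\n")
    manifest["tree"] = str(nwk)

    seqs = outdir / "clone_sequences.tsv"
    rows = {}
    for node in tree.preorder():
        g = tree.genotypes.get(node)
        if g is not None:
            rows[node] = np.asarray(g, dtype=int)
    pd.DataFrame.from_dict(rows, orient="index", columns=tree.site_ids).rename_axis("clone").to_csv(seqs, sep="\t")
    manifest["clone_sequences"] = str(seqs)

    assign_path = outdir / "cell_assignments.tsv"
    assignment.to_csv(assign_path, sep="\t", index=False)
    manifest["assignments"] = str(assign_path)

    report = dict(report or {})
    report.setdefault("n_assigned_cells", int((~assignment["clone"].isin(["DOUBLET", "UNINFORMATIVE"])).sum()) if len(assignment) else 0)
    if rates is not None:
        report["fnr"] = float(rates.fnr)
        report["fpr"] = float(rates.fpr)
    rep_path = outdir / "run_report.json"
    rep_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    manifest["report"] = str(rep_path)
    return manifest
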
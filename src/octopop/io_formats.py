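"""Readers and writers for the pipeline's external representations.

Formats handled here:

* allele-count TSV (one row per candidate site from the read mapping),
* genotype CSV (rows = individuals, a ``population`` column, loci columns,
  missing calls written as ``NA``),
* GenePop (two-digit allele codes; the panel is strictly biallelic so only
  codes 01/02/00 are accepted),
* Newick with bootstrap supports as internal node labels,
* the bracketed-SNP marker-table dialect used for the published 12-marker
  sturgeon assignment panel (``<name>\\t<left>[X/Y]<right>``).

Positions are 1-based throughout.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    GenotypeMatrix,
    MarkerRecord,
    PopTree,
    PopTreeNode,
    SiteCounts,
)

_SITE_COLUMNS = ("est_id", "position", "allele_a", "allele_b", "count_a", "count_b")

# genotype code <-> GenePop two-digit diploid code
_GENEPOP_OF_CALL = {0: "0101", 1: "0102", 2: "0202", MISSING: "0000"}
_CALL_OF_GENEPOP = {v: k for k, v in _GENEPOP_OF_CALL.items()}
_CALL_OF_GENEPOP["0201"] = 1  # allele order within a genotype is unordered
_CALL_OF_GENEPOP["00"] = MISSING  # some writers use a single missing code

_BRACKET_RE = re.compile(r"^(?P<left>[^\[\]]*)\[(?P<a>[A-Z])/(?P<b>[A-Z])\](?P<right>[^\[\]]*)$")


# ---------------------------------------------------------------------------
# allele-count TSV


def read_site_counts(path) -> list[SiteCounts]:
    """Read an allele-count TSV into a list of :class:`SiteCounts`.

    Expected header: ``est_id position allele_a allele_b count_a count_b``
    with an optional trailing ``mean_baseq`` column. Row order is preserved.
    Malformed or invariant-violating rows raise ``ValueError`` naming the
    1-based line number.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:6]) != _SITE_COLUMNS:
            raise ValueError(
                f"{path}: header must start with {' '.join(_SITE_COLUMNS)}"
            )
        has_q = len(header) > 6 and header[6] == "mean_baseq"
        sites: list[SiteCounts] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                sites.append(
                    SiteCounts(
                        est_id=fields[0],
                        position=int(fields[1]),
                        allele_a=fields[2],
                        allele_b=fields[3],
                        count_a=int(fields[4]),
                        count_b=int(fields[5]),
                        mean_baseq=float(fields[6]) if has_q and len(fields) > 6 else None,
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return sites


def write_site_counts(sites: Iterable[SiteCounts], path) -> None:
    """Write sites in the TSV dialect accepted by :func:`read_site_counts`."""
    sites = list(sites)
    has_q = any(s.mean_baseq is not None for s in sites)
    cols = list(_SITE_COLUMNS) + (["mean_baseq"] if has_q else [])
    with Path(path).open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in sites:
            row = [s.est_id, str(s.position), s.allele_a, s.allele_b,
                   str(s.count_a), str(s.count_b)]
            if has_q:
                row.append("" if s.mean_baseq is None else repr(s.mean_baseq))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# marker table


def parse_marker_table(text: str) -> list[MarkerRecord]:
    """Parse marker-table text, one ``<name>\\t<left>[X/Y]<right>`` record
    per line, into :class:`MarkerRecord` objects.

    The marker name is split at its final period into accession and 1-based
    SNP position; the bracket must contain exactly two ``/``-separated
    alleles; flanks are validated against the IUPAC nucleotide alphabet.
    """
    records: list[MarkerRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            name, seq = line.split("\t", 1)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: expected <name>\\t<sequence>") from exc
        m = _BRACKET_RE.match(seq.strip())
        if m is None:
            raise ValueError(
                f"line {lineno}: sequence must contain one [X/Y] bracket pair"
            )
        try:
            records.append(
                MarkerRecord(
                    name=name.strip(),
                    left_flank=m.group("left"),
                    right_flank=m.group("right"),
                    allele_a=m.group("a"),
                    allele_b=m.group("b"),
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    return records


def load_marker_panel() -> list[MarkerRecord]:
    """Load the packaged 12-marker sturgeon assignment panel."""
    text = (
        resources.files("octopop.data")
        .joinpath("sturgeon_marker_panel.tsv")
        .read_text()
    )
    return parse_marker_table(text)


# ---------------------------------------------------------------------------
# genotype CSV


def read_genotype_csv(path) -> GenotypeMatrix:
    """Read a genotype CSV: index column of individual ids, a ``population``
    column, then one column per locus with calls 0/1/2 or ``NA``."""
    df = pd.read_csv(path, index_col=0, dtype={"population": str})
    if "population" not in df.columns:
        raise ValueError("genotype CSV must have a 'population' column")
    loci = [c for c in df.columns if c != "population"]
    calls = df[loci].to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    return GenotypeMatrix(
        individuals=[str(i) for i in df.index],
        populations=df["population"].tolist(),
        loci=loci,
        calls=calls,
    )


def write_genotype_csv(matrix: GenotypeMatrix, path) -> None:
    calls = matrix.calls.astype(object)
    calls[matrix.calls == MISSING] = np.nan
    df = pd.DataFrame(calls, index=matrix.individuals, columns=matrix.loci)
    df.insert(0, "population", matrix.populations)
    df.to_csv(path, index_label="individual", na_rep="NA")


# ---------------------------------------------------------------------------
# GenePop


def write_genepop(matrix: GenotypeMatrix, path, title: str = "octopop export") -> None:
    """Write a GenePop file: title line, one locus name per line, ``Pop``
    separators, and per-individual lines ``id ,  0101 0102 ...``.

    Biallelic coding is fixed: 0 -> 0101, 1 -> 0102, 2 -> 0202, missing ->
    0000. Individuals are grouped into Pop blocks by their population label,
    in order of first appearance.
    """
    with Path(path).open("w") as fh:
        fh.write(title + "\n")
        for locus in matrix.loci:
            fh.write(locus + "\n")
        pops = np.asarray(matrix.populations)
        for label in matrix.pop_labels:
            fh.write("Pop\n")
            for i in np.flatnonzero(pops == np.str_(label)):
                codes = " ".join(_GENEPOP_OF_CALL[int(c)] for c in matrix.calls[i])
                fh.write(f"{matrix.individuals[i]} ,  {codes}\n")


def read_genepop(path, pop_labels: list[str] | None = None) -> GenotypeMatrix:
    """Read a biallelic GenePop file into a :class:`GenotypeMatrix`.

    Allele codes other than 01/02/00 raise ``ValueError`` (the pipeline is
    strictly biallelic). Populations are labelled ``pop1``, ``pop2``, ... in
    file order unless ``pop_labels`` is given. Round-trips
    :func:`write_genepop` output exactly when labels are supplied.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError("GenePop file too short")
    # locus names: everything between the title and the first Pop line;
    # a single line may carry comma-separated names
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        loci.extend(tok.strip() for tok in lines[i].split(",") if tok.strip())
        i += 1
    if i == len(lines):
        raise ValueError("GenePop file has no Pop separator")
    individuals: list[str] = []
    populations: list[str] = []
    rows: list[list[int]] = []
    pop_idx = -1
    for lineno, line in enumerate(lines[i:], start=i + 1):
        if not line.strip():
            continue
        if line.strip().lower() == "pop":
            pop_idx += 1
            continue
        if "," not in line:
            raise ValueError(f"line {lineno}: expected 'id , codes'")
        ind, codes_str = line.split(",", 1)
        codes = codes_str.split()
        if len(codes) != len(loci):
            raise ValueError(
                f"line {lineno}: {len(codes)} genotypes for {len(loci)} loci"
            )
        row: list[int] = []
        for code in codes:
            call = _CALL_OF_GENEPOP.get(code)
            if call is None:
                raise ValueError(
                    f"line {lineno}: allele code {code!r} not in 01/02/00"
                )
            row.append(call)
        label = (
            pop_labels[pop_idx]
            if pop_labels is not None
            else f"pop{pop_idx + 1}"
        )
        individuals.append(ind.strip())
        populations.append(label)
        rows.append(row)
    return GenotypeMatrix(individuals, populations, loci, np.array(rows))


# ---------------------------------------------------------------------------
# Newick


def _newick_node(node: PopTreeNode, parent_height: float | None) -> str:
    if node.is_leaf:
        body = node.label
    else:
        inner = ",".join(_newick_node(c, node.height) for c in node.children)
        body = f"({inner})"
        if node.support is not None:
            body += str(int(node.support))
    if parent_height is None:
        return body
    return f"{body}:{parent_height - node.height:.10g}"


def newick_string(tree: PopTree) -> str:
    """Serialize a :class:`PopTree` to Newick, bootstrap supports (if any)
    as internal node labels, branch lengths from the ultrametric heights."""
    return _newick_node(tree.root, None) + ";"


def write_newick(tree: PopTree, path) -> str:
    """Write the tree to ``path`` and return the Newick text."""
    text = newick_string(tree)
    Path(path).write_text(text + "\n")
    return text
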
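"""Core domain containers shared across the pipeline.

All sequence positions are 1-based offsets within their EST reference.
Genotypes are coded functionally diploid: 0 = AA, 1 = AB, 2 = BB and
``MISSING`` (-1) for no call — the three-cluster coding a GoldenGate-style
assay reports for an octoploid even though the underlying loci are
tetrasomic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

#: Missing-genotype sentinel used inside ``GenotypeMatrix.calls``.
MISSING: int = -1

#: Nucleotide alphabet accepted in marker flanking sequences.
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

_NAME_RE = re.compile(r"^(?P<accession>[A-Za-z0-9_]+)\.(?P<position>\d+)$")


@dataclass(frozen=True)
class SiteCounts:
    """Allele read counts at one candidate site of the transcriptome mapping.

    ``count_a``/``count_b`` are per-allele read depths; their sum is the site
    coverage that the discovery filter thresholds on.
    """

    est_id: str
    position: int
    allele_a: str
    allele_b: str
    count_a: int
    count_b: int
    mean_baseq: float | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.allele_a == self.allele_b:
            raise ValueError("allele_a and allele_b must differ")
        if self.count_a < 0 or self.count_b < 0:
            raise ValueError("allele counts must be non-negative")
        if self.mean_baseq is not None and self.mean_baseq < 0:
            raise ValueError("mean_baseq must be >= 0")

    @property
    def depth(self) -> int:
        return self.count_a + self.count_b


@dataclass(frozen=True)
class MarkerRecord:
    """One assignment-panel marker: ``<accession>.<position>`` plus the SNP
    alleles in brackets between two flanking sequences."""

    name: str
    left_flank: str
    right_flank: str
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        m = _NAME_RE.match(self.name)
        if m is None or int(m.group("position")) < 1:
            raise ValueError(
                f"marker name {self.name!r} is not <accession>.<position>"
            )
        for flank in (self.left_flank, self.right_flank):
            if not flank:
                raise ValueError(f"marker {self.name}: empty flank")
            bad = set(flank.upper()) - IUPAC_ALPHABET
            if bad:
                raise ValueError(
                    f"marker {self.name}: non-IUPAC characters {sorted(bad)}"
                )
        if self.allele_a == self.allele_b:
            raise ValueError(f"marker {self.name}: alleles must differ")

    @property
    def accession(self) -> str:
        return self.name.rsplit(".", 1)[0]

    @property
    def position(self) -> int:
        """1-based SNP position within the EST, parsed from the name."""
        return int(self.name.rsplit(".", 1)[1])


class GenotypeMatrix:
    """Individuals x loci biallelic genotype calls with population labels.

    Parameters
    ----------
    individuals : sequence of str
        Sample identifiers, one per row.
    populations : sequence of str
        Population label per individual; every label must occur at least
        once (population blocks of size zero are invalid).
    loci : sequence of str
        Locus identifiers, one per column.
    calls : array-like of int, shape (n_individuals, n_loci)
        Genotype codes 0/1/2 with ``MISSING`` (-1) for no call.
    """

    def __init__(self, individuals, populations, loci, calls) -> None:
        self.individuals = list(individuals)
        self.populations = list(populations)
        self.loci = list(loci)
        self.calls = np.asarray(calls, dtype=np.int8)
        self._validate()

    def _validate(self) -> None:
        n, L = len(self.individuals), len(self.loci)
        if len(self.populations) != n:
            raise ValueError("populations length must match individuals")
        if self.calls.shape != (n, L):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {L})"
            )
        if n == 0 or L == 0:
            raise ValueError("matrix must have >=1 individual and >=1 locus")
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid genotype codes {bad.tolist()}")
        if len(set(self.individuals)) != n:
            raise ValueError("duplicate individual ids")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def pop_labels(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def pop_indices(self, label: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.populations) == np.str_(label))
        if idx.size == 0:
            raise KeyError(f"no individuals in population {label!r}")
        return idx

    def subset_loci(self, loci) -> "GenotypeMatrix":
        """New matrix restricted to ``loci`` (by id or integer index),
        preserving individual order."""
        cols = [
            l if isinstance(l, (int, np.integer)) else self.loci.index(l)
            for l in loci
        ]
        return GenotypeMatrix(
            self.individuals,
            self.populations,
            [self.loci[c] for c in cols],
            self.calls[:, cols],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_individuals} individuals x "
            f"{self.n_loci} loci, {len(self.pop_labels)} populations)"
        )


@dataclass
class PopulationFrequencies:
    """Per-population, per-locus B-allele frequencies with sample sizes.

    ``freq_b`` is (n_pops, n_loci) with NaN where a population has no
    non-missing call at a locus; ``n_obs`` counts non-missing individuals
    (zero for parametric frequencies from the simulator).
    """

    pop_labels: list[str]
    loci: list[str]
    freq_b: np.ndarray
    n_obs: np.ndarray

    def __post_init__(self) -> None:
        self.freq_b = np.asarray(self.freq_b, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=int)
        shape = (len(self.pop_labels), len(self.loci))
        if self.freq_b.shape != shape or self.n_obs.shape != shape:
            raise ValueError("frequency arrays inconsistent with labels")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.freq_b, initial=0.0) < 0 or np.nanmax(
                self.freq_b, initial=0.0
            ) > 1:
                raise ValueError("frequencies must lie in [0, 1]")

    def pop_index(self, label: str) -> int:
        return self.pop_labels.index(label)


@dataclass
class PopDistanceMatrix:
    """Symmetric non-negative pairwise population distances, zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def __getitem__(self, pair) -> float:
        i, j = pair
        if isinstance(i, str):
            i = self.labels.index(i)
        if isinstance(j, str):
            j = self.labels.index(j)
        return float(self.values[i, j])


@dataclass
class PopTreeNode:
    """Node of a rooted ultrametric population tree.

    ``height`` is the distance from this node down to any of its leaf
    descendants (leaves sit at height 0); ``support`` is a bootstrap
    percentage in [0, 100] for internal nodes, if computed.
    """

    height: float
    children: list["PopTreeNode"] = field(default_factory=list)
    label: str | None = None
    support: int | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PopTree:
    """Rooted ultrametric tree over population labels."""

    root: PopTreeNode

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets of all internal nodes below the root (the root clade,
        containing every leaf, is uninformative and excluded)."""
        out: set[frozenset[str]] = set()

        def walk(node: PopTreeNode) -> None:
            if not node.is_leaf:
                if node is not self.root:
                    out.add(frozenset(node.leaves()))
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    def internal_nodes(self) -> list[PopTreeNode]:
        out: list[PopTreeNode] = []

        def walk(node: PopTreeNode) -> None:
            if not node.is_leaf:
                out.append(node)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    def is_ultrametric(self, tol: float = 1e-12) -> bool:
        """True if every root-to-leaf path has the same length."""
        depths: list[float] = []

        def walk(node: PopTreeNode, up: float) -> None:
            if node.is_leaf:
                depths.append(up)
            for c in node.children:
                walk(c, up + (node.height - c.height))

        walk(self.root, 0.0)
        return max(depths) - min(depths) <= tol
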
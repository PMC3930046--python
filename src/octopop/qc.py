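"""Post-genotyping locus QC.

On a polyploid panel typed with a diploid-style assay, an uninformative
locus is diagnostic of an upstream artifact: a locus heterozygous in every
individual is almost certainly a paralog pair fixed for alternative alleles
(the assay sees both paralogs at once), and a locus with one genotype in all
individuals is simply monomorphic in the sample. Both are dropped before any
population analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .types import MISSING, GenotypeMatrix


@dataclass
class QCReport:
    """Tally of the locus filter: input = retained + every dropped category
    (all-heterozygous, monomorphic, all-missing), categories disjoint."""

    n_input_loci: int
    n_retained: int
    n_all_heterozygous: int
    n_monomorphic: int
    n_all_missing: int
    dropped_locus_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        total = (
            self.n_retained
            + self.n_all_heterozygous
            + self.n_monomorphic
            + self.n_all_missing
        )
        if total != self.n_input_loci:
            raise ValueError("QC categories must partition the input loci")


class InformativeLocusFilter(BaseEstimator, TransformerMixin):
    """Transformer dropping loci that cannot inform population comparisons.

    ``fit`` inspects a calls array (individuals x loci, codes 0/1/2 and -1
    missing) and marks each locus: retained if its non-missing calls take
    more than one value; dropped as ``all_heterozygous`` (all 1 — paralog
    artifact), ``monomorphic`` (all 0 or all 2), or ``all_missing``.
    ``transform`` removes the dropped columns, preserving row order.

    Fitted attributes: ``keep_mask_`` (bool per locus), ``category_``
    (str per locus: retained/all_heterozygous/monomorphic/all_missing).
    """

    def fit(self, X, y=None) -> "InformativeLocusFilter":
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[0] == 0 or X.shape[1] == 0:
            raise ValueError("X must be a non-empty 2-D calls array")
        n, L = X.shape
        category = np.empty(L, dtype=object)
        for j in range(L):
            col = X[:, j]
            vals = np.unique(col[col != MISSING])
            if vals.size == 0:
                category[j] = "all_missing"
            elif vals.size > 1:
                category[j] = "retained"
            elif vals[0] == 1:
                category[j] = "all_heterozygous"
            else:
                category[j] = "monomorphic"
        self.category_ = category
        self.keep_mask_ = category == "retained"
        self.n_features_in_ = L
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of loci than fit saw")
        return X[:, self.keep_mask_]


def filter_informative_loci(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, QCReport]:
    """Apply :class:`InformativeLocusFilter` to a :class:`GenotypeMatrix`.

    Returns the filtered matrix (individual order preserved) and an exact
    :class:`QCReport`. Idempotent: a second application is the identity.
    Raises if no locus survives (the downstream analyses need >=1).
    """
    filt = InformativeLocusFilter().fit(matrix.calls)
    cat = filt.category_
    keep = filt.keep_mask_
    if not keep.any():
        raise ValueError("no informative locus remains after QC")
    report = QCReport(
        n_input_loci=matrix.n_loci,
        n_retained=int(keep.sum()),
        n_all_heterozygous=int((cat == "all_heterozygous").sum()),
        n_monomorphic=int((cat == "monomorphic").sum()),
        n_all_missing=int((cat == "all_missing").sum()),
        dropped_locus_ids=[l for l, k in zip(matrix.loci, keep) if not k],
    )
    filtered = GenotypeMatrix(
        matrix.individuals,
        matrix.populations,
        [l for l, k in zip(matrix.loci, keep) if k],
        filt.transform(matrix.calls),
    )
    return filtered, report


def mapping_fraction(mapped: int, total: int, decimals: int = 1) -> float:
    """Percentage of reads mapped, rounded half-up to ``decimals`` places.

    Half-up (not banker's) rounding so printed report arithmetic like
    821,892 of 252,186,716 -> 0.3% reproduces exactly.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= mapped <= total:
        raise ValueError("mapped must be in [0, total]")
    pct = Decimal(100 * mapped) / Decimal(total)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))
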
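"""SNP discovery under the two-tetrasomic-paralog octoploid dosage model.

A candidate site in the transcriptome mapping carries eight allele copies
(two paralogous tetrasomic loci). The B-allele read fraction at a site with
total B-dosage d in {0..8} and symmetric per-read error e is

    p_d = (d/8)(1 - e) + (1 - d/8) e .

Classification is by maximum binomial likelihood over the nine dosages
rather than a hard ratio window — at high coverage this reduces to the
familiar rules of thumb: d = 2 or 6 is the ~3:1 site where one paralog is
fixed (AAAA) and the other is a balanced heterozygote (AABB), i.e. a usable
within-locus SNP; d = 4 is the ~1:1 signature of a fixed difference between
paralogs (a PSV, not a polymorphism); d = 0 or 8 is monomorphic. Odd dosages
(unbalanced heterozygotes) are kept distinct as ``other_heterozygous``
because they do not type cleanly on a diploid-style assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .types import SiteCounts
from .simulate import expected_b_fraction

#: site_class values, in rough order of downstream usefulness
SITE_CLASSES = (
    "monomorphic",
    "candidate_snp",
    "psv",
    "other_heterozygous",
    "low_coverage",
)

_CLASS_OF_DOSAGE = {
    0: "monomorphic",
    1: "other_heterozygous",
    2: "candidate_snp",
    3: "other_heterozygous",
    4: "psv",
    5: "other_heterozygous",
    6: "candidate_snp",
    7: "other_heterozygous",
    8: "monomorphic",
}


@dataclass(frozen=True)
class SiteClassification:
    """Dosage call for one site: the 9-dosage log-likelihood profile, its
    argmax, and the derived class label."""

    site: SiteCounts
    mle_dosage: int
    log_likelihoods: np.ndarray
    site_class: str

    @property
    def likelihood_margin(self) -> float:
        """Best minus runner-up log-likelihood; 0 on a tie, inf when only
        one dosage has finite likelihood."""
        ll = np.sort(self.log_likelihoods)[::-1]
        return float(ll[0] - ll[1])


def dosage_log_likelihoods(count_b, depth, error_rate: float) -> np.ndarray:
    """Binomial log-likelihood of ``count_b`` of ``depth`` B reads under each
    total dosage d in 0..8. Vectorized: scalar inputs give shape (9,), array
    inputs shape (n, 9)."""
    scalar = np.isscalar(count_b)
    count_b = np.atleast_1d(np.asarray(count_b))
    depth = np.atleast_1d(np.asarray(depth))
    p = np.array([expected_b_fraction(d, error_rate) for d in range(9)])
    ll = stats.binom.logpmf(count_b[:, None], depth[:, None], p[None, :])
    return ll[0] if scalar else ll


class SiteDosageClassifier(BaseEstimator):
    """Maximum-likelihood dosage classifier for octoploid allele-count sites.

    Stateless in the sklearn sense (``fit`` only validates parameters);
    ``predict`` maps arrays of (count_a, count_b) to class labels and
    ``predict_dosage`` to MLE dosages. Ties in the likelihood profile are
    broken toward ``other_heterozygous``, the conservative choice that keeps
    ambiguous sites out of the SNP panel.

    Parameters
    ----------
    error_rate : float, default 0.01
        Symmetric per-read sequencing error, in [0, 0.5).
    min_coverage : int, default 100
        Sites with total depth below this are labelled ``low_coverage``.
    """

    def __init__(self, error_rate: float = 0.01, min_coverage: int = 100):
        self.error_rate = error_rate
        self.min_coverage = min_coverage

    def _check_params(self) -> None:
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")

    def fit(self, X=None, y=None) -> "SiteDosageClassifier":
        self._check_params()
        self.classes_ = np.array(SITE_CLASSES)
        self.dosage_probs_ = np.array(
            [expected_b_fraction(d, self.error_rate) for d in range(9)]
        )
        return self

    def _ll_matrix(self, count_a, count_b) -> np.ndarray:
        count_a = np.asarray(count_a, dtype=np.int64)
        count_b = np.asarray(count_b, dtype=np.int64)
        depth = count_a + count_b
        p = np.array([expected_b_fraction(d, self.error_rate) for d in range(9)])
        return stats.binom.logpmf(count_b[:, None], depth[:, None], p[None, :])

    def predict_dosage(self, count_a, count_b):
        """MLE total dosage per site and a tie flag.

        Returns ``(dosage, tied)`` arrays; on a tied maximum the reported
        dosage is the smallest tied value.
        """
        self.fit()
        ll = self._ll_matrix(count_a, count_b)
        best = ll.max(axis=1)
        # smallest dosage attaining the max; flag any multiplicity
        is_max = ll >= best[:, None] - 1e-12
        dosage = is_max.argmax(axis=1)
        tied = is_max.sum(axis=1) > 1
        return dosage, tied

    def predict(self, count_a, count_b) -> np.ndarray:
        """Site class per site, applying the coverage gate first."""
        count_a = np.asarray(count_a, dtype=np.int64)
        count_b = np.asarray(count_b, dtype=np.int64)
        dosage, tied = self.predict_dosage(count_a, count_b)
        labels = np.array([_CLASS_OF_DOSAGE[int(d)] for d in dosage], dtype=object)
        labels[tied] = "other_heterozygous"
        labels[count_a + count_b < self.min_coverage] = "low_coverage"
        return labels


def classify_site(
    site: SiteCounts, error_rate: float = 0.01, min_coverage: int = 100
) -> SiteClassification:
    """Classify one site under the nine-dosage model.

    Depth below ``min_coverage`` (including zero) short-circuits to
    ``low_coverage``; the likelihood profile is still reported (it is
    constant-zero at depth 0, where every dosage fits equally).
    """
    clf = SiteDosageClassifier(error_rate=error_rate, min_coverage=min_coverage)
    ll = clf.fit()._ll_matrix([site.count_a], [site.count_b])[0]
    dosage, tied = clf.predict_dosage([site.count_a], [site.count_b])
    mle = int(dosage[0])
    if site.depth < min_coverage:
        cls = "low_coverage"
    elif tied[0]:
        cls = "other_heterozygous"
    else:
        cls = _CLASS_OF_DOSAGE[mle]
    return SiteClassification(
        site=site, mle_dosage=mle, log_likelihoods=ll, site_class=cls
    )


def call_candidates(
    sites,
    error_rate: float = 0.01,
    min_coverage: int = 100,
    max_panel: int = 384,
) -> list[SiteClassification]:
    """Rank usable SNP candidates for a genotyping panel.

    Keeps only ``candidate_snp`` classifications and ranks by descending
    coverage, then descending likelihood margin (best dosage vs runner-up),
    then (est_id, position) so the order is fully deterministic; the list is
    truncated to ``max_panel`` (default 384, one GoldenGate plate). An input
    with no candidates yields an empty list.
    """
    if max_panel < 1:
        raise ValueError("max_panel must be >= 1")
    kept = [
        c
        for c in (classify_site(s, error_rate, min_coverage) for s in sites)
        if c.site_class == "candidate_snp"
    ]
    kept.sort(
        key=lambda c: (
            -c.site.depth,
            -c.likelihood_margin,
            c.site.est_id,
            c.site.position,
        )
    )
    return kept[:max_panel]


def coverage_tally(
    sites, thresholds, error_rate: float = 0.01
) -> pd.DataFrame:
    """Count sites passing each coverage threshold, total and heterozygous.

    A site counts as heterozygous when its MLE dosage is in 1..7 (any class
    other than monomorphic), judged without a coverage gate so the same call
    is tallied consistently across thresholds. Returns a DataFrame indexed
    by threshold with columns ``n_total`` and ``n_heterozygous``; both are
    monotone non-increasing in the threshold.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    sites = list(sites)
    depths = np.array([s.depth for s in sites], dtype=int)
    if sites:
        clf = SiteDosageClassifier(error_rate=error_rate, min_coverage=1)
        dosage, _ = clf.predict_dosage(
            [s.count_a for s in sites], [s.count_b for s in sites]
        )
        het = (dosage >= 1) & (dosage <= 7)
    else:
        het = np.zeros(0, dtype=bool)
    rows = {
        t: {
            "n_total": int((depths >= t).sum()),
            "n_heterozygous": int(((depths >= t) & het).sum()),
        }
        for t in thresholds
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "min_coverage"
    return out
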
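"""Frequency-based population assignment and informative-locus selection.

An individual is assigned to the population in which its multilocus genotype
is most likely under Hardy–Weinberg proportions: for B-allele frequency p,
genotype probabilities (1-p)^2, 2p(1-p), p^2. Reference frequencies of 0 or
1 are nudged to 1/(2n+1) (respectively 2n/(2n+1)) before taking logs — the
standard assignment-test convention so that a single novel allele does not
produce an infinite penalty. Accuracy is estimated leave-one-out: each
individual is scored against its own population's frequencies recomputed
without it.

Locus ranking follows the resampled-dataset strategy used for SNP panel
design: several datasets are simulated by resampling individuals per
population from the observed allele frequencies (default sizes 100, 100,
100 and 500), each locus is scored in each dataset by its mean single-locus
leave-one-out log-likelihood ratio (true population vs best other), and the
consensus panel keeps loci ranked in the top K of every dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .types import MISSING, GenotypeMatrix, PopulationFrequencies

#: Assignment label used when two or more populations tie for the maximum
#: log-likelihood; tied individuals count as incorrectly assigned.
UNASSIGNED = "<unassigned>"

_TIE_TOL = 1e-9


def _corrected_freq(p: np.ndarray, n_obs: np.ndarray) -> np.ndarray:
    """Clamp frequencies away from 0/1 with the 1/(2n+1) rule; populations
    with no observation at a locus fall back to an uninformative 0.5."""
    p = np.asarray(p, dtype=float)
    n_obs = np.asarray(n_obs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lo = 1.0 / (2.0 * n_obs + 1.0)
    out = np.where(np.isnan(p) | (n_obs == 0), 0.5, p)
    out = np.where(out <= 0.0, lo, out)
    out = np.where(out >= 1.0, 1.0 - lo, out)
    return out


def _genotype_logprob_table(p: np.ndarray) -> np.ndarray:
    """Stack of HWE log genotype probabilities for codes 0/1/2 given
    corrected frequencies ``p``; shape (3, *p.shape)."""
    logp = np.log(p)
    log1p = np.log1p(-p)
    return np.stack([2.0 * log1p, np.log(2.0) + logp + log1p, 2.0 * logp])


def _loglik_matrix(X: np.ndarray, pcorr: np.ndarray) -> np.ndarray:
    """Log-likelihood of each row of ``X`` (n, L; -1 missing) under each
    population's corrected frequencies ``pcorr`` (P, L); returns (n, P)."""
    n, L = X.shape
    P = pcorr.shape[0]
    obs = X != MISSING
    Gc = np.clip(X, 0, 2)
    ll = np.zeros((n, P))
    cols = np.arange(L)
    for k in range(P):
        table = _genotype_logprob_table(pcorr[k])  # (3, L)
        per_locus = table[Gc, cols]  # (n, L)
        ll[:, k] = np.where(obs, per_locus, 0.0).sum(axis=1)
    return ll


class PopulationAssigner(ClassifierMixin, BaseEstimator):
    """Hardy–Weinberg frequency classifier for biallelic genotype calls.

    ``fit`` takes a calls array ``X`` (n_individuals, n_loci; codes 0/1/2,
    -1 missing) and population labels ``y``; it stores per-population allele
    frequencies and sample sizes. ``predict`` assigns each row to the
    population maximising the HWE log-likelihood; exact ties return
    ``UNASSIGNED``.

    Fitted attributes: ``classes_``, ``freq_b_`` (P, L), ``n_obs_`` (P, L).
    """

    def fit(self, X, y) -> "PopulationAssigner":
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (individuals x loci)")
        if y.shape[0] != X.shape[0]:
            raise ValueError("y length must match X rows")
        self.classes_ = np.unique(y)
        P, L = len(self.classes_), X.shape[1]
        self.freq_b_ = np.full((P, L), np.nan)
        self.n_obs_ = np.zeros((P, L), dtype=int)
        for k, label in enumerate(self.classes_):
            calls = X[y == label]
            obs = calls != MISSING
            self.n_obs_[k] = obs.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                self.freq_b_[k] = np.where(
                    self.n_obs_[k] > 0,
                    np.where(obs, calls, 0).sum(axis=0) / (2.0 * self.n_obs_[k]),
                    np.nan,
                )
        self.n_features_in_ = L
        return self

    def predict_log_likelihood(self, X) -> np.ndarray:
        """(n, n_populations) HWE log-likelihoods with 1/(2n+1) correction."""
        X = np.asarray(X)
        pcorr = _corrected_freq(self.freq_b_, self.n_obs_)
        return _loglik_matrix(X, pcorr)

    def predict(self, X) -> np.ndarray:
        ll = self.predict_log_likelihood(X)
        best = ll.max(axis=1)
        tied = (ll >= best[:, None] - _TIE_TOL).sum(axis=1) > 1
        out = self.classes_[ll.argmax(axis=1)].astype(object)
        out[tied] = UNASSIGNED
        return out


def assignment_loglik(
    genotypes, freqs: PopulationFrequencies, loci=None
) -> pd.Series:
    """Per-population HWE log-likelihood of one individual's genotypes.

    ``genotypes`` is a length-n_loci vector of calls (codes 0/1/2, -1
    missing) aligned with ``freqs.loci``; ``loci`` optionally restricts the
    evaluation to a subset (ids or indices) and must be non-empty. The
    caller is responsible for the leave-one-out contract (frequencies must
    exclude the focal individual if it was part of the reference sample).
    """
    g = np.asarray(genotypes)
    if g.shape != (len(freqs.loci),):
        raise ValueError("genotypes must align with freqs.loci")
    if loci is None:
        cols = np.arange(len(freqs.loci))
    else:
        loci = list(loci)
        if not loci:
            raise ValueError("locus subset must be non-empty")
        cols = np.array([
            l if isinstance(l, (int, np.integer)) else freqs.loci.index(l)
            for l in loci
        ])
    pcorr = _corrected_freq(freqs.freq_b[:, cols], freqs.n_obs[:, cols])
    ll = _loglik_matrix(g[cols][None, :], pcorr)[0]
    return pd.Series(ll, index=list(freqs.pop_labels))


@dataclass
class AssignmentResult:
    """Leave-one-out assignment outcome: per-individual table, overall and
    per-population accuracies, and the confusion matrix (rows = true
    population, columns = assigned, including ``UNASSIGNED``)."""

    table: pd.DataFrame
    log_likelihoods: pd.DataFrame
    overall_accuracy: float
    per_pop_accuracy: dict
    confusion: pd.DataFrame


def leave_one_out_accuracy(matrix: GenotypeMatrix, loci=None) -> AssignmentResult:
    """Leave-one-out assignment over all individuals.

    Each individual is assigned with its own population's allele frequencies
    recomputed without it (other populations keep their full-sample
    frequencies). Ties are recorded as ``UNASSIGNED`` and count as
    incorrect. Every population must have at least two individuals.
    """
    labels = matrix.pop_labels
    for label in labels:
        if len(matrix.pop_indices(label)) < 2:
            raise ValueError(
                f"population {label!r} has fewer than 2 individuals"
            )
    if loci is None:
        sub = matrix
    else:
        sub = matrix.subset_loci(loci)
    X = sub.calls.astype(int)
    y = np.asarray(sub.populations)
    clf = PopulationAssigner().fit(X, y)
    classes = list(clf.classes_)

    # per-population allele-copy sums and observation counts, for O(1)
    # leave-one-out frequency updates
    S = np.zeros_like(clf.freq_b_)
    for k, label in enumerate(classes):
        calls = X[y == label]
        obs = calls != MISSING
        S[k] = np.where(obs, calls, 0).sum(axis=0)

    n = X.shape[0]
    ll = np.zeros((n, len(classes)))
    pcorr_full = _corrected_freq(clf.freq_b_, clf.n_obs_)
    for i in range(n):
        k = classes.index(y[i])
        obs_i = X[i] != MISSING
        m_loo = clf.n_obs_[k] - obs_i
        s_loo = S[k] - np.where(obs_i, X[i], 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_loo = np.where(m_loo > 0, s_loo / (2.0 * m_loo), np.nan)
        pcorr = pcorr_full.copy()
        pcorr[k] = _corrected_freq(p_loo, m_loo)
        ll[i] = _loglik_matrix(X[i][None, :], pcorr)[0]

    best = ll.max(axis=1)
    tied = (ll >= best[:, None] - _TIE_TOL).sum(axis=1) > 1
    assigned = np.asarray(classes, dtype=object)[ll.argmax(axis=1)]
    assigned[tied] = UNASSIGNED
    correct = (assigned == y) & ~tied

    table = pd.DataFrame(
        {
            "individual": sub.individuals,
            "true_pop": y,
            "assigned_pop": assigned,
            "correct": correct,
        }
    )
    per_pop = {
        label: float(correct[y == label].mean()) for label in labels
    }
    confusion = pd.crosstab(
        table["true_pop"], table["assigned_pop"], dropna=False
    ).reindex(index=labels, columns=classes + [UNASSIGNED], fill_value=0)
    return AssignmentResult(
        table=table,
        log_likelihoods=pd.DataFrame(ll, index=sub.individuals, columns=classes),
        overall_accuracy=float(correct.mean()),
        per_pop_accuracy=per_pop,
        confusion=confusion,
    )


@dataclass
class LocusRanking:
    """Locus informativeness over resampled datasets: full per-dataset
    orderings, per-locus scores, and the consensus panel (loci in the top K
    of every dataset, ordered by mean score)."""

    per_dataset_order: list
    scores: pd.DataFrame  # loci x datasets, mean LLR score
    consensus: list
    top_k: int


def _single_locus_scores(
    sim_calls: np.ndarray, sim_pops: np.ndarray, classes: list
) -> np.ndarray:
    """Mean per-individual single-locus leave-one-out log-likelihood ratio
    (true population vs best other) for every locus; shape (L,)."""
    P = len(classes)
    n, L = sim_calls.shape
    S = np.zeros((P, L))
    M = np.zeros((P, L))
    for k, label in enumerate(classes):
        calls = sim_calls[sim_pops == label]
        obs = calls != MISSING
        M[k] = obs.sum(axis=0)
        S[k] = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_full = np.where(M > 0, S / (2.0 * M), np.nan)
    pcorr_full = _corrected_freq(p_full, M)  # (P, L)
    tables_full = np.stack([_genotype_logprob_table(pcorr_full[k]) for k in range(P)])
    # tables_full: (P, 3, L)

    pop_index = np.array([classes.index(lbl) for lbl in sim_pops])
    obs_all = sim_calls != MISSING
    Gc = np.clip(sim_calls, 0, 2)
    cols = np.arange(L)

    # log-probs of each individual's genotype under every population's
    # full-sample frequencies: (n, P, L)
    ll = np.stack([tables_full[k][Gc, cols] for k in range(P)], axis=1)

    # replace each individual's own-population entry by its leave-one-out value
    m_loo = M[pop_index] - obs_all  # (n, L)
    s_loo = S[pop_index] - np.where(obs_all, sim_calls, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_loo = np.where(m_loo > 0, s_loo / (2.0 * m_loo), np.nan)
    pcorr_loo = _corrected_freq(p_loo, m_loo)  # (n, L)
    table_loo = _genotype_logprob_table(pcorr_loo)  # (3, n, L)
    rows = np.arange(n)
    ll[rows, pop_index, :] = table_loo[Gc, rows[:, None], cols]

    ll_true = ll[rows, pop_index, :]  # (n, L)
    ll_masked = ll.copy()
    ll_masked[rows, pop_index, :] = -np.inf
    ll_best_other = ll_masked.max(axis=1)  # (n, L)
    llr = np.where(obs_all, ll_true - ll_best_other, np.nan)
    with np.errstate(invalid="ignore"):
        return np.nanmean(llr, axis=0)


def rank_loci(
    matrix: GenotypeMatrix,
    resample_sizes=(100, 100, 100, 500),
    seed: int = 0,
    top_k: int = 12,
) -> LocusRanking:
    """Rank loci by assignment power over resampled datasets.

    For each entry of ``resample_sizes`` a dataset is simulated by drawing
    that many individuals per population, genotypes sampled under HWE from
    the observed population frequencies. Each locus is scored by its mean
    single-locus leave-one-out log-likelihood ratio and ranked per dataset;
    the consensus panel keeps loci ranked in the top ``top_k`` of every
    dataset, ordered by mean score across datasets (descending, locus id as
    final tie-break). Reproducible under ``seed``.
    """
    resample_sizes = list(resample_sizes)
    if not resample_sizes:
        raise ValueError("resample_sizes must be non-empty")
    rng = np.random.default_rng(seed)
    labels = matrix.pop_labels
    clf = PopulationAssigner().fit(matrix.calls.astype(int), np.asarray(matrix.populations))
    classes = list(clf.classes_)
    L = matrix.n_loci

    score_cols = {}
    per_dataset_order = []
    for r, size in enumerate(resample_sizes):
        blocks, pops = [], []
        for label in labels:
            k = classes.index(label)
            p = clf.freq_b_[k]
            p_draw = np.where(np.isnan(p), 0.5, p)
            blocks.append(rng.binomial(2, p_draw, size=(size, L)))
            pops.extend([label] * size)
        sim_calls = np.vstack(blocks)
        scores = _single_locus_scores(sim_calls, np.asarray(pops), classes)
        score_cols[f"dataset{r+1} (n={size})"] = scores
        order = sorted(
            range(L), key=lambda j: (-scores[j], matrix.loci[j])
        )
        per_dataset_order.append([matrix.loci[j] for j in order])

    scores_df = pd.DataFrame(score_cols, index=matrix.loci)
    in_all = set(matrix.loci)
    for order in per_dataset_order:
        in_all &= set(order[:top_k])
    mean_scores = scores_df.mean(axis=1)
    consensus = sorted(in_all, key=lambda l: (-mean_scores[l], l))
    return LocusRanking(
        per_dataset_order=per_dataset_order,
        scores=scores_df,
        consensus=consensus,
        top_k=top_k,
    )


@dataclass
class PanelSelection:
    """A minimal locus panel: the chosen loci, the leave-one-out accuracy it
    achieves, and whether the requested target was met."""

    loci: list
    accuracy: float
    target_met: bool


def select_min_panel(
    matrix: GenotypeMatrix, ranking: LocusRanking, target_accuracy: float
) -> PanelSelection:
    """Smallest prefix of the consensus ranking whose leave-one-out overall
    accuracy reaches ``target_accuracy``.

    If the consensus set is empty the mean-score ordering over all loci is
    used instead; if even the full candidate list misses the target, the
    full list is returned with ``target_met=False``.
    """
    if not 0 < target_accuracy <= 1:
        raise ValueError("target_accuracy must be in (0, 1]")
    candidates = ranking.consensus
    if not candidates:
        mean_scores = ranking.scores.mean(axis=1)
        candidates = sorted(
            ranking.scores.index, key=lambda l: (-mean_scores[l], l)
        )
    accuracy = 0.0
    for k in range(1, len(candidates) + 1):
        accuracy = leave_one_out_accuracy(matrix, candidates[:k]).overall_accuracy
        if accuracy >= target_accuracy:
            return PanelSelection(
                loci=list(candidates[:k]), accuracy=accuracy, target_met=True
            )
    return PanelSelection(
        loci=list(candidates), accuracy=accuracy, target_met=False
    )
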
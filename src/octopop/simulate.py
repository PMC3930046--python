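"""Synthetic data with the statistical structure the pipeline assumes.

Two generators:

* octoploid read counts at sites governed by two paralogous tetrasomic loci
  (eight allele copies total), with symmetric sequencing error — the setting
  in which a true within-locus SNP (one paralog AAAA, the other AABB; total
  B-dosage 2 of 8) shows a ~3:1 read ratio while a fixed paralog difference
  (AAAA + BBBB; dosage 4) shows ~1:1;

* multi-population biallelic genotype matrices under the Balding–Nichols
  drift model, so pairwise differentiation is controlled by a single
  per-population parameter F that downstream F_ST estimators should recover.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import MISSING, GenotypeMatrix, PopulationFrequencies, SiteCounts

#: Default study populations: Volga and Ural River Russian sturgeon,
#: Azov Sea Russian sturgeon, Persian sturgeon, Siberian sturgeon.
STUDY_POP_LABELS = ("GUE_vol", "GUE_ur", "GUE_azov", "PERS", "BAE")
STUDY_POP_SIZES = (14, 14, 5, 28, 5)
STUDY_N_LOCI = 123
#: Per-population drift from the common ancestor: the two Caspian river
#: populations nearly identical, Azov modestly diverged, Persian more,
#: Siberian the outgroup.
STUDY_DIVERGENCE = (0.02, 0.02, 0.08, 0.15, 0.30)


def expected_b_fraction(dosage: int, error_rate: float) -> float:
    """Expected B-allele read fraction at a site with ``dosage`` B copies of
    the 8 allele copies across both tetrasomic paralogs, with symmetric
    per-read error ``error_rate``."""
    if not 0 <= dosage <= 8:
        raise ValueError("dosage must be in 0..8")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    d = dosage / 8.0
    return d * (1.0 - error_rate) + (1.0 - d) * error_rate


@dataclass(frozen=True)
class OctoSiteConfig:
    """One simulated site: B-allele copies in each tetrasomic paralog set,
    sequencing depth, and symmetric per-read error rate."""

    dosage_paralog1: int
    dosage_paralog2: int
    depth: int
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        for d in (self.dosage_paralog1, self.dosage_paralog2):
            if not 0 <= d <= 4:
                raise ValueError("per-paralog dosage must be in 0..4")
        if self.depth < 1:
            raise ValueError("depth must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")

    @property
    def total_dosage(self) -> int:
        return self.dosage_paralog1 + self.dosage_paralog2


@dataclass(frozen=True)
class SimulatedSite:
    """A simulated site together with its true total dosage, for evaluating
    the discovery classifier against ground truth."""

    site: SiteCounts
    true_dosage: int


def sim_octoploid_site(config: OctoSiteConfig, seed, est_id: str = "SIM",
                       position: int = 1) -> SimulatedSite:
    """Draw read counts for one octoploid site.

    ``count_b ~ Binomial(depth, p)`` with
    ``p = (d/8)(1-e) + (1-d/8)e`` for total dosage d and error rate e;
    ``count_a = depth - count_b``. ``seed`` may be an int or a Generator.
    """
    rng = np.random.default_rng(seed)
    p = expected_b_fraction(config.total_dosage, config.error_rate)
    count_b = int(rng.binomial(config.depth, p))
    site = SiteCounts(
        est_id=est_id,
        position=position,
        allele_a="A",
        allele_b="B",
        count_a=config.depth - count_b,
        count_b=count_b,
    )
    return SimulatedSite(site=site, true_dosage=config.total_dosage)


def sim_sites(dosages, depth: int, error_rate: float, seed) -> list[SimulatedSite]:
    """Vector version: one site per entry of ``dosages`` (total B-dosage in
    0..8), all at the same depth and error rate, under one seed."""
    rng = np.random.default_rng(seed)
    dosages = np.asarray(dosages, dtype=int)
    p = np.array([expected_b_fraction(int(d), error_rate) for d in dosages])
    counts_b = rng.binomial(depth, p)
    return [
        SimulatedSite(
            site=SiteCounts(
                est_id=f"SIM{i:06d}",
                position=1,
                allele_a="A",
                allele_b="B",
                count_a=int(depth - cb),
                count_b=int(cb),
            ),
            true_dosage=int(d),
        )
        for i, (d, cb) in enumerate(zip(dosages, counts_b))
    ]


@dataclass
class PopSimConfig:
    """Balding–Nichols population-simulation settings.

    ``divergence`` is the drift parameter F per population (scalar or one
    value per population); each population's allele frequency at a locus is
    drawn from ``Beta(p0(1-F)/F, (1-p0)(1-F)/F)`` around the ancestral
    frequency p0, so the expected F_ST against the ancestor is F.
    """

    n_pops: int = len(STUDY_POP_LABELS)
    pop_sizes: tuple = STUDY_POP_SIZES
    n_loci: int = STUDY_N_LOCI
    divergence: tuple = STUDY_DIVERGENCE
    ancestral_freq_range: tuple = (0.1, 0.9)
    missing_rate: float = 0.0
    seed: int = 0
    pop_labels: tuple = STUDY_POP_LABELS

    def __post_init__(self) -> None:
        if self.n_pops < 2:
            raise ValueError("need >=2 populations")
        if len(self.pop_sizes) != self.n_pops:
            raise ValueError("pop_sizes length must equal n_pops")
        if any(s < 1 for s in self.pop_sizes):
            raise ValueError("population sizes must be positive")
        if np.isscalar(self.divergence):
            self.divergence = (float(self.divergence),) * self.n_pops
        if len(self.divergence) != self.n_pops:
            raise ValueError("divergence length must equal n_pops")
        if any(not 0 <= f < 1 for f in self.divergence):
            raise ValueError("divergence F must be in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("ancestral_freq_range must lie within (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if len(self.pop_labels) != self.n_pops:
            self.pop_labels = tuple(f"pop{i+1}" for i in range(self.n_pops))


def drift_frequencies(p0, F: float, rng) -> np.ndarray:
    """One Balding–Nichols draw: population frequencies drifted from
    ancestral frequencies ``p0`` with parameter F (F = 0 returns ``p0``).
    Building block for hierarchical scenarios (lineages, then populations
    within lineages)."""
    p0 = np.asarray(p0, dtype=float)
    if not 0 <= F < 1:
        raise ValueError("F must be in [0, 1)")
    if F == 0.0:
        return p0.copy()
    scale = (1.0 - F) / F
    return rng.beta(p0 * scale, (1.0 - p0) * scale)


def sim_population_frequencies(config: PopSimConfig) -> PopulationFrequencies:
    """Draw per-population B-allele frequencies under Balding–Nichols drift.

    F = 0 is handled as the exact limit (the population copies the ancestral
    frequency). ``n_obs`` is zero everywhere: these are parametric truths,
    not sample estimates.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_freq_range
    p0 = rng.uniform(lo, hi, size=config.n_loci)
    freq = np.empty((config.n_pops, config.n_loci))
    for k, f in enumerate(config.divergence):
        freq[k] = drift_frequencies(p0, f, rng)
    return PopulationFrequencies(
        pop_labels=list(config.pop_labels),
        loci=[f"locus{j+1:04d}" for j in range(config.n_loci)],
        freq_b=freq,
        n_obs=np.zeros_like(freq, dtype=int),
    )


def sim_genotypes(
    freqs: PopulationFrequencies,
    pop_sizes,
    missing_rate: float = 0.0,
    seed=0,
) -> GenotypeMatrix:
    """Sample functionally diploid genotypes under Hardy–Weinberg: per
    individual per locus, genotype ~ Binomial(2, freq_b of its population);
    missing calls injected independently at ``missing_rate``."""
    if len(pop_sizes) != len(freqs.pop_labels):
        raise ValueError("pop_sizes must match freqs.pop_labels")
    rng = np.random.default_rng(seed)
    individuals: list[str] = []
    populations: list[str] = []
    blocks: list[np.ndarray] = []
    for label, size in zip(freqs.pop_labels, pop_sizes):
        k = freqs.pop_index(label)
        p = freqs.freq_b[k]
        if np.isnan(p).any():
            raise ValueError(f"population {label} has undefined frequencies")
        calls = rng.binomial(2, p, size=(size, len(freqs.loci)))
        blocks.append(calls)
        individuals.extend(f"{label}_{i+1:02d}" for i in range(size))
        populations.extend([label] * size)
    calls = np.vstack(blocks).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = MISSING
    return GenotypeMatrix(individuals, populations, freqs.loci, calls)


def sim_study_dataset(seed: int = 0, missing_rate: float = 0.0,
                      config: PopSimConfig | None = None) -> GenotypeMatrix:
    """Convenience: a full synthetic analogue of the study's genotype panel —
    five sturgeon populations of sizes 14/14/5/28/5 at 123 biallelic loci,
    with default per-population divergence ``STUDY_DIVERGENCE``."""
    if config is None:
        config = PopSimConfig(seed=seed, missing_rate=missing_rate)
    else:
        config.seed = seed
    freqs = sim_population_frequencies(config)
    return sim_genotypes(
        freqs, config.pop_sizes, missing_rate=config.missing_rate,
        seed=config.seed + 1,
    )
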
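"""Shared fixtures and scenario builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from octopop import GenotypeMatrix, drift_frequencies, sim_genotypes
from octopop.types import MISSING, PopulationFrequencies

settings.register_profile(
    "ci",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_matrix(calls, populations, loci=None, individuals=None) -> GenotypeMatrix:
    """Small-matrix builder: calls as nested lists, 'NA'/-1 for missing."""
    calls = np.array(
        [[MISSING if c in ("NA", None, MISSING) else c for c in row] for row in calls],
        dtype=np.int8,
    )
    n, L = calls.shape
    loci = loci or [f"L{j+1}" for j in range(L)]
    individuals = individuals or [f"ind{i+1}" for i in range(n)]
    return GenotypeMatrix(individuals, list(populations), loci, calls)


def paired_pop_matrix(
    seed: int,
    f_between: float = 0.4,
    f_within: float = 0.02,
    n_per_pop: int = 15,
    n_loci: int = 200,
) -> GenotypeMatrix:
    """Four populations as two well-separated pairs (A1, A2) and (B1, B2):
    two lineages drift far apart (f_between), then each splits into two
    barely-diverged populations (f_within). The true tree pairs A1 with A2
    and B1 with B2."""
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.2, 0.8, size=n_loci)
    lineages = [drift_frequencies(p0, f_between, rng) for _ in range(2)]
    labels, freq_rows = [], []
    for lin_name, lin_freq in zip("AB", lineages):
        for rep in (1, 2):
            labels.append(f"{lin_name}{rep}")
            freq_rows.append(drift_frequencies(lin_freq, f_within, rng))
    freqs = PopulationFrequencies(
        pop_labels=labels,
        loci=[f"L{j+1}" for j in range(n_loci)],
        freq_b=np.vstack(freq_rows),
        n_obs=np.zeros((4, n_loci), dtype=int),
    )
    return sim_genotypes(freqs, [n_per_pop] * 4, seed=seed + 1)


def planted_matrix(
    seed: int,
    n_informative: int = 10,
    n_null: int = 113,
    f_informative: float = 0.5,
    f_null: float = 0.002,
    pop_sizes=(20, 20, 20),
):
    """Genotype matrix with a handful of strongly divergent loci planted in
    a background of essentially undifferentiated loci. Returns the matrix
    and the set of informative locus ids (named INF*)."""
    rng = np.random.default_rng(seed)
    n_pops = len(pop_sizes)
    n_loci = n_informative + n_null
    p0 = rng.uniform(0.3, 0.7, size=n_loci)
    freq = np.vstack([
        np.concatenate([
            drift_frequencies(p0[:n_informative], f_informative, rng),
            drift_frequencies(p0[n_informative:], f_null, rng),
        ])
        for _ in range(n_pops)
    ])
    loci = [f"INF{j+1:02d}" for j in range(n_informative)] + [
        f"NULL{j+1:03d}" for j in range(n_null)
    ]
    freqs = PopulationFrequencies(
        pop_labels=[f"pop{k+1}" for k in range(n_pops)],
        loci=loci,
        freq_b=freq,
        n_obs=np.zeros((n_pops, n_loci), dtype=int),
    )
    matrix = sim_genotypes(freqs, pop_sizes, seed=seed + 1)
    return matrix, {l for l in loci if l.startswith("INF")}


@pytest.fixture
def toy_matrix() -> GenotypeMatrix:
    """Two populations x two individuals, four loci of which only one is
    informative (locus1 all-het, locus2 all-ref, locus4 all-alt)."""
    return make_matrix(
        calls=[
            [1, 0, 0, 2],
            [1, 0, 1, 2],
            [1, 0, 2, 2],
            [1, 0, 2, 2],
        ],
        populations=["p1", "p1", "p2", "p2"],
        loci=["locus1", "locus2", "locus3", "locus4"],
    )
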
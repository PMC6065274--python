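"""Synthetic genotype and morphometric data with known truth.

Genotypes follow the F-model (correlated allele frequencies): each locus
has an ancestral allele frequency p_A drawn uniformly from a configurable
range, and each population k drifts from it with parameter F_k, its
frequency drawn from Beta(p_A(1-F_k)/F_k, (1-p_A)(1-F_k)/F_k) — so the
expected differentiation between two symmetric populations is approximately
F.  Individuals are either unadmixed members of their home population
(alpha = 0) or carry Dirichlet(alpha) ancestry proportions over the
population frequency pools; each diploid genotype is two independent
allele draws with success probability sum_k q_ik p_kl.  Missing genotypes
are masked independently per cell.

Morphometric tables are multivariate normal length traits (equicorrelation
rho across the five traits, population-specific means and SDs), truncated
at zero by redrawing, which preserves means at realistic coefficients of
variation.  A high rho regime reproduces the one-dominant-PC structure
typical of strongly size-correlated measurements.

The study-shaped fixture bundles both: 33 individuals (16 "west", 17
"east") at 77 biallelic loci, the east unadmixed and the west an admixed
mixture of the two ancestral clusters, plus a matching morphometric table
with a longer western snout, a larger eastern fore limb and inflated
western variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometrics import TRAITS, validate_morph_table
from .types import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class GenotypeSimParams:
    n_per_pop: tuple[int, ...] = (16, 17)
    n_loci: int = 77
    F_k: tuple[float, ...] = (0.3, 0.3)
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    alpha: float = 0.0
    missing_rate: float = 0.0
    seed: int | None = None
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.F_k) != len(self.n_per_pop):
            raise ValueError("F_k must have one entry per population")
        if any(n <= 0 for n in self.n_per_pop) or self.n_loci <= 0:
            raise ValueError("counts must be positive")
        if any(not 0 <= f < 1 for f in self.F_k):
            raise ValueError("F_k must lie in [0, 1) (0 = panmixia limit)")
        lo, hi = self.ancestral_freq_range
        if not 0 < lo <= hi < 1:
            raise ValueError("ancestral_freq_range must be inside (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not self.labels:
            self.labels = tuple(f"pop_{i + 1}" for i in range(len(self.n_per_pop)))


@dataclass
class SimTruth:
    ancestral_freqs: np.ndarray      # (L,)
    population_freqs: np.ndarray     # (K, L)
    Q_true: np.ndarray               # (n, K)
    expected_fst: float
    seed: int | None = None


def _draw_pop_freqs(
    rng: np.random.Generator, p_anc: np.ndarray, F: float
) -> np.ndarray:
    if F == 0.0:
        return p_anc.copy()
    ratio = (1.0 - F) / F
    a, b = p_anc * ratio, (1.0 - p_anc) * ratio
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("degenerate Beta parameters in F-model draw")
    return rng.beta(a, b)


def generate_genotypes(
    params: GenotypeSimParams,
) -> tuple[GenotypeMatrix, PopulationMap, SimTruth]:
    """Simulate a biallelic genotype matrix under the F-model."""
    rng = np.random.default_rng(params.seed)
    K = len(params.n_per_pop)
    L = params.n_loci
    lo, hi = params.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, L)
    p_pop = np.stack([_draw_pop_freqs(rng, p_anc, f) for f in params.F_k])

    n_total = sum(params.n_per_pop)
    Q = np.zeros((n_total, K))
    ids: list[str] = []
    assignments: dict[str, str] = {}
    row = 0
    for k, (n_k, lab) in enumerate(zip(params.n_per_pop, params.labels)):
        for i in range(n_k):
            ind = f"{lab}_{i + 1:02d}"
            ids.append(ind)
            assignments[ind] = lab
            if params.alpha == 0.0:
                Q[row, k] = 1.0
            else:
                Q[row] = rng.dirichlet(np.full(K, params.alpha))
            row += 1

    r = Q @ p_pop  # (n, L) per-copy allele-1 probability
    calls = (rng.random((n_total, L, 2)) < r[:, :, None]).astype(np.int32)
    if params.missing_rate > 0:
        miss = rng.random((n_total, L)) < params.missing_rate
        calls[miss] = MISSING

    locus_ids = [f"{j + 1}_1" for j in range(L)]  # '<radlocus>_<column>' convention
    positions = {lid: ("1", j + 1) for j, lid in enumerate(locus_ids)}
    matrix = GenotypeMatrix(ids, locus_ids, calls, positions).recode_dense()
    truth = SimTruth(p_anc, p_pop, Q, float(np.mean(params.F_k)), params.seed)
    return matrix, PopulationMap(assignments), truth


def generate_morphs(
    n_per_pop: tuple[int, ...],
    trait_means: dict[str, np.ndarray | list[float]],
    trait_sds: dict[str, np.ndarray | list[float]],
    correlation: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a morphometric table (five traits, truncated-normal).

    ``trait_means``/``trait_sds`` map population label -> length-5 vector.
    ``correlation`` is the common inter-trait correlation; it must keep the
    5x5 equicorrelation matrix positive definite (rho in (-1/4, 1)).
    """
    if not -0.25 < correlation < 1:
        raise ValueError("correlation must be in (-1/4, 1) for positive definiteness")
    if set(trait_means) != set(trait_sds) or len(trait_means) != len(n_per_pop):
        raise ValueError("trait_means and trait_sds must cover the same populations")
    rng = np.random.default_rng(seed)
    R = np.full((5, 5), correlation)
    np.fill_diagonal(R, 1.0)
    rows = []
    for lab, n_k in zip(trait_means, n_per_pop):
        mu = np.asarray(trait_means[lab], dtype=float)
        sd = np.asarray(trait_sds[lab], dtype=float)
        if mu.shape != (5,) or sd.shape != (5,) or (sd <= 0).any():
            raise ValueError("means and sds must be positive length-5 vectors")
        cov = R * np.outer(sd, sd)
        for i in range(n_k):
            for _ in range(1000):  # redraw to truncate at zero
                x = rng.multivariate_normal(mu, cov, method="cholesky")
                if (x > 0).all():
                    break
            else:
                raise ValueError("truncation rejection failed; means too close to zero")
            rows.append(
                {"individual_id": f"{lab}_{i + 1:02d}", "population": lab,
                 **dict(zip(TRAITS, x))}
            )
    return validate_morph_table(pd.DataFrame(rows))


@dataclass
class StudyFixture:
    matrix: GenotypeMatrix
    popmap: PopulationMap
    genotype_truth: SimTruth
    morphs: pd.DataFrame
    morph_params: dict = field(default_factory=dict)


# Study-shaped defaults: small-mongoose carcass lengths in cm.  Snout is
# longer in the west, fore limb larger in the east; western SDs inflated so
# the western PC1 range is wider; rho near 1 yields one dominant PC.
_MORPH_MEANS = {
    "west": np.array([55.0, 3.6, 20.0, 9.5, 12.0]),
    "east": np.array([55.0, 3.2, 21.0, 10.3, 12.2]),
}
_MORPH_SDS = {
    "west": np.array([5.4, 0.36, 2.0, 0.95, 1.2]),
    "east": np.array([3.0, 0.20, 1.1, 0.53, 0.66]),
}
_MORPH_RHO = 0.99


def make_study_shaped_fixture(seed: int | None = 0) -> StudyFixture:
    """A 33-individual, 77-locus bundle shaped like a two-population
    riverine study: 16 admixed "west" individuals, 17 unadmixed "east"
    individuals, plus the matching morphometric table."""
    rng = np.random.default_rng(seed)
    L = 77
    p_anc = rng.uniform(0.1, 0.9, L)
    F = (0.3, 0.3)
    p_pop = np.stack([_draw_pop_freqs(rng, p_anc, f) for f in F])

    n_west, n_east = 16, 17
    ids = [f"west_{i + 1:02d}" for i in range(n_west)] + [
        f"east_{i + 1:02d}" for i in range(n_east)
    ]
    assignments = {i: i.split("_")[0] for i in ids}
    Q = np.zeros((n_west + n_east, 2))
    Q[:n_west] = rng.dirichlet([1.0, 1.0], size=n_west)  # admixed west
    Q[n_west:, 1] = 1.0                                   # unadmixed east

    r = Q @ p_pop
    calls = (rng.random((len(ids), L, 2)) < r[:, :, None]).astype(np.int32)
    miss = rng.random((len(ids), L)) < 0.10
    calls[miss] = MISSING
    locus_ids = [f"{j + 1}_1" for j in range(L)]
    positions = {lid: ("1", j + 1) for j, lid in enumerate(locus_ids)}
    matrix = GenotypeMatrix(ids, locus_ids, calls, positions).recode_dense()
    truth = SimTruth(p_anc, p_pop, Q, float(np.mean(F)), seed)

    morph_seed = int(rng.integers(2**31 - 1))
    morphs = generate_morphs(
        (n_west, n_east), _MORPH_MEANS, _MORPH_SDS, _MORPH_RHO, seed=morph_seed
    )
    return StudyFixture(
        matrix, PopulationMap(assignments), truth, morphs,
        {"means": _MORPH_MEANS, "sds": _MORPH_SDS, "rho": _MORPH_RHO,
         "seed": morph_seed},
    )
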
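"""Per-locus, per-population diversity statistics.

For each locus within a population we compute allele frequencies over the
genotyped individuals, observed heterozygosity Ho (fraction of heterozygous
genotypes), expected heterozygosity under Hardy-Weinberg He = 1 - sum(p_i^2)
(optionally with the unbiased 2n/(2n-1) small-sample factor), their
homozygosity complements, and the inbreeding coefficient
FIS = 1 - Ho/He (undefined at monomorphic loci where He = 0).

Population summaries are locus means and sample standard deviations, and
two populations are compared metric-by-metric with a two-sample t test
(Welch by default) on the per-locus values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import GenotypeMatrix, PopulationMap

METRICS = ("HomO", "HomE", "Ho", "He", "FIS")


@dataclass
class LocusDiversity:
    locus_id: str
    population: str
    n_genotyped: int
    allele_freqs: np.ndarray
    Ho: float
    He: float
    FIS: float | None  # None where He == 0

    @property
    def HomO(self) -> float:
        return 1.0 - self.Ho

    @property
    def HomE(self) -> float:
        return 1.0 - self.He


@dataclass
class DiversitySummary:
    population: str
    mean: dict[str, float | None]
    sd: dict[str, float | None]
    n_loci: dict[str, int]
    per_locus: dict[str, np.ndarray]  # metric -> vector over loci where defined


@dataclass
class MetricComparison:
    metric: str
    mean_a: float
    mean_b: float
    t: float
    df: float
    p_value: float


def allele_frequencies(
    matrix: GenotypeMatrix, popmap: PopulationMap, population: str
) -> list[np.ndarray | None]:
    """Allele frequency vector per locus for one population.

    Frequencies are taken over non-missing calls only.  A locus with no
    genotyped individual in the population yields ``None``.
    """
    labels = popmap.labels_for(matrix)
    rows = np.flatnonzero(labels == population)
    if rows.size == 0:
        raise ValueError(f"population {population!r} is empty or unknown")
    k_all = matrix.n_alleles()
    out: list[np.ndarray | None] = []
    for j in range(matrix.n_loci):
        obs = matrix.calls[rows, j, :]
        obs = obs[obs >= 0]
        if obs.size == 0:
            out.append(None)
            continue
        k = max(int(k_all[j]), int(obs.max()) + 1)
        out.append(np.bincount(obs, minlength=k) / obs.size)
    return out


def locus_diversity(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    population: str,
    unbiased_he: bool = False,
) -> list[LocusDiversity]:
    """Ho, He and FIS per locus for one population.

    ``unbiased_he`` applies Nei's 2n/(2n-1) small-sample correction to He;
    the default is the uncorrected 1 - sum(p^2).
    """
    labels = popmap.labels_for(matrix)
    rows = np.flatnonzero(labels == population)
    if rows.size == 0:
        raise ValueError(f"population {population!r} is empty or unknown")
    freqs = allele_frequencies(matrix, popmap, population)
    out: list[LocusDiversity] = []
    for j, lid in enumerate(matrix.locus_ids):
        calls = matrix.calls[rows, j, :]
        genotyped = calls[:, 0] >= 0
        n = int(genotyped.sum())
        p = freqs[j]
        if n == 0 or p is None:
            out.append(LocusDiversity(lid, population, 0, np.array([]), np.nan, np.nan, None))
            continue
        het = calls[genotyped, 0] != calls[genotyped, 1]
        ho = float(het.mean())
        he = float(1.0 - np.sum(p**2))
        if unbiased_he:
            he *= (2 * n) / (2 * n - 1) if n > 0 else 1.0
        fis = None if he == 0 else float(1.0 - ho / he)
        out.append(LocusDiversity(lid, population, n, p, ho, he, fis))
    return out


def summarize_population(loci: list[LocusDiversity]) -> DiversitySummary:
    """Locus means and sample SDs (n-1) per metric; FIS is averaged over
    the loci where it is defined."""
    usable = [d for d in loci if d.n_genotyped > 0]
    if not usable:
        raise ValueError("no genotyped loci to summarize")
    vectors = {
        "Ho": np.array([d.Ho for d in usable]),
        "He": np.array([d.He for d in usable]),
        "HomO": np.array([d.HomO for d in usable]),
        "HomE": np.array([d.HomE for d in usable]),
        "FIS": np.array([d.FIS for d in usable if d.FIS is not None], dtype=float),
    }
    mean: dict[str, float | None] = {}
    sd: dict[str, float | None] = {}
    n_loci: dict[str, int] = {}
    for m, v in vectors.items():
        n_loci[m] = v.size
        if v.size == 0:
            mean[m], sd[m] = None, None
        else:
            mean[m] = float(v.mean())
            sd[m] = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return DiversitySummary(usable[0].population, mean, sd, n_loci, vectors)


def compare_populations(
    a: DiversitySummary, b: DiversitySummary, welch: bool = True
) -> list[MetricComparison]:
    """Two-sample t test per metric on the per-locus values of two
    populations; two-sided p.  Welch (unequal variance) by default."""
    out: list[MetricComparison] = []
    for m in METRICS:
        va, vb = a.per_locus[m], b.per_locus[m]
        if va.size < 2 or vb.size < 2:
            raise ValueError(f"metric {m}: need >= 2 loci per population")
        res = stats.ttest_ind(va, vb, equal_var=not welch)
        if welch:
            sa2, sb2 = va.var(ddof=1), vb.var(ddof=1)
            na, nb = va.size, vb.size
            num = (sa2 / na + sb2 / nb) ** 2
            den = (sa2 / na) ** 2 / (na - 1) + (sb2 / nb) ** 2 / (nb - 1)
            df = float(num / den) if den > 0 else float(na + nb - 2)
        else:
            df = float(va.size + vb.size - 2)
        out.append(
            MetricComparison(m, float(va.mean()), float(vb.mean()),
                             float(res.statistic), df, float(res.pvalue))
        )
    return out
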
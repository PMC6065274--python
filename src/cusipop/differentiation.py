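"""Weir-Cockerham FST and a label-permutation test of differentiation.

The estimator is Weir & Cockerham's (1984) theta for diploid data, built
from three per-locus variance components: ``a`` (among populations), ``b``
(among individuals within populations) and ``c`` (within individuals).  The
multilocus estimate is the ratio of sums, theta = sum(a) / sum(a + b + c),
over the loci where the components are defined (>= 2 populations genotyped
and mean sample size above 1).  Per-locus and multilocus estimates may be
negative in finite samples and are reported as-is.

The permutation test holds genotypes fixed, reshuffles population labels
while preserving the observed group sizes, and recomputes the multilocus
theta each iteration.  The p-value uses the add-one convention
``(1 + #{null >= observed}) / (1 + n_perm)`` with ties counted as extreme.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .types import GenotypeMatrix, PopulationMap


@dataclass
class FstEstimate:
    theta: float
    a: np.ndarray  # per-locus among-population component (nan where unusable)
    b: np.ndarray
    c: np.ndarray
    locus_ids: list[str]
    n_loci_used: int

    def per_locus_theta(self) -> np.ndarray:
        """a/(a+b+c) per locus; nan where undefined or denominator zero."""
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            t = self.a / denom
        t[denom == 0] = np.nan
        return t


@dataclass
class FstPermutationResult:
    observed_theta: float
    null_thetas: np.ndarray
    p_value: float
    cutoff_95: float
    group_sizes: tuple[int, ...]
    seed: int | None
    exhaustive: bool = False


def wc_components_locus(
    genotype_counts_by_population: dict[str, tuple[int, int, int]],
) -> tuple[float, float, float]:
    """Variance components (a, b, c) for one biallelic locus.

    Input: per population, counts ``(n0, n1, n2)`` of genotypes carrying
    0, 1 and 2 copies of the alternate allele.  Populations with zero
    genotyped individuals are ignored; fewer than two genotyped
    populations, or an average sample size of one, raises ``ValueError``.
    """
    n_list, p_list, h_list = [], [], []
    for counts in genotype_counts_by_population.values():
        n0, n1, n2 = counts
        n = n0 + n1 + n2
        if n == 0:
            continue
        n_list.append(n)
        p_list.append((n1 + 2 * n2) / (2 * n))
        h_list.append(n1 / n)
    if len(n_list) < 2:
        raise ValueError("locus genotyped in fewer than 2 populations")
    n = np.array(n_list, dtype=float)[:, None]
    p = np.array(p_list, dtype=float)[:, None]
    h = np.array(h_list, dtype=float)[:, None]
    a, b, c, usable = _wc_components(n, p, h)
    if not usable[0]:
        raise ValueError("mean sample size must exceed 1")
    return float(a[0]), float(b[0]), float(c[0])


def _wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized components over loci.

    ``n``, ``p``, ``h``: (r, L) per-population sample sizes, allele
    frequencies, observed heterozygote frequencies.  Entries with n == 0
    are excluded from that locus.  Returns (a, b, c, usable), each (L,).
    """
    present = n > 0
    r = present.sum(axis=0).astype(float)  # populations genotyped per locus
    n = np.where(present, n, 0.0)
    sum_n = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = sum_n / r
        usable = (r >= 2) & (nbar > 1)
        nc = (sum_n - (n**2).sum(axis=0) / sum_n) / (r - 1)
        pbar = (n * p).sum(axis=0) / sum_n
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / sum_n
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    bad = ~usable
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c, usable


def _pop_arrays(
    dosage: np.ndarray, labels: np.ndarray, pops: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-population (n, p, h) arrays of shape (r, L) from a dosage matrix."""
    present = ~np.isnan(dosage)
    d0 = np.nan_to_num(dosage)
    het = (dosage == 1.0) & present
    ind = np.stack([(labels == pop) for pop in pops]).astype(float)  # (r, n_ind)
    n = ind @ present  # genotyped counts (r, L)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (ind @ d0) / (2 * n)
        h = (ind @ het.astype(float)) / n
    return n, p, h


def wc_theta(matrix: GenotypeMatrix, popmap: PopulationMap) -> FstEstimate:
    """Multilocus Weir-Cockerham theta (ratio of component sums)."""
    labels = popmap.labels_for(matrix)
    pops = popmap.populations()
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    dosage = matrix.dosage()
    n, p, h = _pop_arrays(dosage, labels, pops)
    a, b, c, usable = _wc_components(n, p, h)
    used = usable & ~np.isnan(a) & ((a + b + c) != 0)
    if not used.any() or np.nansum((a + b + c)[used]) == 0:
        raise ValueError("no usable loci for theta")
    theta = float(np.nansum(a[used]) / np.nansum((a + b + c)[used]))
    return FstEstimate(theta, a, b, c, list(matrix.locus_ids), int(used.sum()))


def _theta_fast(
    present: np.ndarray, d0: np.ndarray, het: np.ndarray, ind: np.ndarray
) -> float:
    """Multilocus theta given precomputed per-individual arrays.

    ``ind`` is the (2, n_ind) group-indicator matrix; nan is returned when
    no locus is usable (cannot happen with variant loci and 2 full groups).
    """
    n = ind @ present
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (ind @ d0) / (2 * n)
        h = (ind @ het) / n
    a, b, c, usable = _wc_components(n, p, h)
    tot = a + b + c
    used = usable & ~np.isnan(a) & (tot != 0)
    if not used.any():
        return float("nan")
    return float(a[used].sum() / tot[used].sum())


def fst_permutation_test(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> FstPermutationResult:
    """Permutation null for two-population differentiation.

    Each iteration randomly reassigns individuals to two groups of the
    observed sizes and recomputes multilocus theta.  With ``exhaustive``
    every distinct split is enumerated instead (small cohorts only) and the
    p-value is the exact proportion of splits with theta >= observed.
    """
    labels = popmap.labels_for(matrix)
    pops = popmap.populations()
    if len(pops) != 2:
        raise ValueError("permutation test requires exactly 2 populations "
                         "(run pairwise subsets for more)")
    dosage = matrix.dosage()
    if np.all(np.nanstd(dosage, axis=0) == 0):
        raise ValueError("no variant loci: permutation null is degenerate")
    present = (~np.isnan(dosage)).astype(float)
    d0 = np.nan_to_num(dosage)
    het = ((dosage == 1.0) & (present > 0)).astype(float)

    z = (labels == pops[1]).astype(int)
    n_ind = len(z)
    sizes = (int((z == 0).sum()), int((z == 1).sum()))

    def theta_for(zvec: np.ndarray) -> float:
        ind = np.stack([zvec == 0, zvec == 1]).astype(float)
        return _theta_fast(present, d0, het, ind)

    observed = theta_for(z)

    if exhaustive:
        null = np.array(
            [theta_for(np.isin(np.arange(n_ind), grp).astype(int))
             for grp in combinations(range(n_ind), sizes[1])]
        )
        p = float((null >= observed - 1e-12).mean())
        cutoff = float(np.quantile(null, 0.95))
        return FstPermutationResult(observed, null, p, cutoff, sizes, seed, True)

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    zp = z.copy()
    for it in range(n_perm):
        rng.shuffle(zp)
        null[it] = theta_for(zp)
    p = float((1 + np.sum(null >= observed)) / (1 + n_perm))
    cutoff = float(np.quantile(null, 0.95))
    return FstPermutationResult(observed, null, p, cutoff, sizes, seed, False)
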
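"""Independent oracles used by the test suite.

These are deliberately naive, scalar, loop-based implementations kept
separate from the package so the production code is checked against a
second, independently written route.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def wc_components_oracle(counts_by_pop):
    """Literal scalar transcription of the Weir & Cockerham (1984)
    variance-component formulas for one biallelic locus.

    ``counts_by_pop``: iterable of (n0, n1, n2) genotype counts (copies of
    the alternate allele).  Returns (a, b, c).
    """
    ns, ps, hs = [], [], []
    for n0, n1, n2 in counts_by_pop:
        n = n0 + n1 + n2
        if n == 0:
            continue
        ns.append(n)
        ps.append((n1 + 2 * n2) / (2 * n))
        hs.append(n1 / n)
    r = len(ns)
    if r < 2:
        raise ValueError("need >= 2 genotyped populations")
    nbar = sum(ns) / r
    if nbar <= 1:
        raise ValueError("mean sample size must exceed 1")
    nc = (r * nbar - sum(x * x for x in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def counts_from_matrix(matrix, labels):
    """Per-locus genotype counts (n0, n1, n2) for each population label."""
    d = matrix.dosage()
    out = []
    for j in range(matrix.n_loci):
        per_pop = {}
        for pop in dict.fromkeys(labels):
            col = d[np.asarray(labels) == pop, j]
            col = col[~np.isnan(col)]
            per_pop[pop] = (
                int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
            )
        out.append(per_pop)
    return out


def multilocus_theta_oracle(matrix, labels):
    """Ratio-of-sums multilocus theta via the scalar locus oracle."""
    num = den = 0.0
    for per_pop in counts_from_matrix(matrix, labels):
        try:
            a, b, c = wc_components_oracle(per_pop.values())
        except ValueError:
            continue
        if a + b + c == 0:
            continue
        num += a
        den += a + b + c
    return num / den


def exhaustive_permutation_p(matrix, labels, group1_size):
    """Exact permutation p-value by enumerating every split of the cohort
    into groups of the observed sizes."""
    labels = np.asarray(labels)
    n = matrix.n_individuals
    obs = multilocus_theta_oracle(matrix, labels)
    pops = list(dict.fromkeys(labels))
    thetas = []
    for grp in combinations(range(n), group1_size):
        lab = np.where(np.isin(np.arange(n), grp), pops[0], pops[1])
        thetas.append(multilocus_theta_oracle(matrix, lab))
    thetas = np.array(thetas)
    return float((thetas >= obs - 1e-12).mean()), thetas


def evanno_delta_k_oracle(lnp_by_k: dict[int, list[float]]):
    """Hand evaluation of the ΔK formula; returns {K: delta_K}."""
    ks = sorted(lnp_by_k)
    mean = {k: float(np.mean(lnp_by_k[k])) for k in ks}
    sd = {k: float(np.std(lnp_by_k[k], ddof=1)) for k in ks}
    out = {}
    for k in ks[1:-1]:
        lpp = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
        out[k] = lpp / sd[k] if sd[k] > 0 else np.nan
    return out
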
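"""Bayesian admixture clustering of diploid SNP genotypes.

The model is the classic admixture mixture model: each of K clusters has
its own allele frequencies P, each individual i has ancestry proportions
Q_i on the K-simplex (Dirichlet(alpha) prior, alpha shared and learned),
and every allele copy is drawn by first choosing a cluster of origin Z
from Q_i and then an allele from that cluster's frequencies.  With the
correlated-frequencies option the cluster frequencies share an ancestral
frequency p_A per locus from which each cluster drifts by its own amount
F_k: P_kl ~ Beta(p_A(1-F_k)/F_k, (1-p_A)(1-F_k)/F_k).

Inference is Gibbs sampling over Z, P and Q, with Metropolis updates for
alpha (log-scale Gaussian proposal), the drift parameters F_k and the
ancestral frequencies.  The per-sweep log-likelihood ln P(X|P,Q) is traced
and the model evidence for a given K is estimated by the usual
mean-minus-half-variance summary of that trace, which is what the
Evanno-style ΔK selection consumes.

Only biallelic loci are supported; missing genotypes contribute nothing to
the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln

from .types import GenotypeMatrix

_EPS = 1e-9
_PCLIP = 1e-6


@dataclass
class AdmixtureModelConfig:
    """Sampler settings.

    ``burn_in``/``reps`` default to the full-study profile (5,000 / 50,000
    sweeps); analyses at desk scale typically pass the reduced profile
    (500 / 2,000).  ``seed`` may be an int or a tuple of ints (the latter
    is how replicate scans derive independent streams deterministically).
    """

    K: int = 2
    burn_in: int = 5000
    reps: int = 50000
    alpha_init: float = 1.0
    alpha_proposal_sd: float = 0.1
    alpha_max: float = 10.0
    lambda_: float = 1.0
    correlated_frequencies: bool = True
    f_init: float = 0.1
    f_proposal_sd: float = 0.05
    anc_proposal_sd: float = 0.05
    seed: int | tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.burn_in < 0 or self.reps < 1:
            raise ValueError("burn_in >= 0 and reps >= 1 required")
        if self.alpha_init <= 0:
            raise ValueError("alpha_init must be > 0")


@dataclass
class AdmixtureRun:
    Q: np.ndarray          # (n, K) posterior-mean ancestry
    P_hat: np.ndarray      # (K, L) posterior-mean allele-1 frequencies
    lnL_trace: np.ndarray  # (reps,) post-burn-in log-likelihood
    lnP_K: float           # evidence estimate mean - var/2
    config: AdmixtureModelConfig
    alpha_mean: float = float("nan")
    F_mean: np.ndarray = field(default_factory=lambda: np.array([]))


def _categorical(rng: np.random.Generator, prob: np.ndarray) -> np.ndarray:
    """Row-wise categorical draw; ``prob`` is (..., K), normalized."""
    cum = np.cumsum(prob, axis=-1)
    u = rng.random(prob.shape[:-1] + (1,)) * cum[..., -1:]
    return (u > cum).sum(axis=-1)


def _dirichlet_rows(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    g = rng.gamma(np.maximum(alpha, _EPS))
    g = np.maximum(g, 1e-300)
    return g / g.sum(axis=-1, keepdims=True)


def fit_admixture(matrix: GenotypeMatrix, config: AdmixtureModelConfig) -> AdmixtureRun:
    """Run the Gibbs sampler and return posterior-mean summaries."""
    if config.K > matrix.n_individuals:
        raise ValueError("K exceeds the number of individuals")
    g = matrix.dosage()  # (n, L) 0/1/2 with nan
    mask = ~np.isnan(g)
    if not mask.any():
        raise ValueError("all genotypes missing")
    n, L = g.shape
    K = config.K
    rng = np.random.default_rng(config.seed)

    c1 = np.where(mask, np.nan_to_num(g), 0.0)        # allele-1 copies per cell
    c0 = np.where(mask, 2.0 - np.nan_to_num(g), 0.0)  # allele-0 copies per cell
    # log-binomial coefficient of heterozygotes: constant across sweeps
    const = np.log(2.0) * float(((g == 1.0) & mask).sum())

    # allele values of the two copies of each genotype (assignment of the
    # single '1' copy of a heterozygote to copy A is arbitrary/exchangeable)
    val_a = (c1 >= 1)
    val_b = (c1 >= 2)
    copy_w = mask.astype(float)          # copy exists (per copy, same mask)
    w1_a = (val_a & mask).astype(float)  # copy A carries allele 1
    w0_a = (~val_a & mask).astype(float)
    w1_b = (val_b & mask).astype(float)
    w0_b = (~val_b & mask).astype(float)
    l_flat = np.broadcast_to(np.arange(L), (n, L)).ravel()
    i_flat = np.repeat(np.arange(n), L)

    P = np.clip(rng.random((K, L)), 0.25, 0.75)
    Q = np.full((n, K), 1.0 / K)
    alpha = config.alpha_init
    F = np.full(K, config.f_init)
    # ancestral frequencies initialized at the pooled sample frequency
    with np.errstate(invalid="ignore"):
        p_anc = np.nanmean(g, axis=0) / 2.0
    p_anc = np.clip(np.nan_to_num(p_anc, nan=0.5), 0.01, 0.99)

    sum_Q = np.zeros_like(Q)
    sum_P = np.zeros_like(P)
    sum_alpha = 0.0
    sum_F = np.zeros(K)
    trace = np.empty(config.reps)

    def beta_prior() -> tuple[np.ndarray, np.ndarray]:
        if config.correlated_frequencies:
            ratio = (1.0 - F[:, None]) / F[:, None]
            return p_anc[None, :] * ratio, (1.0 - p_anc[None, :]) * ratio
        lam = config.lambda_
        return np.full((K, L), lam), np.full((K, L), lam)

    total = config.burn_in + config.reps
    for sweep in range(total):
        # ----- Z: cluster of origin for every allele copy ---------------
        if K == 1:
            n1 = c1.sum(axis=0)[None, :]
            n0 = c0.sum(axis=0)[None, :]
            m = (c1 + c0).sum(axis=1)[:, None]
        else:
            Pt = P.T[None, :, :]  # (1, L, K)
            prob_a = Q[:, None, :] * np.where(val_a[:, :, None], Pt, 1.0 - Pt)
            prob_b = Q[:, None, :] * np.where(val_b[:, :, None], Pt, 1.0 - Pt)
            z_a = _categorical(rng, prob_a)
            z_b = _categorical(rng, prob_b)
            fa = (z_a.ravel() * L + l_flat)
            fb = (z_b.ravel() * L + l_flat)
            n1 = (
                np.bincount(fa, weights=w1_a.ravel(), minlength=K * L)
                + np.bincount(fb, weights=w1_b.ravel(), minlength=K * L)
            ).reshape(K, L)
            n0 = (
                np.bincount(fa, weights=w0_a.ravel(), minlength=K * L)
                + np.bincount(fb, weights=w0_b.ravel(), minlength=K * L)
            ).reshape(K, L)
            ma = i_flat * K + z_a.ravel()
            mb = i_flat * K + z_b.ravel()
            m = (
                np.bincount(ma, weights=copy_w.ravel(), minlength=n * K)
                + np.bincount(mb, weights=copy_w.ravel(), minlength=n * K)
            ).reshape(n, K)

        # ----- P | Z ----------------------------------------------------
        pa, pb = beta_prior()
        P = rng.beta(pa + n1, pb + n0)
        P = np.clip(P, _PCLIP, 1.0 - _PCLIP)

        # ----- Q | Z ----------------------------------------------------
        if K == 1:
            Q = np.ones((n, 1))
        else:
            Q = _dirichlet_rows(rng, alpha + m)
            Q = np.clip(Q, _EPS, None)
            Q /= Q.sum(axis=1, keepdims=True)

            # ----- alpha: Metropolis on log scale -----------------------
            prop = alpha * np.exp(rng.normal(0.0, config.alpha_proposal_sd))
            if 0 < prop < config.alpha_max:
                logq = np.log(Q).sum()

                def dir_ll(a: float) -> float:
                    return n * (gammaln(K * a) - K * gammaln(a)) + (a - 1.0) * logq

                log_r = dir_ll(prop) - dir_ll(alpha) + np.log(prop) - np.log(alpha)
                if np.log(rng.random()) < log_r:
                    alpha = prop

        # ----- F-model hyperparameters ---------------------------------
        if config.correlated_frequencies:
            logP = np.log(P)
            log1mP = np.log1p(-P)

            def f_ll(fvec: np.ndarray) -> np.ndarray:
                ratio = (1.0 - fvec[:, None]) / fvec[:, None]
                a = p_anc[None, :] * ratio
                b = (1.0 - p_anc[None, :]) * ratio
                return ((a - 1) * logP + (b - 1) * log1mP - betaln(a, b)).sum(axis=1)

            fp = F + rng.normal(0.0, config.f_proposal_sd, K)
            ok = (fp > 0.001) & (fp < 0.999)
            if ok.any():
                cur = f_ll(F)
                cand = f_ll(np.where(ok, fp, F))
                acc = ok & (np.log(rng.random(K)) < cand - cur)
                F = np.where(acc, fp, F)

            ratio = (1.0 - F[:, None]) / F[:, None]
            ap = p_anc + rng.normal(0.0, config.anc_proposal_sd, L)
            okl = (ap > 0.001) & (ap < 0.999)

            def anc_ll(pvec: np.ndarray) -> np.ndarray:
                a = pvec[None, :] * ratio
                b = (1.0 - pvec[None, :]) * ratio
                return ((a - 1) * logP + (b - 1) * log1mP - betaln(a, b)).sum(axis=0)

            cand_p = np.where(okl, ap, p_anc)
            accl = okl & (np.log(rng.random(L)) < anc_ll(cand_p) - anc_ll(p_anc))
            p_anc = np.where(accl, ap, p_anc)

        # ----- trace and accumulation ----------------------------------
        if sweep >= config.burn_in:
            r = Q @ P  # per-copy allele-1 probability (n, L)
            ll = const + float((c1 * np.log(r) + c0 * np.log1p(-r)).sum())
            t = sweep - config.burn_in
            trace[t] = ll
            sum_Q += Q
            sum_P += P
            sum_alpha += alpha
            sum_F += F

    reps = config.reps
    ln_mean = float(trace.mean())
    ln_var = float(trace.var(ddof=1)) if reps > 1 else 0.0
    return AdmixtureRun(
        Q=sum_Q / reps,
        P_hat=sum_P / reps,
        lnL_trace=trace,
        lnP_K=ln_mean - ln_var / 2.0,
        config=config,
        alpha_mean=sum_alpha / reps,
        F_mean=sum_F / reps,
    )


def _column_corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def best_permutation(Q: np.ndarray, Q_ref: np.ndarray) -> tuple[int, ...]:
    """Column permutation of ``Q`` maximizing summed per-column correlation
    with ``Q_ref`` (exhaustive over K! permutations; K <= 6)."""
    K = Q.shape[1]
    if K > 6:
        raise ValueError("exhaustive alignment supported for K <= 6")
    best, best_score = None, -np.inf
    for perm in permutations(range(K)):
        score = sum(_column_corr(Q_ref[:, k], Q[:, perm[k]]) for k in range(K))
        if score > best_score:
            best, best_score = perm, score
    return best  # type: ignore[return-value]


def align_runs(runs: list[AdmixtureRun]) -> list[AdmixtureRun]:
    """Resolve label switching: permute each run's cluster columns to best
    match the first run.  Returns new run objects; the first is unchanged."""
    if not runs:
        return []
    K = runs[0].Q.shape[1]
    n = runs[0].Q.shape[0]
    for r in runs:
        if r.Q.shape != (n, K):
            raise ValueError("runs have mismatched shapes")
    out = [runs[0]]
    for r in runs[1:]:
        perm = list(best_permutation(r.Q, runs[0].Q))
        out.append(
            replace(r, Q=r.Q[:, perm], P_hat=r.P_hat[perm, :],
                    F_mean=r.F_mean[perm] if r.F_mean.size == K else r.F_mean)
        )
    return out


def replicate_runs(
    matrix: GenotypeMatrix,
    k_range: range | list[int],
    n_replicates: int,
    base_seed: int,
    config: AdmixtureModelConfig | None = None,
) -> tuple[pd.DataFrame, dict[tuple[int, int], AdmixtureRun]]:
    """Independent seeded runs for each K; returns the evidence table
    (columns K, replicate, lnP) and the runs keyed by (K, replicate)."""
    ks = sorted(k_range)
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per K for a ΔK standard deviation")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("k_range must be contiguous")
    template = config or AdmixtureModelConfig()
    rows = []
    runs: dict[tuple[int, int], AdmixtureRun] = {}
    for K in ks:
        for rep in range(n_replicates):
            cfg = replace(template, K=K, seed=(int(base_seed), K, rep))
            run = fit_admixture(matrix, cfg)
            runs[(K, rep)] = run
            rows.append({"K": K, "replicate": rep, "lnP": run.lnP_K})
    return pd.DataFrame(rows), runs
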
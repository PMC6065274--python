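"""Evanno-style ΔK selection of the number of clusters.

Given replicate evidence values lnP(K) for a contiguous range of K, ΔK at
an interior K is the absolute second difference of the replicate means,
|L''(K)| = |mean(K+1) - 2·mean(K) + mean(K-1)|, divided by the sample
standard deviation of the replicates at K.  The K with the largest ΔK is
the supported cluster number; ties break toward smaller K (parsimony).
ΔK is undefined at the endpoints and wherever the replicate SD is zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .admixture import AdmixtureModelConfig, replicate_runs
from .types import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class DeltaKTable:
    table: pd.DataFrame  # columns K, mean_lnP, sd_lnP, L_prime, L_double_prime_abs, delta_K
    k_hat: int | None
    delta_k_at_k_hat: float | None


def delta_k(evidence: pd.DataFrame) -> DeltaKTable:
    """Compute the ΔK table from an evidence frame (columns K, lnP).

    Requires at least three consecutive K values with >= 2 replicates each.
    """
    if not {"K", "lnP"}.issubset(evidence.columns):
        raise ValueError("evidence must have columns K and lnP")
    grp = evidence.groupby("K")["lnP"]
    ks = sorted(grp.groups)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K values must be contiguous")
    if len(ks) < 3:
        raise ValueError("need >= 3 consecutive K values for ΔK")
    counts = grp.count()
    if (counts < 2).any():
        raise ValueError("need >= 2 replicates at every K")
    mean = grp.mean().reindex(ks).to_numpy()
    sd = grp.std(ddof=1).reindex(ks).to_numpy()

    lp = np.full(len(ks), np.nan)
    lpp = np.full(len(ks), np.nan)
    dk = np.full(len(ks), np.nan)
    lp[1:] = np.diff(mean)
    for i in range(1, len(ks) - 1):
        lpp[i] = abs(mean[i + 1] - 2 * mean[i] + mean[i - 1])
        if sd[i] == 0:
            logger.warning("sd(lnP) = 0 at K=%d; ΔK undefined there", ks[i])
        else:
            dk[i] = lpp[i] / sd[i]

    table = pd.DataFrame(
        {"K": ks, "mean_lnP": mean, "sd_lnP": sd,
         "L_prime": lp, "L_double_prime_abs": lpp, "delta_K": dk}
    )
    if np.isnan(dk).all():
        return DeltaKTable(table, None, None)
    # ties toward smaller K: nanargmax returns the first maximum
    i_hat = int(np.nanargmax(dk))
    return DeltaKTable(table, int(ks[i_hat]), float(dk[i_hat]))


def detect_k(
    matrix: GenotypeMatrix,
    k_range: range | list[int],
    n_replicates: int,
    base_seed: int,
    config: AdmixtureModelConfig | None = None,
) -> tuple[DeltaKTable, int | None]:
    """Run the replicate admixture scan and apply ΔK selection."""
    ks = sorted(k_range)
    if len(ks) < 3:
        raise ValueError("k_range must span at least 3 values")
    evidence, _ = replicate_runs(matrix, ks, n_replicates, base_seed, config)
    result = delta_k(evidence)
    return result, result.k_hat
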
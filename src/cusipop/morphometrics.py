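"""Morphometric stage: trait comparisons and PCA of length measurements.

Five external length traits per individual (total, snout, tail, fore limb,
hind limb — one consistent unit, cm by convention) are compared between two
populations with Welch's two-sample t test, and summarized jointly by a
principal component analysis of the zero-centered (and, by default,
unit-variance scaled) trait matrix.  Body weight is deliberately not a
column: carcass desiccation makes it incomparable across collection delays.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

TRAITS = (
    "total_length",
    "snout_length",
    "tail_length",
    "fore_limb_length",
    "hind_limb_length",
)
_REQUIRED = ("individual_id", "population") + TRAITS


@dataclass
class TraitComparison:
    trait: str
    means: dict[str, float]
    t: float
    df: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class PcaResult:
    eigenvalues: np.ndarray          # descending
    proportion_variance: np.ndarray
    loadings: np.ndarray             # traits x components, orthonormal columns
    scores: np.ndarray               # individuals x components
    scaled: bool
    trait_names: tuple[str, ...] = TRAITS


def read_morph_table(path: str | Path) -> pd.DataFrame:
    """Load and validate a morphometric CSV/TSV table.

    Requires columns ``individual_id``, ``population`` and the five length
    traits; lengths must be positive and individual ids unique.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    return validate_morph_table(df)


def validate_morph_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {missing}")
    dup = df["individual_id"][df["individual_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate individual id(s): {sorted(set(dup))}")
    bad = df.index[(df[list(TRAITS)] <= 0).any(axis=1) | df[list(TRAITS)].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"non-positive or missing length(s) at row(s): {list(bad)}")
    return df.reset_index(drop=True)


def write_morph_table(df: pd.DataFrame, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=False)


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch t statistic, Welch–Satterthwaite df and two-sided p."""
    res = stats.ttest_ind(x, y, equal_var=False)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    num = (vx / nx + vy / ny) ** 2
    den = (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    df = float(num / den) if den > 0 else float(nx + ny - 2)
    return float(res.statistic), df, float(res.pvalue)


def compare_traits(table: pd.DataFrame, welch: bool = True) -> list[TraitComparison]:
    """Per-trait two-sample t tests between the two populations."""
    table = validate_morph_table(table)
    pops = list(dict.fromkeys(table["population"]))
    if len(pops) != 2:
        raise ValueError(f"expected exactly 2 populations, found {pops}")
    groups = {p: table[table["population"] == p] for p in pops}
    for p, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"population {p!r} has fewer than 2 individuals")
    out = []
    for trait in TRAITS:
        x = groups[pops[0]][trait].to_numpy(float)
        y = groups[pops[1]][trait].to_numpy(float)
        if welch:
            t, df, p = welch_t(x, y)
        else:
            res = stats.ttest_ind(x, y, equal_var=True)
            t, df, p = float(res.statistic), float(len(x) + len(y) - 2), float(res.pvalue)
        out.append(TraitComparison(trait, {pops[0]: float(x.mean()), pops[1]: float(y.mean())}, t, df, p))
    return out


def pca_traits(table: pd.DataFrame, scale: bool = True) -> PcaResult:
    """PCA of the centered (and optionally unit-variance scaled) traits.

    Eigen-decomposition of the sample covariance (n-1 denominator) of the
    transformed data; with scaling the eigenvalues sum to the number of
    traits.  Component signs follow the largest-absolute-loading-positive
    convention so loadings are platform-reproducible.
    """
    table = validate_morph_table(table)
    X = table[list(TRAITS)].to_numpy(float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 individuals")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = [t for t, s in zip(TRAITS, sd) if s == 0]
        if zero:
            raise ValueError(f"zero-variance trait(s) with scaling enabled: {zero}")
        X = X / sd
    # SVD of the data matrix == eigendecomposition of its covariance
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / (X.shape[0] - 1)
    loadings = Vt.T
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
    scores = X @ loadings
    total = eig.sum()
    prop = eig / total if total > 0 else np.zeros_like(eig)
    return PcaResult(eig, prop, loadings, scores, scale)


def pc_ranges_by_population(
    result: PcaResult, table: pd.DataFrame, component: int = 0
) -> dict[str, tuple[float, float]]:
    """Per-population [min, max] interval of scores along one component."""
    table = validate_morph_table(table)
    if len(table) != result.scores.shape[0]:
        raise ValueError("table and scores disagree on individual count")
    out: dict[str, tuple[float, float]] = {}
    sc = result.scores[:, component]
    for pop in dict.fromkeys(table["population"]):
        v = sc[(table["population"] == pop).to_numpy()]
        out[pop] = (float(v.min()), float(v.max()))
    return out
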
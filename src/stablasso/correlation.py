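"""Pairwise Spearman rank correlation screen.

Descriptive multicollinearity check run before the penalized regression: all
pairwise Spearman rank correlations between numeric variables, with
unadjusted two-sided p-values.  Ties receive average ranks, so the
coefficient is the Pearson correlation of the rank vectors.  P-values use
the classical t approximation for n > 10 and exact enumeration of rank
permutations for smaller samples, where the t approximation is poor.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import CohortTable, DesignMatrix

logger = logging.getLogger(__name__)

#: sample size at and below which exact permutation p-values are used
EXACT_N = 10


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman correlation and p-value matrices.

    Variables that are constant have undefined correlations; their rows and
    columns are NaN and their names listed in ``undefined``.
    """

    r: np.ndarray
    p_values: np.ndarray
    names: list[str]
    n_obs: int = 0
    undefined: list[str] = field(default_factory=list)

    def to_tsv(self, r_path: str | Path, p_path: str | Path) -> None:
        pd.DataFrame(self.r, index=self.names, columns=self.names).to_csv(
            r_path, sep="\t", index_label="variable"
        )
        pd.DataFrame(self.p_values, index=self.names, columns=self.names).to_csv(
            p_path, sep="\t", index_label="variable"
        )


def _numeric_frame(data: CohortTable | DesignMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(data, CohortTable):
        cols = [
            n
            for n in data.predictors
            if data.meta[n].kind == "numeric"
        ]
        return data.data[cols].astype(float)
    if isinstance(data, DesignMatrix):
        cols = [n for n in data.column_names if n not in data.binary_columns]
        idx = [data.column_names.index(n) for n in cols]
        return pd.DataFrame(data.X[:, idx], columns=cols)
    return data.astype(float)


def spearman_matrix(data: CohortTable | DesignMatrix | pd.DataFrame) -> CorrelationMatrix:
    """Spearman rank correlation of every numeric variable pair.

    The screen is meant to run on the complete-case table; missing values
    are rejected rather than handled pairwise.
    """
    frame = _numeric_frame(data)
    if frame.isna().any().any():
        raise ValueError("correlation screen requires complete cases")
    n, p = frame.shape
    if n < 3:
        raise ValueError("need at least 3 observations")
    if p < 2:
        raise ValueError("need at least 2 numeric variables")
    names = list(frame.columns)
    values = frame.to_numpy(dtype=np.float64)

    constant = [names[j] for j in range(p) if np.ptp(values[:, j]) == 0.0]
    ranks = np.column_stack([stats.rankdata(values[:, j]) for j in range(p)])

    with np.errstate(invalid="ignore"):
        r = np.corrcoef(ranks, rowvar=False)
    np.fill_diagonal(r, 1.0)

    if n > EXACT_N:
        pmat = _t_approx_p(r, n)
    else:
        pmat = _exact_permutation_p(ranks)
    np.fill_diagonal(pmat, np.nan)

    if constant:
        logger.warning("constant variables with undefined correlations: %s", constant)
        for name in constant:
            j = names.index(name)
            r[j, :] = np.nan
            r[:, j] = np.nan
            pmat[j, :] = np.nan
            pmat[:, j] = np.nan
    return CorrelationMatrix(r=r, p_values=pmat, names=names, n_obs=n, undefined=constant)


def _t_approx_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value via t = r * sqrt((n-2)/(1-r^2)) on n-2 df."""
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt((n - 2) / (1.0 - rr * rr))
    pmat = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pmat[np.isinf(t)] = 0.0
    return pmat


def _perm_chunks(n: int, chunk: int = 50_000):
    """Yield all n! permutations of range(n) as (chunk, n) index arrays."""
    it = itertools.permutations(range(n))
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            return
        yield np.asarray(block, dtype=np.intp)


def _exact_permutation_p(ranks: np.ndarray) -> np.ndarray:
    """Exact permutation p-values: proportion of permutations of one rank
    vector whose |rho| is at least the observed |rho| (ties kept fixed)."""
    n, p = ranks.shape
    pmat = np.ones((p, p))
    counts = np.zeros((p, p), dtype=np.int64)
    obs = np.zeros((p, p))
    active = [j for j in range(p) if np.ptp(ranks[:, j]) > 0.0]
    for j in active:
        for k in active:
            if k > j:
                obs[j, k] = _pearson(ranks[:, j], ranks[:, k])
    total = 0
    for perms in _perm_chunks(n):
        total += perms.shape[0]
        for j in active:
            xj = ranks[:, j]
            for k in active:
                if k <= j:
                    continue
                null = _pearson_many(xj, ranks[perms, k])
                counts[j, k] += int(np.sum(np.abs(null) >= np.abs(obs[j, k]) - 1e-12))
    for j in active:
        for k in active:
            if k > j:
                pmat[j, k] = pmat[k, j] = counts[j, k] / total
    return pmat


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def _pearson_many(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson correlation of x against every row of Y."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = Yc @ xc
    den = np.sqrt((xc @ xc) * np.einsum("ij,ij->i", Yc, Yc))
    return num / den


def significant_pairs(
    corr: CorrelationMatrix, alpha: float = 0.05
) -> list[tuple[str, str, float, float]]:
    """Off-diagonal pairs with p < alpha, each once, sorted by |r| descending."""
    out: list[tuple[str, str, float, float]] = []
    p = len(corr.names)
    for j in range(p):
        for k in range(j + 1, p):
            pv = corr.p_values[j, k]
            if np.isfinite(pv) and pv < alpha:
                out.append((corr.names[j], corr.names[k], float(corr.r[j, k]), float(pv)))
    out.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))
    return out


def plot_heatmap(corr: CorrelationMatrix, path: str | Path, alpha: float = 0.05) -> None:
    """Optional dot-heatmap of significant correlations (area ∝ |r|)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = len(corr.names)
    fig, ax = plt.subplots(figsize=(0.4 * p + 2, 0.4 * p + 2))
    for j in range(p):
        for k in range(p):
            if j == k:
                continue
            pv = corr.p_values[j, k]
            if np.isfinite(pv) and pv < alpha:
                r = corr.r[j, k]
                ax.scatter(k, p - 1 - j, s=200 * abs(r), c=[r], cmap="RdBu_r",
                           vmin=-1, vmax=1)
    ax.set_xticks(range(p), corr.names, rotation=90, fontsize=7)
    ax.set_yticks(range(p), list(reversed(corr.names)), fontsize=7)
    ax.set_xlim(-0.5, p - 0.5)
    ax.set_ylim(-0.5, p - 0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
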
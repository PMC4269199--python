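"""Pairwise Pearson screening of phylum relative abundances against
environmental variables, with false-discovery-rate control.

The input is a samples × features matrix whose columns mix phylum relative
abundances (from the 85%-subsampled averaging in
:func:`deepcomm.tables_io.mean_relative_abundance`) and environmental
measurements.  Every unordered column pair is correlated; pairs are declared
significant only when the raw p-value and the adjusted q-value are both
below their cutoffs.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pairwise_pearson",
    "adjust_qvalues",
    "significant_pairs",
    "correlation_screen",
]


def pairwise_pearson(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and two-sided p for every unordered column pair.

    Rows with a missing value in either column of a pair are dropped for
    that pair (pairwise-complete); pairs with fewer than 3 complete rows or
    a zero-variance column are excluded with a warning.  p-values use the
    exact t-distribution with n − 2 degrees of freedom.
    """
    if matrix.shape[0] < 3:
        raise ValueError("need at least three samples")
    cols = list(matrix.columns)
    rows = []
    skipped = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            x = matrix[cols[i]].astype(float)
            y = matrix[cols[j]].astype(float)
            ok = x.notna() & y.notna()
            n = int(ok.sum())
            if n < 3:
                skipped.append((cols[i], cols[j], "fewer than 3 complete samples"))
                continue
            xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
            if np.std(xv) == 0 or np.std(yv) == 0:
                skipped.append((cols[i], cols[j], "zero variance"))
                continue
            res = stats.pearsonr(xv, yv)
            rows.append(
                {"var1": cols[i], "var2": cols[j], "n": n,
                 "r": float(res.statistic), "p": float(res.pvalue)}
            )
    if skipped:
        warnings.warn(f"excluded {len(skipped)} column pairs: {skipped[:5]}...", stacklevel=2)
    return pd.DataFrame(rows, columns=["var1", "var2", "n", "r", "p"])


def _storey_qvalues(p: np.ndarray, lambdas: Sequence[float] = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)) -> np.ndarray:
    """Storey-style q-values with a conservative fixed-λ-grid π0 estimate.

    π0 is the median over the grid of #{p > λ} / (m(1−λ)), clipped to
    (0, 1]; q-values are π0 · (BH step-up values).  At small m this reduces
    in practice to BH (π0 → 1).
    """
    m = len(p)
    pi0_grid = [np.mean(p > lam) / (1.0 - lam) for lam in lambdas]
    pi0 = float(np.clip(np.median(pi0_grid), 1.0 / m if m else 1.0, 1.0))
    bh = multipletests(p, method="fdr_bh")[1]
    return np.minimum(pi0 * bh, 1.0)


def adjust_qvalues(pvals, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment of a p-value list.

    ``bh`` is the Benjamini–Hochberg step-up (deterministic, the default);
    ``storey`` additionally rescales by an estimated null proportion π0.
    Either way the ranking of the p-values is preserved and q_i ≥ p_i.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        return _storey_qvalues(p)
    raise ValueError(f"unknown method {method!r}")


def significant_pairs(table: pd.DataFrame, p_cut: float = 0.05, q_cut: float = 0.05) -> pd.DataFrame:
    """Rows with p < p_cut and q < q_cut (both conditions required)."""
    if "q" not in table.columns:
        raise ValueError("table lacks a 'q' column; run adjust_qvalues first")
    if table.empty:
        return table.copy()
    return table[(table["p"] < p_cut) & (table["q"] < q_cut)].copy()


def correlation_screen(
    matrix: pd.DataFrame,
    method: str = "bh",
    p_cut: float = 0.05,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Full screen: pairwise Pearson → q-values → significance flag."""
    table = pairwise_pearson(matrix)
    if table.empty:
        table["q"] = []
        table["significant"] = []
        return table
    table["q"] = adjust_qvalues(table["p"].to_numpy(), method=method)
    table["significant"] = (table["p"] < p_cut) & (table["q"] < q_cut)
    return table
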
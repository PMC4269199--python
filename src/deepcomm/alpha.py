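"""Within-site (alpha) diversity: Shannon entropy, Pielou's evenness, Chao1
richness with its classical standard error, rarefaction curves, and the
observed/Chao1 coverage percentage used to judge how completely a sample was
sequenced.

All entropies default to base 2 (bits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import CommunityTable, _iteration_rng, _subsample_counts

__all__ = [
    "shannon",
    "pielou",
    "chao1",
    "Chao1Estimate",
    "DiversityEstimate",
    "coverage_percent",
    "rarefaction_curve",
    "diversity_table",
]


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D abundance vector")
    if (arr < 0).any():
        raise ValueError("abundances must be nonnegative")
    return arr


def shannon(counts, log_base: float = 2.0) -> float:
    """Shannon entropy H' = −Σ p_i log(p_i) over taxa with positive counts."""
    arr = _as_counts(counts)
    total = arr.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = arr[arr > 0] / total
    return float(-(p * (np.log(p) / np.log(log_base))).sum())


def pielou(counts) -> float:
    """Pielou's evenness J = H' / log2(G_obs), in [0, 1].

    Undefined for fewer than two observed taxa (log2(1) = 0).
    """
    arr = _as_counts(counts)
    g_obs = int((arr > 0).sum())
    if g_obs < 2:
        raise ValueError("evenness requires at least two observed taxa")
    return shannon(arr, log_base=2.0) / float(np.log2(g_obs))


@dataclass(frozen=True)
class DiversityEstimate:
    site: str
    g_obs: int
    h_prime: float
    evenness: float | None


@dataclass(frozen=True)
class Chao1Estimate:
    site: str
    g_obs: int
    f1: int  # singleton taxa
    f2: int  # doubleton taxa
    estimate: float
    se: float


def chao1(counts, site: str = "") -> Chao1Estimate:
    """Chao1 richness: G_obs + F1²/(2 F2), from singleton/doubleton counts.

    When no doubletons are observed the bias-corrected form
    G_obs + F1(F1−1)/2 is used instead of an unguarded division.  The
    standard error follows the classical Chao (1987) variance formulas;
    with no singletons the estimator degenerates to G_obs and se is 0.
    """
    arr = _as_counts(counts)
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("Chao1 requires integer counts")
    arr = np.round(arr).astype(np.int64)
    g_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    if f1 == 0:
        est, var = float(g_obs), 0.0
    elif f2 > 0:
        est = g_obs + f1 * f1 / (2.0 * f2)
        r = f1 / f2
        var = f2 * (r**2 / 2.0 + r**3 + r**4 / 4.0)
    else:
        est = g_obs + f1 * (f1 - 1) / 2.0
        var = (
            f1 * (f1 - 1) / 2.0
            + f1 * (2 * f1 - 1) ** 2 / 4.0
            - f1**4 / (4.0 * est)
        )
    return Chao1Estimate(site=site, g_obs=g_obs, f1=f1, f2=f2,
                         estimate=float(est), se=float(np.sqrt(max(var, 0.0))))


def coverage_percent(g_obs: int, chao1_estimate: float) -> int:
    """Observed richness as a percentage of the Chao1 extrapolation,
    rounded to the nearest integer."""
    if chao1_estimate <= 0:
        raise ValueError("Chao1 estimate must be positive")
    return int(round(100.0 * g_obs / chao1_estimate))


def rarefaction_curve(counts, depths, iterations: int = 100, seed: int = 0) -> np.ndarray:
    """Mean number of taxa observed in without-replacement subsamples.

    For each depth, ``iterations`` subsamples are drawn and the mean count of
    taxa present is returned; the analytic expectation is
    G − Σ_i C(N−n_i, d)/C(N, d), non-decreasing in depth.
    """
    arr = np.round(_as_counts(counts)).astype(np.int64)
    total = int(arr.sum())
    depths = np.asarray(depths, dtype=np.int64)
    if (depths > total).any():
        raise ValueError(f"depth exceeds total reads ({total})")
    if (depths < 1).any():
        raise ValueError("depths must be positive")
    means = np.zeros(len(depths), dtype=float)
    for i in range(iterations):
        rng = _iteration_rng(seed, i)
        for k, d in enumerate(depths):
            sub = _subsample_counts(arr, int(d), rng)
            means[k] += (sub > 0).sum()
    return means / iterations


def diversity_table(table: CommunityTable, drop_singletons: bool = False) -> pd.DataFrame:
    """Per-site summary: G_obs, H' (bits), Pielou's J, Chao1 ± se, coverage %.

    ``drop_singletons`` removes taxa observed exactly once in each site
    before computing, the sensitivity analysis used to check that rare taxa
    do not drive the result.
    """
    rows = []
    for site in table.sites:
        counts = table.site_counts(site)
        if drop_singletons:
            counts = np.where(counts == 1, 0, counts)
        g_obs = int((counts > 0).sum())
        h = shannon(counts)
        j = pielou(counts) if g_obs >= 2 else np.nan
        c = chao1(counts, site=site)
        rows.append(
            {
                "site": site, "N": int(counts.sum()), "G_obs": g_obs,
                "shannon_bits": h, "pielou": j, "chao1": c.estimate,
                "chao1_se": c.se,
                "coverage_percent": coverage_percent(g_obs, c.estimate) if c.estimate > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("site")
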
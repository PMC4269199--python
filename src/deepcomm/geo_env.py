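"""Geography and environment: great-circle distance matrices, scaled
environmental Euclidean distances, matrix (Mantel-style) Pearson correlation,
the exhaustive best-subset ("bioenv") search for the environmental variables
whose distance structure best matches a community dissimilarity matrix, and
geothermal depth estimation from spring temperature.

The depth estimate assumes conductively warmed, gravity-circulated meteoric
water: depth = (water temperature − mean annual surface temperature) /
geothermal gradient, evaluated at the low and high ends of the regional
gradient to bracket the circulation depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .beta import DistanceMatrix

__all__ = [
    "great_circle_matrix",
    "scale_variables",
    "euclidean_env_distance",
    "matrix_correlation",
    "bioenv",
    "BioenvResult",
    "estimate_depth",
    "DepthEstimate",
]

EARTH_RADIUS_KM = 6371.0


def great_circle_matrix(
    coords: Sequence[tuple[float, float]] | pd.DataFrame,
    ids: Sequence[str] | None = None,
    radius_km: float = EARTH_RADIUS_KM,
) -> DistanceMatrix:
    """Pairwise great-circle (haversine) distances in km.

    ``coords`` is a sequence of (latitude, longitude) in signed decimal
    degrees, or a DataFrame with ``latitude``/``longitude`` columns (its
    index supplies ids).
    """
    if isinstance(coords, pd.DataFrame):
        if ids is None:
            ids = [str(i) for i in coords.index]
        arr = coords[["latitude", "longitude"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(coords, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("coords must be (n, 2) latitude/longitude pairs")
    n = arr.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]
    lat = np.radians(arr[:, 0])[:, None]
    lon = np.radians(arr[:, 1])[:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    h = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    d = 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # symmetrise away rounding noise
    return DistanceMatrix(tuple(ids), d)


def scale_variables(env: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    """Center each named column to mean 0 and scale to unit (sample) sd.

    Missing values and zero-variance columns are rejected: a silent NaN or a
    constant column would make the downstream Euclidean distances
    meaningless.
    """
    missing_cols = [v for v in variables if v not in env.columns]
    if missing_cols:
        raise KeyError(f"variables not in table: {missing_cols}")
    sub = env[list(variables)].astype(float)
    for v in variables:
        col = sub[v]
        if col.isna().any():
            bad = list(col.index[col.isna()])
            raise ValueError(f"variable {v!r} missing for sites {bad}")
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"variable {v!r} has zero variance")
    return (sub - sub.mean()) / sub.std(ddof=1)


def euclidean_env_distance(scaled: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distance between sites over the scaled columns."""
    arr = scaled.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("scaled matrix contains missing values")
    sq = ((arr[:, None, :] - arr[None, :, :]) ** 2).sum(axis=2)
    return DistanceMatrix(tuple(map(str, scaled.index)), np.sqrt(sq))


def matrix_correlation(
    m1: DistanceMatrix, m2: DistanceMatrix, full_matrix: bool = False
) -> tuple[float, float]:
    """Pearson correlation between two distance matrices → (PCC, R²).

    The strictly-upper triangles are vectorised and correlated; with
    ``full_matrix`` every cell (including the diagonal) is used instead — a
    compatibility mode for spreadsheet-style whole-matrix correlation.
    """
    if m1.ids != m2.ids:
        if set(m1.ids) != set(m2.ids):
            raise ValueError("matrices cover different site sets")
        m2 = m2.reorder(m1.ids)
    if full_matrix:
        v1, v2 = m1.values.ravel(), m2.values.ravel()
    else:
        v1, v2 = m1.condensed(), m2.condensed()
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("matrix correlation undefined for a constant matrix")
    r = float(stats.pearsonr(v1, v2).statistic)
    return r, r * r


@dataclass(frozen=True)
class BioenvResult:
    """Exhaustive ranking of environmental-variable subsets.

    ``ranking`` rows are (subset, PCC, R²), sorted by descending PCC with
    ties broken toward smaller subsets (then lexicographically); the best
    entry is duplicated in the ``best_*`` fields.  ``n_subsets`` = 2^k − 1.
    """

    ranking: tuple[tuple[tuple[str, ...], float, float], ...]
    best_subset: tuple[str, ...]
    best_pcc: float
    best_r2: float
    n_subsets: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(", ".join(s), pcc, r2) for s, pcc, r2 in self.ranking],
            columns=["subset", "pcc", "r2"],
        )


def bioenv(
    env: pd.DataFrame,
    variables: Sequence[str],
    community_dissim: DistanceMatrix,
    max_variables: int = 20,
    full_matrix: bool = False,
) -> BioenvResult:
    """Search all nonempty variable subsets for the best matrix correlation.

    Each subset is scaled, turned into a Euclidean distance matrix, and
    correlated (Pearson, upper triangle) against ``community_dissim``.  With
    k variables 2^k − 1 subsets are evaluated, so k is guarded at
    ``max_variables``.
    """
    variables = [str(v) for v in variables]
    k = len(variables)
    if k == 0:
        raise ValueError("no variables given")
    if k > max_variables:
        raise ValueError(
            f"{k} variables imply {2**k - 1} subsets; raise max_variables to override"
        )
    site_order = [str(s) for s in env.index]
    if set(site_order) != set(community_dissim.ids):
        raise ValueError("environment table and dissimilarity matrix cover different sites")
    dissim = community_dissim.reorder(site_order)
    scaled_all = scale_variables(env, variables)
    # squared Euclidean distance is additive over variables, so precompute
    # one condensed squared-difference vector per variable and assemble each
    # subset's distances by summation
    n = len(site_order)
    iu = np.triu_indices(n, k=1)
    sq_by_var = {}
    for v in variables:
        col = scaled_all[v].to_numpy()
        if full_matrix:
            sq_by_var[v] = ((col[:, None] - col[None, :]) ** 2).ravel()
        else:
            sq_by_var[v] = ((col[:, None] - col[None, :]) ** 2)[iu]
    target = dissim.values.ravel() if full_matrix else dissim.condensed()
    t_centered = target - target.mean()
    t_norm = float(np.sqrt((t_centered**2).sum()))
    if t_norm == 0:
        raise ValueError("matrix correlation undefined for a constant matrix")
    results = []
    # enumerate by subset size, then lexicographically in the given order
    for size in range(1, k + 1):
        for subset in combinations(variables, size):
            d = np.sqrt(sum(sq_by_var[v] for v in subset))
            d_centered = d - d.mean()
            d_norm = float(np.sqrt((d_centered**2).sum()))
            if d_norm == 0:
                raise ValueError(
                    f"subset {subset} yields a constant distance matrix"
                )
            pcc = float((d_centered * t_centered).sum() / (d_norm * t_norm))
            results.append((subset, pcc, pcc * pcc))
    # stable sort: descending PCC; ties stay in size-then-lex order (parsimony)
    ranking = tuple(sorted(results, key=lambda t: -t[1]))
    best = ranking[0]
    return BioenvResult(
        ranking=ranking, best_subset=best[0], best_pcc=best[1], best_r2=best[2],
        n_subsets=len(results),
    )


@dataclass(frozen=True)
class DepthEstimate:
    water_temp: float
    surface_temp: float
    gradient_low: float
    gradient_high: float
    depth_min_m: int  # ΔT / gradient_high
    depth_max_m: int  # ΔT / gradient_low


def estimate_depth(
    water_temp: float | tuple[float, float],
    surface_temp: float = 20.0,
    gradient_low: float = 20.0,
    gradient_high: float = 30.0,
) -> DepthEstimate:
    """Bracket the minimum groundwater circulation depth of a thermal spring.

    ``water_temp`` may be a (min, max) measured range, in which case its
    midpoint is used.  Depths are reported in metres, rounded to the nearest
    metre; the steep gradient gives the shallow bound and the gentle
    gradient the deep bound.
    """
    if isinstance(water_temp, (tuple, list)):
        t = 0.5 * (water_temp[0] + water_temp[1])
    else:
        t = float(water_temp)
    if gradient_low <= 0 or gradient_high <= 0:
        raise ValueError("geothermal gradients must be positive")
    if t < surface_temp:
        raise ValueError("water temperature below surface temperature")
    dt = t - surface_temp
    return DepthEstimate(
        water_temp=t, surface_temp=surface_temp,
        gradient_low=gradient_low, gradient_high=gradient_high,
        depth_min_m=int(round(1000.0 * dt / gradient_high)),
        depth_max_m=int(round(1000.0 * dt / gradient_low)),
    )
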
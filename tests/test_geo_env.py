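import itertools
import math

import numpy as np
import pandas as pd
import pytest

from deepcomm import synthetic
from deepcomm.beta import DistanceMatrix
from deepcomm.geo_env import (
    EARTH_RADIUS_KM,
    bioenv,
    estimate_depth,
    euclidean_env_distance,
    great_circle_matrix,
    matrix_correlation,
    scale_variables,
)
from deepcomm.tables_io import metadata_frame


class TestGreatCircle:
    def test_identical_points(self):
        d = great_circle_matrix([(10.0, 20.0), (10.0, 20.0)])
        assert d.values[0, 1] == 0.0

    def test_antipodal_points(self):
        d = great_circle_matrix([(0.0, 0.0), (0.0, 180.0)])
        assert d.values[0, 1] == pytest.approx(math.pi * EARTH_RADIUS_KM, rel=1e-9)

    def test_neighbouring_boreholes_four_km(self):
        # two mine boreholes a few km apart, from their DMS coordinates
        meta = {r.site: r for r in synthetic.load_fixture("table3_subsurface")}
        d = great_circle_matrix(
            [(meta[s].latitude, meta[s].longitude) for s in ("Dr5IPC", "TT109")],
            ids=["Dr5IPC", "TT109"],
        )
        assert round(d[("Dr5IPC", "TT109")]) == 4

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pts = np.column_stack(
                [rng.uniform(-90, 90, 3), rng.uniform(-180, 180, 3)]
            )
            d = great_circle_matrix([tuple(p) for p in pts]).values
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0)
            for i, j, k in itertools.permutations(range(3)):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-6


class TestScaleVariables:
    def test_hand_zscore(self):
        env = pd.DataFrame({"v": [1.0, 2.0, 3.0]}, index=list("abc"))
        out = scale_variables(env, ["v"])
        assert out["v"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_column_rejected(self):
        env = pd.DataFrame({"v": [2.0, 2.0, 2.0]}, index=list("abc"))
        with pytest.raises(ValueError, match="'v'"):
            scale_variables(env, ["v"])

    def test_idempotent_on_standardised_column(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=8)
        col = (col - col.mean()) / col.std(ddof=1)
        env = pd.DataFrame({"v": col}, index=[f"s{i}" for i in range(8)])
        out = scale_variables(env, ["v"])
        assert np.allclose(out["v"], col, atol=1e-12)

    def test_missing_value_names_site(self):
        env = pd.DataFrame({"v": [1.0, np.nan, 3.0]}, index=list("abc"))
        with pytest.raises(ValueError, match="b"):
            scale_variables(env, ["v"])


class TestEuclideanEnvDistance:
    def test_three_four_five(self):
        scaled = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        d = euclidean_env_distance(scaled)
        assert d.values[0, 1] == pytest.approx(5.0)

    def test_identical_rows(self):
        scaled = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        assert euclidean_env_distance(scaled).values[0, 1] == 0.0

    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(4, 3))
        d = euclidean_env_distance(pd.DataFrame(x, index=list("abcd"))).values
        for i, j in itertools.combinations(range(4), 2):
            expected = math.sqrt(sum((x[i, k] - x[j, k]) ** 2 for k in range(3)))
            assert d[i, j] == pytest.approx(expected, abs=1e-12)


def random_distance_matrix(rng, ids):
    n = len(ids)
    raw = rng.random((n, n))
    d = (raw + raw.T) / 2
    np.fill_diagonal(d, 0)
    return DistanceMatrix(tuple(ids), d)


class TestMatrixCorrelation:
    def test_proportional_matrices(self):
        rng = np.random.default_rng(3)
        m1 = random_distance_matrix(rng, "abcde")
        m2 = DistanceMatrix(m1.ids, 2.0 * m1.values)
        pcc, r2 = matrix_correlation(m1, m2)
        assert pcc == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_decreasing_affine_gives_minus_one(self):
        rng = np.random.default_rng(4)
        m1 = random_distance_matrix(rng, "abcd")
        vals = 5.0 - 2.0 * m1.values
        np.fill_diagonal(vals, 0)
        # not a metric, but correlation only sees the upper triangle
        m2 = DistanceMatrix(m1.ids, vals)
        pcc, _ = matrix_correlation(m1, m2)
        assert pcc == pytest.approx(-1.0)

    def test_matches_manual_pearson_on_pairs(self):
        rng = np.random.default_rng(5)
        m1 = random_distance_matrix(rng, "abcde")
        m2 = random_distance_matrix(rng, "abcde")
        v1, v2 = m1.condensed(), m2.condensed()
        assert len(v1) == 10
        r_manual = (
            ((v1 - v1.mean()) * (v2 - v2.mean())).sum()
            / math.sqrt(((v1 - v1.mean()) ** 2).sum() * ((v2 - v2.mean()) ** 2).sum())
        )
        pcc, _ = matrix_correlation(m1, m2)
        assert pcc == pytest.approx(r_manual, abs=1e-12)

    def test_site_order_is_aligned_before_correlating(self):
        rng = np.random.default_rng(6)
        m1 = random_distance_matrix(rng, "abcd")
        m2 = m1.reorder(["d", "b", "a", "c"])
        pcc, _ = matrix_correlation(m1, m2)
        assert pcc == pytest.approx(1.0)


def bioenv_oracle(env, variables, dissim):
    """Naive re-implementation: explicit subset loops, hand-rolled z-scores,
    squared-difference distances and textbook Pearson."""
    ids = list(env.index)
    n = len(ids)
    pairs = list(itertools.combinations(range(n), 2))
    target = [dissim.values[i, j] for i, j in pairs]
    best = None
    for size in range(1, len(variables) + 1):
        for subset in itertools.combinations(variables, size):
            cols = []
            for v in subset:
                x = env[v].to_numpy(dtype=float)
                cols.append((x - x.mean()) / x.std(ddof=1))
            dist = [
                math.sqrt(sum((col[i] - col[j]) ** 2 for col in cols))
                for i, j in pairs
            ]
            mx, my = np.mean(dist), np.mean(target)
            num = sum((a - mx) * (b - my) for a, b in zip(dist, target))
            den = math.sqrt(
                sum((a - mx) ** 2 for a in dist) * sum((b - my) ** 2 for b in target)
            )
            r = num / den
            if best is None or r > best[0] + 1e-12:
                best = (r, subset)
    return best


class TestBioenv:
    def test_nine_variables_511_subsets(self):
        rng = np.random.default_rng(7)
        ids = [f"s{i}" for i in range(6)]
        env = pd.DataFrame(
            rng.normal(size=(6, 9)), index=ids, columns=[f"v{i}" for i in range(9)]
        )
        dissim = random_distance_matrix(rng, ids)
        res = bioenv(env, list(env.columns), dissim)
        assert res.n_subsets == 511

    def test_single_variable(self):
        rng = np.random.default_rng(8)
        ids = list("abcd")
        env = pd.DataFrame({"only": rng.normal(size=4)}, index=ids)
        res = bioenv(env, ["only"], random_distance_matrix(rng, ids))
        assert res.n_subsets == 1
        assert res.best_subset == ("only",)

    def test_matches_naive_oracle_small_k(self):
        rng = np.random.default_rng(9)
        for trial in range(10):
            ids = [f"s{i}" for i in range(6)]
            k = 2 + trial % 3  # 2..4 variables
            env = pd.DataFrame(
                rng.normal(size=(6, k)), index=ids, columns=[f"v{i}" for i in range(k)]
            )
            dissim = random_distance_matrix(rng, ids)
            res = bioenv(env, list(env.columns), dissim)
            r_oracle, subset_oracle = bioenv_oracle(env, list(env.columns), dissim)
            assert res.best_pcc == pytest.approx(r_oracle, abs=1e-12)
            assert res.best_subset == subset_oracle

    def test_best_dominates_full_subset(self):
        rng = np.random.default_rng(10)
        ids = [f"s{i}" for i in range(7)]
        env = pd.DataFrame(
            rng.normal(size=(7, 5)), index=ids, columns=[f"v{i}" for i in range(5)]
        )
        dissim = random_distance_matrix(rng, ids)
        res = bioenv(env, list(env.columns), dissim)
        full = [entry for entry in res.ranking if len(entry[0]) == 5]
        assert res.best_pcc >= full[0][1]

    def test_planted_variables_recovered(self):
        variables = tuple(f"v{i}" for i in range(8))
        rng = np.random.default_rng(11)
        coords = rng.normal(size=(7, 2))
        d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        dissim = DistanceMatrix(tuple(f"s{i}" for i in range(7)), d)
        env = synthetic.generate_env(
            dissim,
            synthetic.EnvScenario(variables=variables, planted=("v0", "v1"), noise_sd=0.1, seed=11),
        )
        res = bioenv(env, list(variables), dissim)
        assert {"v0", "v1"} <= set(res.best_subset)

    def test_guard_on_variable_count(self):
        env = pd.DataFrame(
            np.random.default_rng(0).normal(size=(4, 25)),
            index=list("abcd"),
            columns=[f"v{i}" for i in range(25)],
        )
        dissim = random_distance_matrix(np.random.default_rng(1), "abcd")
        with pytest.raises(ValueError, match="override"):
            bioenv(env, list(env.columns), dissim)


class TestEstimateDepth:
    def test_warm_spring_lower_bound(self):
        # 58 degC over a 20 degC surface at 30 degC/km -> 1267 m
        assert estimate_depth(58.0).depth_min_m == 1267

    def test_hottest_spring_upper_bound(self):
        # (63-67) midpoint 65 degC at 20 degC/km -> 2250 m
        assert estimate_depth((63.0, 67.0)).depth_max_m == 2250

    def test_equilibrium_water(self):
        est = estimate_depth(20.0)
        assert est.depth_min_m == est.depth_max_m == 0

    def test_linear_in_delta_t(self):
        a = estimate_depth(30.0)
        b = estimate_depth(40.0)
        assert b.depth_min_m == pytest.approx(2 * a.depth_min_m, abs=1)
        assert b.depth_max_m == pytest.approx(2 * a.depth_max_m, abs=1)

    def test_cold_water_rejected(self):
        with pytest.raises(ValueError):
            estimate_depth(10.0)


class TestFixtureDepthTable:
    def test_spring_depth_brackets_match_printed_rows(self):
        # the rows where nearest-metre rounding reproduces the published
        # bracket exactly (one printed row is internally inconsistent)
        springs = {r.site: r for r in synthetic.load_fixture("table2_springs")}
        for site, lo, hi in [("Tshipise", 1267, 1900), ("Siloam", 1500, 2250),
                             ("Mphephu", 767, 1150), ("Eiland", 700, 1050)]:
            est = estimate_depth(springs[site].temperature)
            assert (est.depth_min_m, est.depth_max_m) == (lo, hi)
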
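#!/usr/bin/env python
"""Geography vs geochemistry as drivers of community structure.

From the packaged site tables: great-circle distance matrices, geothermal
circulation-depth brackets for each spring, the geographic-vs-community
matrix correlation, and the exhaustive bioenv search over the nine spring
variables (community side from the spring-regime simulation of step 01).
"""

from pathlib import Path

import pandas as pd

from deepcomm.beta import DistanceMatrix, dissimilarity_matrix
from deepcomm.geo_env import bioenv, estimate_depth, great_circle_matrix, matrix_correlation
from deepcomm.synthetic import load_fixture
from deepcomm.tables_io import metadata_frame, read_community_table

OUT = Path(__file__).resolve().parents[1] / "results"
SPRING_VARS = ["elevation", "temperature", "depth", "pH", "TDS", "Na+", "K+", "Ca2+", "Mg2+"]


def main() -> None:
    springs = load_fixture("table2_springs")
    mines = load_fixture("table3_subsurface")
    for name, records in [("spring", springs), ("subsurface", mines)]:
        d = great_circle_matrix(
            [(r.latitude, r.longitude) for r in records], ids=[r.site for r in records]
        )
        d.to_tsv(OUT / f"geographic_km_{name}.tsv")
        print(f"{name}: geographic distances {d.condensed().min():.0f}-{d.condensed().max():.0f} km")

    rows = []
    for r in springs:
        est = estimate_depth(r.temperature)
        rows.append({"site": r.site, "T_mid_C": est.water_temp,
                     "depth_min_m": est.depth_min_m, "depth_max_m": est.depth_max_m})
    depths = pd.DataFrame(rows).set_index("site")
    depths.to_csv(OUT / "spring_depth_estimates.tsv", sep="\t")
    print(depths.to_string())

    # environmental best-subset search against the simulated spring communities
    env = metadata_frame(springs)
    env["depth"] = depths[["depth_min_m", "depth_max_m"]].mean(axis=1)
    table = read_community_table(OUT / "community_spring.tsv")
    dissim = dissimilarity_matrix(table)
    dissim = DistanceMatrix(tuple(env.index), dissim.values)  # align synthetic sites to springs
    res = bioenv(env, SPRING_VARS, dissim)
    res.to_frame().to_csv(OUT / "bioenv_spring_ranking.tsv", sep="\t", index=False)
    print(f"bioenv: {res.n_subsets} subsets; best {res.best_subset} "
          f"(PCC {res.best_pcc:.3f}, R2 {res.best_r2:.3f})")

    geo = DistanceMatrix.from_tsv(OUT / "geographic_km_spring.tsv").reorder(dissim.ids)
    pcc, r2 = matrix_correlation(geo, dissim)
    print(f"geographic vs community matrix correlation: PCC {pcc:.3f}, R2 {r2:.3f}")


if __name__ == "__main__":
    main()
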
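#!/usr/bin/env python
"""Generate the two study regimes used throughout the analysis.

Writes a subsurface-like table (7 deeply sequenced sites sharing a 220-taxon
core) and a spring-like table (6 shallow sites, independent dominants, many
singletons) to results/, and prints their scale so later steps have context.
"""

from pathlib import Path

from deepcomm.synthetic import generate_community, spring_like, subsurface_like
from deepcomm.tables_io import write_community_table

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    for name, scenario in [
        ("subsurface", subsurface_like(seed=SEED)),
        ("spring", spring_like(seed=SEED)),
    ]:
        table = generate_community(scenario)
        path = OUT / f"community_{name}.tsv"
        write_community_table(table, path)
        print(
            f"{name}: {len(table.sites)} sites, {len(table.taxa)} taxa, "
            f"{table.grand_total} reads (depths {table.totals.min()}-{table.totals.max()}) "
            f"-> {path.name}"
        )


if __name__ == "__main__":
    main()
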
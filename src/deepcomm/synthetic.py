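"""Synthetic data generation and packaged fixtures.

Because the amplicon reads behind the original spring/subsurface comparison
were never deposited, every pipeline input can be simulated here instead:

* community count tables in two regimes — a *subsurface-like* regime (a
  large core of taxa shared by all sites with correlated lognormal
  abundances, so pairwise Morisita dissimilarities are low) and a
  *spring-like* regime (essentially no core, per-site independent dominant
  taxa, shallow read depth and many singletons, so dissimilarities are
  high);
* environmental metadata in which a planted subset of variables drives the
  community dissimilarity structure (for best-subset recovery experiments);
* aligned V6-like read sets built from planted haplotypes plus iid
  per-base substitution error (for OTU and oligotyping tests).

The module also ships machine-readable transcriptions of the published
site-property and diversity summary tables as package fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .beta import DistanceMatrix
from .seq_ops import AlignedSequenceSet, SequenceRecord
from .tables_io import CommunityTable, SiteMetadata, read_site_metadata

__all__ = [
    "CommunityScenario",
    "EnvScenario",
    "subsurface_like",
    "spring_like",
    "generate_community",
    "generate_env",
    "generate_reads",
    "load_fixture",
    "fixture_path",
    "FIXTURES",
]


@dataclass(frozen=True)
class CommunityScenario:
    """Parameters of a simulated multi-site community.

    Abundance follows a lognormal rank-abundance model: each taxon gets a
    global weight exp(N(0, sigma)) shared across sites, multiplied per site
    by exp(N(0, site_noise_sigma)).  ``core_size`` taxa occur in every site
    (each is guaranteed at least one read); the rest form a pool from which
    each site draws ``private_fraction`` of the pool independently.  With
    ``dominant_independent`` each site additionally promotes one of its own
    taxa to dominance — the spring-style pattern of one runaway genus per
    site.
    """

    n_sites: int = 7
    n_taxa: int = 900
    core_size: int = 220
    private_fraction: float = 0.08
    sigma: float = 1.6
    site_noise_sigma: float = 0.35
    #: multiplier on non-core taxon weights; < 1 keeps site-private taxa in
    #: the tail so the shared core carries the abundance structure
    private_weight_scale: float = 1.0
    reads_range: tuple[int, int] = (14000, 23500)
    dominant_independent: bool = False
    dominance_factor: float = 40.0
    site_prefix: str = "site"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_size > self.n_taxa:
            raise ValueError("core_size exceeds n_taxa")
        if not 0 <= self.private_fraction <= 1:
            raise ValueError("private_fraction must lie in [0, 1]")
        if self.reads_range[0] > self.reads_range[1] or self.reads_range[0] < 1:
            raise ValueError("invalid reads range")
        if self.reads_range[0] < self.core_size:
            raise ValueError("read totals must cover one read per core taxon")


def subsurface_like(seed: int = 0, n_sites: int = 7) -> CommunityScenario:
    """Deeply sequenced sites sharing a large correlated core (low Morisita
    dissimilarity): 220 core taxa of 900, 14,000–23,500 reads per site."""
    return CommunityScenario(
        n_sites=n_sites, n_taxa=900, core_size=220, private_fraction=0.08,
        sigma=1.6, site_noise_sigma=0.35, private_weight_scale=0.1,
        reads_range=(14000, 23500),
        dominant_independent=False, site_prefix="sub", seed=seed,
    )


def spring_like(seed: int = 0, n_sites: int = 6) -> CommunityScenario:
    """Shallowly sequenced sites with almost no core, independent per-site
    dominant taxa and many singletons (high Morisita dissimilarity)."""
    return CommunityScenario(
        n_sites=n_sites, n_taxa=300, core_size=1, private_fraction=0.4,
        sigma=1.2, site_noise_sigma=0.5, reads_range=(120, 800),
        dominant_independent=True, dominance_factor=40.0,
        site_prefix="spr", seed=seed,
    )


def generate_community(scenario: CommunityScenario) -> CommunityTable:
    """Draw a site × taxon count table from a community scenario.

    Core taxa are seeded with one read each (so the configured core really
    is shared by every site) and the remaining depth is multinomial over the
    site's lognormal weights.  Deterministic for a fixed scenario seed; row
    totals equal the drawn per-site depths exactly.
    """
    rng = np.random.default_rng(scenario.seed)
    n_core = scenario.core_size
    pool = scenario.n_taxa - n_core
    width = len(str(scenario.n_taxa))
    # taxon ids carry the scenario prefix so different regimes never collide
    taxa = [f"{scenario.site_prefix}_core_{i:0{width}d}" for i in range(n_core)] + [
        f"{scenario.site_prefix}_tax_{i:0{width}d}" for i in range(pool)
    ]
    sites = [f"{scenario.site_prefix}_{j + 1}" for j in range(scenario.n_sites)]
    global_w = np.exp(rng.normal(0.0, scenario.sigma, size=scenario.n_taxa))
    n_private = int(round(scenario.private_fraction * pool))
    counts = np.zeros((scenario.n_sites, scenario.n_taxa), dtype=np.int64)
    for j in range(scenario.n_sites):
        chosen = np.zeros(scenario.n_taxa, dtype=bool)
        chosen[:n_core] = True
        if n_private > 0 and pool > 0:
            picks = rng.choice(pool, size=min(n_private, pool), replace=False)
            chosen[n_core + picks] = True
        w = global_w * np.exp(rng.normal(0.0, scenario.site_noise_sigma, size=scenario.n_taxa))
        w[n_core:] *= scenario.private_weight_scale
        w = np.where(chosen, w, 0.0)
        if scenario.dominant_independent:
            candidates = np.nonzero(chosen)[0]
            dom = rng.choice(candidates[candidates >= n_core]) if (candidates >= n_core).any() else rng.choice(candidates)
            w[dom] *= scenario.dominance_factor
        depth = int(rng.integers(scenario.reads_range[0], scenario.reads_range[1] + 1))
        row = np.zeros(scenario.n_taxa, dtype=np.int64)
        row[:n_core] = 1
        p = w / w.sum()
        row += rng.multinomial(depth - n_core, p)
        counts[j] = row
    return CommunityTable(pd.DataFrame(counts, index=sites, columns=taxa))


@dataclass(frozen=True)
class EnvScenario:
    """Environmental-metadata scenario for best-subset recovery experiments.

    ``planted`` variables are built from the leading principal coordinates
    of the community dissimilarity (so their Euclidean distance structure
    tracks it at roughly ``effect_size`` signal against ``noise_sd`` noise);
    the remaining variables are independent standard-normal decoys.
    """

    variables: tuple[str, ...]
    planted: tuple[str, ...]
    effect_size: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.planted) - set(self.variables)
        if unknown:
            raise ValueError(f"planted variables not in variable list: {sorted(unknown)}")


def _principal_coordinates(dissim: DistanceMatrix, k: int) -> np.ndarray:
    """Classical MDS embedding: top-k axes of −½ J D² J (negative axes dropped)."""
    d = dissim.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = np.zeros((n, k))
    for axis in range(min(k, n)):
        if vals[axis] > 1e-12:
            coords[:, axis] = vecs[:, axis] * np.sqrt(vals[axis])
    return coords


def _equalize_column_variance(coords: np.ndarray, sweeps: int = 8) -> np.ndarray:
    """Rotate an embedding so all columns share the same variance.

    Pairwise Jacobi-style rotations preserve the row-to-row distances while
    redistributing variance across columns.  This matters because the
    best-subset search standardises each variable independently: only when
    the planted columns carry equal variance does that standardisation act
    as a pure rescaling of the planted distance structure.
    """
    x = coords.copy()
    k = x.shape[1]
    for _ in range(sweeps):
        for a in range(k):
            for b in range(a + 1, k):
                va, vb = x[:, a].var(), x[:, b].var()
                c = ((x[:, a] - x[:, a].mean()) * (x[:, b] - x[:, b].mean())).mean()
                if abs(va - vb) < 1e-15 and abs(c) < 1e-15:
                    continue
                theta = 0.5 * np.arctan2(vb - va, 2.0 * c) if c != 0 else np.pi / 4
                u = x[:, a] * np.cos(theta) + x[:, b] * np.sin(theta)
                w = -x[:, a] * np.sin(theta) + x[:, b] * np.cos(theta)
                x[:, a], x[:, b] = u, w
    return x


def generate_env(community_dissim: DistanceMatrix, scenario: EnvScenario) -> pd.DataFrame:
    """Build a sites × variables metadata table around a dissimilarity matrix."""
    rng = np.random.default_rng(scenario.seed)
    n = len(community_dissim.ids)
    coords = _principal_coordinates(community_dissim, len(scenario.planted))
    if coords.shape[1] > 1:
        coords = _equalize_column_variance(coords)
    data: dict[str, np.ndarray] = {}
    for axis, name in enumerate(scenario.planted):
        signal = coords[:, axis]
        sd = signal.std()
        if sd > 0:
            signal = signal / sd
        data[name] = scenario.effect_size * signal + scenario.noise_sd * rng.normal(size=n)
    for name in scenario.variables:
        if name not in data:
            data[name] = rng.normal(size=n)
    frame = pd.DataFrame(data, index=community_dissim.ids)
    return frame[list(scenario.variables)]


_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def generate_reads(
    haplotypes: list[str],
    proportions: list[float],
    n_reads: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> AlignedSequenceSet:
    """Simulate aligned reads from haplotypes with iid substitution error.

    Each read picks a source haplotype (multinomial over ``proportions``)
    and every non-gap base is substituted, independently with probability
    ``error_rate``, by one of the three other bases.  Gap columns are
    preserved so the output stays aligned.  All reads carry abundance 1.
    """
    if not haplotypes:
        raise ValueError("no haplotypes given")
    lengths = {len(h) for h in haplotypes}
    if len(lengths) != 1:
        raise ValueError("haplotypes must have equal length")
    props = np.asarray(proportions, dtype=float)
    if len(props) != len(haplotypes) or (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, props)
    records = []
    read_no = 0
    for h_idx, (hap, count) in enumerate(zip(haplotypes, counts)):
        hap = hap.upper()
        base_pos = [i for i, c in enumerate(hap) if c != "-"]
        for _ in range(count):
            seq = list(hap)
            if error_rate > 0 and base_pos:
                errs = np.nonzero(rng.random(len(base_pos)) < error_rate)[0]
                for e in errs:
                    pos = base_pos[e]
                    current = _BASE_INDEX.get(seq[pos])
                    if current is None:
                        continue
                    shift = int(rng.integers(1, 4))
                    seq[pos] = "ACGT"[(current + shift) % 4]
            read_no += 1
            records.append(
                SequenceRecord(id=f"read_{read_no:06d}", seq="".join(seq), abundance=1)
            )
    return AlignedSequenceSet(records)


# --- packaged fixtures -------------------------------------------------------

FIXTURES = {
    "table2_springs": "table2_springs.tsv",
    "table3_subsurface": "table3_subsurface.tsv",
    "table4_diversity": "table4_diversity.tsv",
    "contaminant_genera_demo": "contaminant_genera_demo.txt",
}


def fixture_path(name: str) -> Path:
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    return Path(str(resources.files("deepcomm.data") / FIXTURES[name]))


def load_fixture(name: str):
    """Load a packaged fixture by name.

    ``table2_springs`` / ``table3_subsurface`` return lists of
    :class:`SiteMetadata`; ``table4_diversity`` returns a DataFrame indexed
    by site; ``contaminant_genera_demo`` returns a list of genus names.
    """
    path = fixture_path(name)
    if name in ("table2_springs", "table3_subsurface"):
        return read_site_metadata(path)
    if name == "table4_diversity":
        return pd.read_csv(path, sep="\t", index_col=0)
    lines = path.read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
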
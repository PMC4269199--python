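"""Community count tables, site metadata, and abundance-normalisation procedures.

The central container is :class:`CommunityTable`, a site × taxon matrix of
nonnegative integer read counts (``n_ji`` for taxon *i* in site *j*, with
per-site totals ``N_j``).  Site metadata tables carry coordinates in
degrees–minutes–seconds text form (as printed in field tables), physical
measurements that may be ranges (e.g. a temperature of ``63–67``), and
concentrations that may be missing or censored.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTable",
    "SiteMetadata",
    "read_community_table",
    "write_community_table",
    "read_site_metadata",
    "metadata_frame",
    "parse_dms",
    "aggregate_rank",
    "mean_relative_abundance",
    "rarefy",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus")


class TableFormatError(ValueError):
    """Malformed input table (duplicate ids, bad header, unparseable cell)."""


@dataclass
class CommunityTable:
    """Site × taxon count matrix with optional per-taxon rank labels.

    Parameters
    ----------
    counts
        DataFrame indexed by site id with one integer column per taxon.
    taxonomy
        Optional DataFrame indexed by taxon id whose columns are rank labels
        (subset of ``RANKS``); required only by rank aggregation.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            raise TableFormatError("duplicate site identifiers")
        if c.columns.duplicated().any():
            raise TableFormatError("duplicate taxon identifiers")
        values = c.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                if not np.allclose(values, np.round(values)):
                    raise ValueError("counts must be integers")
                c = c.round().astype(np.int64)
            if (c.to_numpy() < 0).any():
                raise ValueError("counts must be nonnegative")
        self.counts = c.astype(np.int64) if values.size else c
        if self.taxonomy is not None:
            missing = set(map(str, c.columns)) - set(map(str, self.taxonomy.index))
            if missing:
                raise ValueError(f"taxonomy missing entries for taxa: {sorted(missing)}")

    @property
    def sites(self) -> list[str]:
        return [str(s) for s in self.counts.index]

    @property
    def taxa(self) -> list[str]:
        return [str(t) for t in self.counts.columns]

    @property
    def totals(self) -> pd.Series:
        """Per-site read totals ``N_j`` (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def site_counts(self, site: str) -> np.ndarray:
        return self.counts.loc[site].to_numpy()

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised proportions (raw, without subsampling)."""
        totals = self.totals
        if (totals == 0).any():
            bad = list(totals.index[totals == 0])
            raise ValueError(f"sites with zero reads: {bad}")
        return self.counts.div(totals, axis=0)


def read_community_table(
    path: str | Path,
    orientation: str = "sites_rows",
    taxonomy: pd.DataFrame | None = None,
) -> CommunityTable:
    """Read a tab-delimited count table.

    ``orientation='sites_rows'`` expects one row per site and a header of
    taxon ids; ``'taxa_rows'`` reads the transpose.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "taxa_rows":
        df = df.T
    elif orientation != "sites_rows":
        raise ValueError(f"unknown orientation: {orientation!r}")
    return CommunityTable(df, taxonomy=taxonomy)


def write_community_table(table: CommunityTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t")


# --- site metadata -----------------------------------------------------------

#: accepts 26°25′12″ with unicode prime/double-prime or ASCII quotes, optional
#: fractional seconds/minutes, optional hemisphere suffix, stray spaces
_DMS_RE = re.compile(
    r"""^\s*(?P<deg>\d+(?:\.\d+)?)\s*[°]\s*
        (?:(?P<min>\d+(?:\.\d+)?)\s*[′'´‘’])?\s*
        (?:(?P<sec>\d+(?:\.\d+)?)\s*[″"“”]|(?P<sec2>\d+(?:\.\d+)?)\s*[′'´‘’][′'´‘’])?\s*
        (?P<hemi>[NSEW])?\s*$""",
    re.VERBOSE,
)


def parse_dms(text: str, hemisphere: str | None = None) -> float:
    """Convert a DMS coordinate string to signed decimal degrees.

    South and West are negative.  The hemisphere may be a suffix on the cell
    or supplied separately (typically taken from a column label such as
    ``"Latitude (S)"``).
    """
    m = _DMS_RE.match(text)
    if not m:
        raise TableFormatError(f"unparseable DMS coordinate: {text!r}")
    deg = float(m.group("deg"))
    minutes = float(m.group("min") or 0.0)
    seconds = float(m.group("sec") or m.group("sec2") or 0.0)
    if minutes >= 60 or seconds >= 60:
        raise TableFormatError(f"minutes/seconds out of range in {text!r}")
    value = deg + minutes / 60.0 + seconds / 3600.0
    hemi = m.group("hemi") or (hemisphere.upper() if hemisphere else None)
    if hemi in ("S", "W"):
        value = -value
    elif hemi not in (None, "N", "E"):
        raise TableFormatError(f"unknown hemisphere {hemi!r}")
    return value


@dataclass
class SiteMetadata:
    """Physical/chemical description of one sampling site.

    ``temperature`` and ``ph`` are (min, max) intervals — equal endpoints for
    a single measurement; ``concentrations`` maps analyte name to molar value
    (``None`` when missing / below detection).  ``censored`` records analytes
    whose value is a one-sided bound rather than a measurement.
    """

    site: str
    latitude: float
    longitude: float
    elevation: float | None = None
    temperature: tuple[float, float] | None = None
    ph: tuple[float, float] | None = None
    tds: float | None = None
    depth: float | None = None
    concentrations: dict[str, float | None] = field(default_factory=dict)
    censored: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not -90 <= self.latitude <= 90:
            raise ValueError(f"{self.site}: latitude out of range")
        if not -180 <= self.longitude <= 180:
            raise ValueError(f"{self.site}: longitude out of range")
        for name, value in self.concentrations.items():
            if value is not None and value < 0:
                raise ValueError(f"{self.site}: negative concentration for {name}")

    @property
    def temperature_mid(self) -> float | None:
        if self.temperature is None:
            return None
        return 0.5 * (self.temperature[0] + self.temperature[1])

    @property
    def ph_mid(self) -> float | None:
        if self.ph is None:
            return None
        return 0.5 * (self.ph[0] + self.ph[1])


_MISSING = {"", "n.a.", "na", "nan", "n.d.", "<d.l.", "<dl", "-"}
_RANGE_RE = re.compile(r"^\s*(-?\d+(?:\.\d+)?(?:e-?\d+)?)\s*[-–]\s*(-?\d+(?:\.\d+)?(?:e-?\d+)?)\s*$", re.I)


def _parse_value(cell: str) -> tuple[tuple[float, float] | None, bool]:
    """Parse a numeric cell: scalar, range, censored bound, or missing.

    Returns ((lo, hi) or None, censored_flag).  Scalars come back with
    lo == hi.  Bounds like ``>1862`` or ``<1e-4`` return the bound value with
    the censored flag set; non-numeric markers return missing.
    """
    text = str(cell).strip()
    if text.lower() in _MISSING:
        return None, False
    censored = False
    if text[0] in "<>":
        inner = text[1:].strip()
        if inner.lower() in _MISSING or not re.match(r"^-?\d", inner):
            return None, False
        text = inner
        censored = True
    m = _RANGE_RE.match(text)
    if m:
        lo, hi = float(m.group(1)), float(m.group(2))
        return (lo, hi), censored
    try:
        v = float(text)
    except ValueError:
        raise TableFormatError(f"unparseable numeric cell: {cell!r}") from None
    return (v, v), censored


_HEMI_RE = re.compile(r"\(([NSEW])\)")


def read_site_metadata(path: str | Path) -> list[SiteMetadata]:
    """Read a tab-delimited site metadata table (sites as rows).

    Coordinate columns are recognised by name (``Latitude``/``Longitude``)
    with the hemisphere taken from the column label, e.g. ``Latitude (S)``.
    Columns whose label ends in ``(M)`` are molar concentrations; recognised
    scalar columns are elevation, depth, temperature, pH and TDS.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    records: list[SiteMetadata] = []
    for site, row in df.iterrows():
        lat = lon = None
        elev = tds = depth = None
        temp = ph = None
        conc: dict[str, float | None] = {}
        censored: set[str] = set()
        for col, cell in row.items():
            label = str(col).strip()
            low = label.lower()
            try:
                if low.startswith("latitude"):
                    hemi = _HEMI_RE.search(label)
                    lat = parse_dms(str(cell), hemi.group(1) if hemi else None)
                elif low.startswith("longitude"):
                    hemi = _HEMI_RE.search(label)
                    lon = parse_dms(str(cell), hemi.group(1) if hemi else None)
                elif low.startswith("elevation") or low.startswith("surface elevation"):
                    v, _ = _parse_value(cell)
                    elev = None if v is None else 0.5 * (v[0] + v[1])
                elif low.startswith("depth"):
                    v, _ = _parse_value(cell)
                    depth = None if v is None else 0.5 * (v[0] + v[1])
                elif low.startswith("temperature") or low == "t (c)":
                    v, c = _parse_value(cell)
                    temp = v
                    if c:
                        censored.add("temperature")
                elif low == "ph":
                    ph, _ = _parse_value(cell)
                elif low.startswith("tds"):
                    v, c = _parse_value(cell)
                    tds = None if v is None else 0.5 * (v[0] + v[1])
                    if c:
                        censored.add("TDS")
                elif label.endswith("(M)"):
                    name = label[: -len("(M)")].strip()
                    v, c = _parse_value(cell)
                    conc[name] = None if v is None else 0.5 * (v[0] + v[1])
                    if c:
                        censored.add(name)
                # other columns (estimated depth, sampling codes, ...) pass through
            except TableFormatError as err:
                raise TableFormatError(f"site {site!r}, column {label!r}: {err}") from None
        if lat is None or lon is None:
            raise TableFormatError(f"site {site!r}: missing coordinates")
        records.append(
            SiteMetadata(
                site=str(site), latitude=lat, longitude=lon, elevation=elev,
                temperature=temp, ph=ph, tds=tds, depth=depth,
                concentrations=conc, censored=censored,
            )
        )
    return records


def metadata_frame(records: Sequence[SiteMetadata]) -> pd.DataFrame:
    """Flatten metadata into a numeric sites × variables frame.

    Ranges collapse to midpoints; missing values become NaN.  This is the
    form consumed by environmental scaling / bioenv.
    """
    rows = {}
    for r in records:
        row: dict[str, float] = {
            "latitude": r.latitude,
            "longitude": r.longitude,
            "elevation": np.nan if r.elevation is None else r.elevation,
            "temperature": np.nan if r.temperature_mid is None else r.temperature_mid,
            "pH": np.nan if r.ph_mid is None else r.ph_mid,
            "TDS": np.nan if r.tds is None else r.tds,
            "depth": np.nan if r.depth is None else r.depth,
        }
        for name, value in r.concentrations.items():
            row[name] = np.nan if value is None else value
        rows[r.site] = row
    return pd.DataFrame.from_dict(rows, orient="index")


# --- normalisation -----------------------------------------------------------

def _iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    # stream for iteration i is a deterministic function of (seed, i)
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(iteration))))


def _subsample_counts(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``depth`` reads without replacement from a count vector."""
    return rng.multivariate_hypergeometric(counts, depth)


def mean_relative_abundance(
    table: CommunityTable,
    fraction: float = 0.85,
    iterations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Subsampled mean relative abundance.

    Every iteration subsamples every site, without replacement, to a common
    depth of ``floor(fraction × min_j N_j)`` and converts to proportions; the
    result is the per-cell mean over iterations, so each row sums to one.
    This smooths out unequal sequencing depth before cross-site comparison.
    """
    totals = table.totals.to_numpy()
    if (totals <= 0).any():
        raise ValueError("all sites must have at least one read")
    depth = int(np.floor(fraction * totals.min()))
    if depth < 1:
        raise ValueError(f"subsample depth is zero (fraction={fraction}, min N={totals.min()})")
    counts = table.counts.to_numpy()
    acc = np.zeros(counts.shape, dtype=float)
    for i in range(iterations):
        rng = _iteration_rng(seed, i)
        for j in range(counts.shape[0]):
            acc[j] += _subsample_counts(counts[j], depth, rng)
    mean = acc / (iterations * depth)
    return pd.DataFrame(mean, index=table.counts.index, columns=table.counts.columns)


def rarefy(table: CommunityTable, depth: int, seed: int = 0) -> CommunityTable:
    """Subsample every site without replacement to exactly ``depth`` reads."""
    totals = table.totals
    too_small = totals.index[totals < depth]
    if len(too_small):
        raise ValueError(f"depth {depth} exceeds reads at sites: {list(too_small)}")
    rng = _iteration_rng(seed, 0)
    counts = table.counts.to_numpy()
    out = np.vstack([_subsample_counts(counts[j], depth, rng) for j in range(counts.shape[0])])
    return CommunityTable(
        pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns),
        taxonomy=table.taxonomy,
    )


def aggregate_rank(
    table: CommunityTable, rank: str, split_proteobacteria: bool = False
) -> CommunityTable:
    """Sum counts within groups at the requested taxonomic rank.

    With ``split_proteobacteria`` set, taxa whose phylum is Proteobacteria
    are grouped by their class instead (the convention used when that phylum
    dominates and phylum-level bars would hide its internal structure).
    """
    if table.taxonomy is None:
        raise ValueError("table has no taxonomy; cannot aggregate by rank")
    if rank not in table.taxonomy.columns:
        raise ValueError(f"rank {rank!r} not present in taxonomy")
    labels = table.taxonomy.loc[table.counts.columns, rank]
    missing = [str(t) for t, v in labels.items() if pd.isna(v)]
    if missing:
        raise ValueError(f"taxa missing {rank!r} labels: {missing}")
    labels = labels.astype(str).copy()
    if split_proteobacteria:
        if rank != "phylum":
            raise ValueError("split_proteobacteria only applies at phylum rank")
        if "class" not in table.taxonomy.columns:
            raise ValueError("taxonomy lacks class labels needed to split Proteobacteria")
        is_proteo = labels == "Proteobacteria"
        cls = table.taxonomy.loc[table.counts.columns, "class"].astype(str)
        bad = [str(t) for t in labels.index[is_proteo & cls.isin(["nan", "None", ""])]]
        if bad:
            raise ValueError(f"Proteobacteria taxa missing class labels: {bad}")
        labels[is_proteo] = cls[is_proteo]
    grouped = table.counts.T.groupby(labels, sort=False).sum().T
    return CommunityTable(grouped)
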
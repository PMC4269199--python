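"""Sequence-level procedures for amplicon data: dereplication, gap-aware
pairwise distances, abundance-greedy preclustering, average-linkage OTU
clustering, the cross-site shared-OTU procedure, exhaustive k-mismatch read
mapping, and contaminant-genus screening.

Distance semantics follow the "eachgap / countend=F" convention: terminal
gap runs (alignment overhangs) are ignored, a gap aligned to a base counts
as one difference, and columns where both sequences have gaps are excluded
from numerator and denominator alike.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from ._cluster import agglomerate
from .tables_io import CommunityTable

__all__ = [
    "SequenceRecord",
    "AlignedSequenceSet",
    "OTUSet",
    "MappingHit",
    "SharedOtu",
    "read_fasta",
    "write_fasta",
    "dereplicate",
    "pairwise_distance",
    "distance_matrix",
    "precluster",
    "cluster_otus",
    "shared_otus",
    "kmismatch_map",
    "contaminant_screen",
    "reverse_complement",
]

_VALID = set("ACGTN-")


@dataclass(frozen=True)
class SequenceRecord:
    """A (possibly aligned) DNA sequence with a read abundance."""

    id: str
    seq: str
    abundance: int = 1

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.seq.upper()) - _VALID
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")
        if self.abundance < 1:
            raise ValueError(f"{self.id}: abundance must be >= 1")
        object.__setattr__(self, "seq", self.seq.upper())


@dataclass
class AlignedSequenceSet:
    """Equal-length sequence records (an alignment slab)."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty sequence set")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal alignment lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    @property
    def total_abundance(self) -> int:
        return sum(r.abundance for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


# --- FASTA with ;size= abundance annotations --------------------------------

_SIZE_RE = re.compile(r";size=(\d+);?$")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA; a trailing ``;size=N`` in the header becomes the abundance."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _SIZE_RE.search(rec.id)
        size = int(m.group(1)) if m else 1
        rid = _SIZE_RE.sub("", rec.id)
        records.append(SequenceRecord(id=rid, seq=str(rec.seq), abundance=size))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        BioSeqRecord(Seq(r.seq), id=f"{r.id};size={r.abundance}", description="")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# --- dereplication -----------------------------------------------------------

def dereplicate(records: Sequence[SequenceRecord], mode: str = "prefix") -> list[SequenceRecord]:
    """Merge duplicate (or prefix-duplicate) sequences, summing abundances.

    ``full`` merges exact string duplicates only; ``prefix`` additionally
    folds any sequence that is an exact prefix of a longer retained one into
    that record.  Candidates are processed longest first (ties: more
    abundant, then id) and merge into the earliest retained match; output is
    sorted by descending abundance (ties by id).
    """
    if mode not in ("full", "prefix"):
        raise ValueError(f"unknown mode {mode!r}")
    order = sorted(records, key=lambda r: (-len(r.seq), -r.abundance, r.id))
    retained: list[SequenceRecord] = []
    for rec in order:
        target_idx = None
        for k, kept in enumerate(retained):
            if (mode == "full" and kept.seq == rec.seq) or (
                mode == "prefix" and kept.seq.startswith(rec.seq)
            ):
                target_idx = k
                break
        if target_idx is None:
            retained.append(rec)
        else:
            kept = retained[target_idx]
            retained[target_idx] = SequenceRecord(
                id=kept.id, seq=kept.seq, abundance=kept.abundance + rec.abundance
            )
    return sorted(retained, key=lambda r: (-r.abundance, r.id))


# --- aligned distances -------------------------------------------------------

def _nongap_span(seq: str) -> tuple[int, int]:
    n = len(seq)
    start = 0
    while start < n and seq[start] == "-":
        start += 1
    end = n
    while end > start and seq[end - 1] == "-":
        end -= 1
    return start, end


def _diff_columns(s1: str, s2: str) -> tuple[int, int]:
    """(mismatching columns, compared columns) under eachgap/countend=F."""
    if len(s1) != len(s2):
        raise ValueError("aligned sequences must have equal length")
    a1, b1 = _nongap_span(s1)
    a2, b2 = _nongap_span(s2)
    start, end = max(a1, a2), min(b1, b2)
    mism = compared = 0
    for k in range(start, end):
        c1, c2 = s1[k], s2[k]
        if c1 == "-" and c2 == "-":
            continue
        compared += 1
        if c1 != c2:
            mism += 1
    return mism, compared


def pairwise_distance(s1: str, s2: str) -> float:
    """Fractional distance between two aligned sequences.

    Terminal gap runs in either sequence are excluded from the comparable
    span; within it, any differing column (including gap vs base) counts 1
    and gap-vs-gap columns are skipped.  Distance = mismatches / compared.
    """
    mism, compared = _diff_columns(s1, s2)
    if compared == 0:
        raise ValueError("no comparable columns between sequences")
    return mism / compared


def distance_matrix(aligned: AlignedSequenceSet) -> np.ndarray:
    n = len(aligned)
    d = np.zeros((n, n), dtype=float)
    seqs = [r.seq for r in aligned]
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(seqs[i], seqs[j])
    return d


# --- preclustering and OTUs --------------------------------------------------

def precluster(records: Sequence[SequenceRecord], max_diffs: int = 2) -> list[SequenceRecord]:
    """Greedy abundance-ordered merging of near-identical aligned sequences.

    Records are processed in descending abundance (ties by id); each merges
    into the first already-retained record within ``max_diffs`` mismatching
    columns, adding its abundance, otherwise it is retained.  This is the
    "pseudo-single-linkage" denoising pass: greedy, not true single linkage,
    so a chain A–B–C can leave C unmerged even though C is within reach of B.
    """
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise ValueError("precluster requires aligned, equal-length records")
    order = sorted(records, key=lambda r: (-r.abundance, r.id))
    retained: list[SequenceRecord] = []
    for rec in order:
        target_idx = None
        for k, kept in enumerate(retained):
            mism, compared = _diff_columns(kept.seq, rec.seq)
            if compared > 0 and mism <= max_diffs:
                target_idx = k
                break
        if target_idx is None:
            retained.append(rec)
        else:
            kept = retained[target_idx]
            retained[target_idx] = SequenceRecord(
                id=kept.id, seq=kept.seq, abundance=kept.abundance + rec.abundance
            )
    return retained


@dataclass
class OTUSet:
    """Partition of sequence ids into OTUs at a distance threshold.

    ``clusters`` lists member ids per OTU; each OTU's representative is its
    most abundant member (ties by lexicographic id).
    """

    clusters: list[list[str]]
    representatives: list[str]
    threshold: float
    abundances: dict[str, int] = field(default_factory=dict)

    @property
    def n_otus(self) -> int:
        return len(self.clusters)


def cluster_otus(aligned: AlignedSequenceSet, threshold: float = 0.03) -> OTUSet:
    """Average-linkage agglomerative OTU clustering cut at ``threshold``.

    The usual 0.03 cut approximates 97% sequence identity; merges with
    height ≤ threshold define the OTUs.
    """
    records = aligned.records
    if len(records) == 1:
        only = records[0]
        return OTUSet([[only.id]], [only.id], threshold, {only.id: only.abundance})
    d = distance_matrix(aligned)
    dend = agglomerate(d, labels=[r.id for r in records], linkage="average")
    clusters = dend.cut(threshold)
    by_id = {r.id: r for r in records}
    reps = [
        min(members, key=lambda rid: (-by_id[rid].abundance, rid))
        for members in clusters
    ]
    return OTUSet(clusters, reps, threshold, {r.id: r.abundance for r in records})


@dataclass(frozen=True)
class SharedOtu:
    """One cross-site cluster of OTU representatives."""

    members: tuple[tuple[str, str], ...]  # (site, representative id)
    sites: frozenset[str]


def shared_otus(
    site_otus: Mapping[str, OTUSet],
    site_records: Mapping[str, Sequence[SequenceRecord]],
    final_threshold: float = 0.0049,
) -> list[SharedOtu]:
    """Cross-site OTU sharing via representative reclustering.

    Procedure: each site's OTUs are reduced to their most abundant
    representative sequence; representatives are pooled across sites,
    dereplicated (identical sequences collapse, provenance retained),
    clustered at the tight ``final_threshold``, and every resulting cluster
    is mapped to the set of sites it draws members from.  Representatives
    must share a common alignment (equal lengths).
    """
    pooled: list[tuple[str, str, str, int]] = []  # (site, rep id, seq, abundance)
    for site, otus in site_otus.items():
        by_id = {r.id: r for r in site_records[site]}
        for rep in otus.representatives:
            rec = by_id[rep]
            pooled.append((site, rep, rec.seq, rec.abundance))
    if not pooled:
        return []
    lengths = {len(seq) for _, _, seq, _ in pooled}
    if len(lengths) > 1:
        raise ValueError(
            f"representatives have unequal lengths {sorted(lengths)}; "
            "a shared alignment is a precondition"
        )
    # dereplicate identical representatives, keeping contributor provenance
    groups: dict[str, list[tuple[str, str, int]]] = {}
    for site, rep, seq, ab in pooled:
        groups.setdefault(seq, []).append((site, rep, ab))
    unique_seqs = list(groups)
    if len(unique_seqs) == 1:
        idx_clusters = [[0]]
    else:
        n = len(unique_seqs)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pairwise_distance(unique_seqs[i], unique_seqs[j])
        dend = agglomerate(d, labels=[str(i) for i in range(n)], linkage="average")
        idx_clusters = [[int(x) for x in c] for c in dend.cut(final_threshold)]
    out = []
    for members in idx_clusters:
        pairs = []
        for idx in members:
            pairs.extend((site, rep) for site, rep, _ab in groups[unique_seqs[idx]])
        pairs.sort()
        out.append(SharedOtu(members=tuple(pairs), sites=frozenset(s for s, _ in pairs)))
    return out


# --- read mapping ------------------------------------------------------------

@dataclass(frozen=True)
class MappingHit:
    query_id: str
    reference_id: str
    offset: int  # 0-based start in the reference
    mismatches: int
    strand: str  # '+' forward query, '-' reverse complement


def kmismatch_map(
    queries: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    max_mismatches: int = 0,
    both_strands: bool = True,
) -> list[MappingHit]:
    """Exhaustive ungapped mapping of short queries onto references.

    Every (query, reference, offset, strand) placement with Hamming
    mismatches ≤ ``max_mismatches`` is reported — the brute-force equivalent
    of an end-to-end 0/2-mismatch short-read aligner, adequate at amplicon
    scale and exact by construction.
    """
    hits: list[MappingHit] = []
    for q in queries:
        variants = [(q.seq, "+")]
        if both_strands:
            variants.append((reverse_complement(q.seq), "-"))
        qlen = len(q.seq)
        for ref in references:
            rseq = ref.seq
            for offset in range(0, len(rseq) - qlen + 1):
                window = rseq[offset : offset + qlen]
                for qseq, strand in variants:
                    mism = sum(1 for a, b in zip(qseq, window) if a != b)
                    if mism <= max_mismatches:
                        hits.append(
                            MappingHit(q.id, ref.id, offset, mism, strand)
                        )
    return hits


# --- contaminant screening ---------------------------------------------------

def contaminant_screen(
    table: CommunityTable, contaminant_genera: Sequence[str]
) -> pd.DataFrame:
    """Per-site summary of listed contaminant genera.

    Returns, for each site, how many of the listed genera were observed and
    the summed relative abundance of reads assigned to them.
    """
    listed = [g for g in contaminant_genera if g in table.taxa]
    rel = table.relative_abundance()
    present = table.counts[listed] > 0 if listed else pd.DataFrame(index=table.counts.index)
    out = pd.DataFrame(index=table.counts.index)
    out["contaminant_genera_observed"] = present.sum(axis=1).astype(int) if listed else 0
    out["contaminant_relative_abundance"] = rel[listed].sum(axis=1) if listed else 0.0
    return out
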
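"""Oligotyping: entropy-guided decomposition of highly similar sequence
groups (an OTU or a genus bin) into sub-populations.

Per-column Shannon entropy over an abundance-weighted alignment locates the
information-rich positions; reads are then keyed by their residues at those
component positions, and low-abundance keys — overwhelmingly sequencing/PCR
noise — are removed by a minimum substantive abundance floor M.  Random
sequencing error produces column entropies near or below 0.2 bits, which is
the default component-selection cutoff.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq_ops import AlignedSequenceSet

__all__ = [
    "EntropyProfile",
    "OligotypeSet",
    "entropy_profile",
    "select_components",
    "decompose",
]

#: the gap counts as a fifth symbol by default: indel columns carry signal
SYMBOLS = ("A", "C", "G", "T", "-", "N")


@dataclass(frozen=True)
class EntropyProfile:
    """Per-column Shannon entropy (bits) of an aligned, abundance-weighted set."""

    entropy: np.ndarray

    def __len__(self) -> int:
        return len(self.entropy)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": np.arange(len(self.entropy)), "entropy_bits": self.entropy})


@dataclass(frozen=True)
class OligotypeSet:
    """Decomposition result.

    ``oligotypes`` maps the residue string over the component positions to
    its total abundance, descending; ``filtered`` holds the keys removed by
    the abundance floor ``m``.  Retained + filtered abundances always equal
    the input total.
    """

    components: tuple[int, ...]
    oligotypes: tuple[tuple[str, int], ...]
    filtered: tuple[tuple[str, int], ...]
    m: int

    @property
    def total_abundance(self) -> int:
        return sum(a for _, a in self.oligotypes) + sum(a for _, a in self.filtered)


def entropy_profile(aligned: AlignedSequenceSet, include_gaps: bool = True) -> EntropyProfile:
    """Shannon entropy (bits) of each alignment column.

    Symbol frequencies are weighted by read abundance; with
    ``include_gaps=False`` gap characters are dropped from a column's
    distribution instead of counting as a symbol.
    """
    length = aligned.length
    ent = np.zeros(length, dtype=float)
    for pos in range(length):
        weights: Counter[str] = Counter()
        for rec in aligned:
            sym = rec.seq[pos]
            if not include_gaps and sym == "-":
                continue
            weights[sym] += rec.abundance
        total = sum(weights.values())
        if total == 0:
            continue
        p = np.array([w / total for w in weights.values()])
        ent[pos] = float(-(p * np.log2(p)).sum())
    return EntropyProfile(entropy=ent)


def select_components(
    profile: EntropyProfile,
    mode: str = "threshold",
    entropy_cutoff: float = 0.2,
    c: int | None = None,
) -> list[int]:
    """Choose the alignment positions to decompose on.

    ``threshold`` mode returns every position with entropy strictly above
    the cutoff (0.2 bits, the random-error noise floor); ``top_c`` returns
    the ``c`` highest-entropy positions, ties resolved toward the lower
    index.  Either way positions come back in ascending order.
    """
    ent = profile.entropy
    if mode == "threshold":
        return [int(i) for i in np.nonzero(ent > entropy_cutoff)[0]]
    if mode == "top_c":
        if c is None:
            raise ValueError("top_c mode requires c")
        if c > len(ent):
            raise ValueError(f"c={c} exceeds alignment length {len(ent)}")
        order = sorted(range(len(ent)), key=lambda i: (-ent[i], i))
        return sorted(order[:c])
    raise ValueError(f"unknown mode {mode!r}")


def decompose(
    aligned: AlignedSequenceSet, components: list[int], m: int = 20
) -> OligotypeSet:
    """Aggregate reads by their residues at the component positions.

    Keys with total abundance below the minimum substantive abundance ``m``
    are moved to the filtered bin rather than discarded, so abundance is
    conserved and the noise load is inspectable.
    """
    if not components:
        raise ValueError("no component positions given")
    length = aligned.length
    bad = [p for p in components if not 0 <= p < length]
    if bad:
        raise ValueError(f"component positions outside alignment: {bad}")
    totals: Counter[str] = Counter()
    for rec in aligned:
        key = "".join(rec.seq[p] for p in components)
        totals[key] += rec.abundance
    retained = sorted(
        ((k, a) for k, a in totals.items() if a >= m), key=lambda t: (-t[1], t[0])
    )
    filtered = sorted(
        ((k, a) for k, a in totals.items() if a < m), key=lambda t: (-t[1], t[0])
    )
    return OligotypeSet(
        components=tuple(components), oligotypes=tuple(retained),
        filtered=tuple(filtered), m=m,
    )
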
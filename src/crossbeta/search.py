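"""Exact subsequence search of boundary k-mers in sequence collections.

Models the "search the whole PDB for this 5-mer" step: the collection is any
iterable of (source id, chain id, sequence) triples, typically read from a
FASTA file such as a PDB-wide seqres dump.  Matching is exact and
case-insensitive, overlapping occurrences all count, and an 'X' in the
target never matches anything.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = ["SequenceHit", "search_kmer", "batch_report", "read_fasta"]


@dataclass(frozen=True)
class SequenceHit:
    """One exact occurrence of a k-mer in a target sequence."""

    kmer: str
    source_id: str
    chain_id: str
    position: int  # 1-based start offset
    context: str  # up to 11 characters centered on the match


Collection = Iterable[tuple[str, str, str]]


def search_kmer(kmer: str, collection: Collection) -> list[SequenceHit]:
    """Every exact, possibly overlapping occurrence of ``kmer``.

    Hits are sorted by (source_id, chain_id, position).
    """
    if not kmer:
        raise ValueError("k-mer must be non-empty")
    needle = kmer.upper()
    if not needle.isalpha():
        raise ValueError(f"k-mer must be amino-acid letters, got {kmer!r}")
    hits: list[SequenceHit] = []
    for source_id, chain_id, sequence in collection:
        seq = sequence.upper()
        start = seq.find(needle)
        while start != -1:
            window = seq[start:start + len(needle)]
            if "X" not in window:
                lo = max(0, start - 3)
                hi = min(len(seq), start + len(needle) + 3)
                hits.append(SequenceHit(
                    kmer=needle,
                    source_id=source_id,
                    chain_id=chain_id,
                    position=start + 1,
                    context=seq[lo:hi],
                ))
            start = seq.find(needle, start + 1)
    hits.sort(key=lambda h: (h.source_id, h.chain_id, h.position))
    return hits


def batch_report(kmers: list[str], collection: Collection):
    """One summary row per k-mer: hit count, source count, source list.

    Row order follows the (de-duplicated) input k-mer order, which makes the
    report deterministic for a fixed query list.
    """
    import pandas as pd

    records = list(collection)
    rows = []
    seen: set[str] = set()
    for kmer in kmers:
        needle = kmer.upper()
        if needle in seen:
            continue
        seen.add(needle)
        hits = search_kmer(needle, records)
        sources = sorted({h.source_id for h in hits})
        rows.append({"kmer": needle, "n_hits": len(hits),
                     "n_sources": len(sources),
                     "sources": ",".join(sources)})
    return pd.DataFrame(rows, columns=["kmer", "n_hits", "n_sources",
                                       "sources"])


def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a FASTA file into (source_id, chain_id, sequence) triples.

    Headers shaped like PDB seqres ids (``1abc_A``) are split into entry and
    chain; any other header becomes the source id with a blank chain.
    """
    from Bio import SeqIO

    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        source, chain = name, ""
        if "_" in name:
            head, _, tail = name.partition("_")
            if len(head) == 4 and tail and len(tail) <= 2:
                source, chain = head, tail
        out.append((source, chain, str(record.seq)))
    return out
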
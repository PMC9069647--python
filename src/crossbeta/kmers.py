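"""Boundary 5-mers of detected parallel segments and their tallies.

The boundary prefix of a detected segment is the XXYYY 5-mer formed by the
two residues immediately N-terminal to the segment (XX, not part of the
sheet) followed by the segment's first three residues (YYY).  The suffix is
the mirror construct at the C-terminal boundary.  Counts are raw
multiplicities -- every occurrence across entries, models and chains counts
once, with no homology correction -- partitioned by experimental method
class (NMR vs X-ray).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

from .geometry import ParallelSegmentPair
from .structure_io import ChainModel, StructureModel

PREFIX = "prefix"
SUFFIX = "suffix"

__all__ = [
    "PREFIX",
    "SUFFIX",
    "BoundaryKmer",
    "KmerCountRow",
    "KmerCountTable",
    "extract_boundary_kmer",
    "collect_kmers",
    "tally_kmers",
    "top_k",
]


@dataclass(frozen=True)
class BoundaryKmer:
    """A length-5 boundary k-mer with full provenance."""

    kmer: str
    side: str
    entry_id: str
    model_index: int
    chain_id: str
    flank_positions: tuple[int, int]
    core_positions: tuple[int, int, int]
    segment_ref: str

    def __post_init__(self) -> None:
        if len(self.kmer) != 5:
            raise ValueError("boundary k-mers have length 5")
        if self.side not in (PREFIX, SUFFIX):
            raise ValueError(f"side must be prefix or suffix, got {self.side!r}")


def _adjacent(chain: ChainModel, i: int, j: int) -> bool:
    """True when residues i and j (= i+1 in list order) are sequence-adjacent.

    Adjacency is an author-numbering notion (gap of at most one, insertion
    codes allowed): the boundary prefix is a sequence construct, so the
    geometric break heuristic used for segment eligibility does not apply.
    """
    a, b = chain.residues[i], chain.residues[j]
    return 0 <= b.author_seq_number - a.author_seq_number <= 1


def extract_boundary_kmer(
    pair: ParallelSegmentPair,
    which_chain: str,
    side: str,
    chain: ChainModel,
) -> BoundaryKmer | None:
    """Boundary 5-mer of one chain of a detected pair, or ``None``.

    Returns ``None`` when fewer than two flanking residues exist, when the
    five residues are not sequence-contiguous, or when any of the five
    letters is 'X' (non-standard residue).
    """
    if which_chain not in ("a", "b"):
        raise ValueError("which_chain must be 'a' or 'b'")
    if side not in (PREFIX, SUFFIX):
        raise ValueError("side must be prefix or suffix")
    start = pair.start_a if which_chain == "a" else pair.start_b
    if side == PREFIX:
        idx = [start - 2, start - 1, start, start + 1, start + 2]
    else:
        end = start + pair.length - 1
        idx = [end - 2, end - 1, end, end + 1, end + 2]
    if idx[0] < 0 or idx[-1] >= chain.n_residues:
        return None
    for a, b in zip(idx, idx[1:]):
        if not _adjacent(chain, a, b):
            return None
    letters = "".join(chain.residues[i].one_letter for i in idx)
    if "X" in letters:
        return None
    positions = tuple(chain.residues[i].author_seq_number for i in idx)
    if side == PREFIX:
        flank, core = positions[:2], positions[2:]
    else:
        flank, core = positions[3:], positions[:3]
    return BoundaryKmer(
        kmer=letters,
        side=side,
        entry_id=pair.entry_id,
        model_index=pair.model_index,
        chain_id=chain.chain_id,
        flank_positions=flank,
        core_positions=core,
        segment_ref=(f"{pair.entry_id}:{pair.model_index}:"
                     f"{pair.chain_a}{pair.resnum_range_a[0]}-{pair.resnum_range_a[1]}/"
                     f"{pair.chain_b}{pair.resnum_range_b[0]}-{pair.resnum_range_b[1]}"),
    )


def collect_kmers(
    structure: StructureModel,
    pairs: Iterable[ParallelSegmentPair],
    sides: tuple[str, ...] = (PREFIX, SUFFIX),
    dedupe: bool = True,
) -> list[BoundaryKmer]:
    """Boundary k-mers of all detected pairs of one structure.

    Both chains of every pair contribute (in a homodimeric fibril the same
    5-mer therefore counts once per chain).  With ``dedupe`` (default) a
    boundary site that several overlapping pairs share -- same entry, model,
    chain, boundary residue and side -- is emitted once: occurrences are
    per segment boundary, not per reported pairing.
    """
    seen: set[tuple] = set()
    out: list[BoundaryKmer] = []
    for pair in pairs:
        for which in ("a", "b"):
            chain_id = pair.chain_a if which == "a" else pair.chain_b
            chain = structure.get_chain(pair.model_index, chain_id)
            for side in sides:
                kmer = extract_boundary_kmer(pair, which, side, chain)
                if kmer is None:
                    continue
                key = (kmer.entry_id, kmer.model_index, kmer.chain_id,
                       kmer.core_positions, kmer.side)
                if dedupe and key in seen:
                    continue
                seen.add(key)
                out.append(kmer)
    return out


@dataclass(frozen=True)
class KmerCountRow:
    kmer: str
    side: str
    method_class: str
    count: int
    entries: tuple[str, ...]


@dataclass
class KmerCountTable:
    """Raw multiplicity tallies of boundary k-mers by method class.

    Rows are sorted by descending count, ties broken lexicographically by
    k-mer; ``entries`` lists the sorted unique entry ids contributing.
    """

    rows: list[KmerCountRow] = field(default_factory=list)

    def filter(self, side: str | None = None,
               method_class: str | None = None) -> "KmerCountTable":
        rows = [r for r in self.rows
                if (side is None or r.side == side)
                and (method_class is None or r.method_class == method_class)]
        return KmerCountTable(rows)

    @property
    def total_count(self) -> int:
        return sum(r.count for r in self.rows)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{"kmer": r.kmer, "count": r.count,
              "entries": ",".join(r.entries),
              "side": r.side, "method_class": r.method_class}
             for r in self.rows],
            columns=["kmer", "count", "entries", "side", "method_class"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def get(self, kmer: str, side: str = PREFIX,
            method_class: str | None = None) -> KmerCountRow | None:
        for r in self.rows:
            if (r.kmer == kmer and r.side == side
                    and (method_class is None or r.method_class == method_class)):
                return r
        return None


def tally_kmers(
    kmers: Iterable[BoundaryKmer],
    method_class_lookup: Mapping[str, str] | Callable[[str], str],
) -> KmerCountTable:
    """Group boundary k-mers by (kmer, side, method class) with raw counts.

    ``method_class_lookup`` maps an entry id to its method class (a mapping
    or a callable).  Multiplicities are preserved: the count of a row equals
    the number of input records falling into it.
    """
    if callable(method_class_lookup):
        lookup = method_class_lookup
    else:
        lookup = method_class_lookup.__getitem__
    groups: dict[tuple[str, str, str], list[BoundaryKmer]] = {}
    for k in kmers:
        method = lookup(k.entry_id)
        groups.setdefault((k.kmer, k.side, method), []).append(k)
    rows = [
        KmerCountRow(kmer=kmer, side=side, method_class=method,
                     count=len(members),
                     entries=tuple(sorted({m.entry_id for m in members})))
        for (kmer, side, method), members in groups.items()
    ]
    rows.sort(key=lambda r: (-r.count, r.kmer, r.side, r.method_class))
    return KmerCountTable(rows)


def top_k(table: KmerCountTable, side: str, method_class: str,
          k: int) -> list[KmerCountRow]:
    """First k rows of the filtered count-descending table.

    Ties are broken lexicographically by k-mer; asking for more rows than
    exist returns them all.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return table.filter(side=side, method_class=method_class).rows[:k]
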
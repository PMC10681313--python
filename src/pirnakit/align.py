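"""Hamming-distance short-read alignment at desk scale.

Reads are mapped to both strands of every reference sequence allowing at
most one substitution over the whole read (no indels), the simplest
faithful reading of "one base mismatch allowed". The production path is a
pigeonhole seed index — any alignment with at most one mismatch has at
least one error-free read half, so exact lookup of the two halves finds
every candidate placement — verified base-by-base. A vectorized
sliding-window scan (`brute_force_align`) serves as the independent oracle
in the test suite.

Coordinates are 0-based, half-open, always on the plus strand of the
reference. A minus-strand hit means the read equals the reverse complement
of ``reference[start:end)``; its biological 5' end sits at plus-strand
position ``end - 1``.

N in either the read or the reference counts as a mismatch at that
position, even against another N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import ReferenceCatalog
from .errors import ConfigurationError
from .simulate import revcomp


@dataclass(frozen=True)
class AlignmentHit:
    """One placement of a read on a reference."""

    query_sequence: str
    ref_name: str
    category_name: str
    start: int  # 0-based inclusive, plus strand
    end: int  # exclusive; end - start == read length
    strand: str  # "+" or "-"
    mismatches: int


def five_prime_position(hit: AlignmentHit) -> int:
    """Plus-strand coordinate of the read's biological 5' end."""
    return hit.start if hit.strand == "+" else hit.end - 1


def _mismatches(query: str, ref: str, start: int, limit: int) -> int:
    """Hamming distance with early exit past ``limit``; N never matches."""
    mm = 0
    for a, b in zip(query, ref[start : start + len(query)]):
        if a != b or a == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


class SeedIndex:
    """Exact-match lookup over reference k-mers for pigeonhole alignment.

    Tables are built lazily per seed length (read halves of 24-32 nt reads
    span a handful of lengths), each mapping a k-mer to every plus-strand
    position where it occurs.
    """

    def __init__(self, catalog: ReferenceCatalog):
        self.catalog = catalog
        self._refs = list(catalog.iter_refs())
        if not self._refs:
            raise ConfigurationError(["catalog contains no sequences"])
        self._tables: dict[int, dict[str, list[tuple[int, int]]]] = {}

    def _table(self, k: int) -> dict:
        table = self._tables.get(k)
        if table is None:
            table = {}
            for ri, (_, _, seq) in enumerate(self._refs):
                for pos in range(len(seq) - k + 1):
                    table.setdefault(seq[pos : pos + k], []).append((ri, pos))
            self._tables[k] = table
        return table

    def align(self, sequence: str, max_mm: int = 1) -> list[AlignmentHit]:
        """All hits of ``sequence`` with at most ``max_mm`` mismatches.

        Hits are deduplicated and ordered by (category priority, reference
        name, start, strand).
        """
        length = len(sequence)
        if length < 2:
            raise ConfigurationError(
                ["reads must be at least 2 nt for pigeonhole alignment"]
            )
        if max_mm not in (0, 1):
            raise ConfigurationError(["max_mm must be 0 or 1"])
        hits = {}
        seen = set()
        for strand, query in (("+", sequence), ("-", revcomp(sequence))):
            half = length // 2
            for offset, seed in ((0, query[:half]), (half, query[half:])):
                table = self._table(len(seed))
                for ri, pos in table.get(seed, ()):
                    start = pos - offset
                    key = (ri, start, strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    cat, name, ref = self._refs[ri]
                    if start < 0 or start + length > len(ref):
                        continue
                    mm = _mismatches(query, ref, start, max_mm)
                    if mm <= max_mm:
                        hits[key] = AlignmentHit(
                            sequence, name, cat, start, start + length, strand, mm
                        )
        return sorted(
            hits.values(),
            key=lambda h: (
                self.catalog.priority(h.category_name),
                h.ref_name,
                h.start,
                h.strand,
            ),
        )


def build_index(catalog: ReferenceCatalog) -> SeedIndex:
    """Build the pigeonhole seed index over a catalog."""
    return SeedIndex(catalog)


def align(read, index: SeedIndex, max_mm: int = 1) -> list[AlignmentHit]:
    """Align a read (CollapsedRead, SmallRNARead or plain string)."""
    sequence = getattr(read, "sequence", read)
    return index.align(sequence, max_mm)


def brute_force_align(
    read, catalog: ReferenceCatalog, max_mm: int = 1
) -> list[AlignmentHit]:
    """Sliding-window Hamming scan of every reference, both strands.

    Independent verification oracle for `SeedIndex.align`; vectorized with
    numpy but algorithmically exhaustive. A read longer than a reference
    yields no hits on it; ``max_mm=0`` reduces to exact substring search.
    """
    sequence = getattr(read, "sequence", read)
    length = len(sequence)
    n_byte = ord("N")
    hits = []
    for cat, name, ref in catalog.iter_refs():
        if length > len(ref):
            continue
        ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(ref_arr, length)
        ref_is_n = windows == n_byte
        for strand, query in (("+", sequence), ("-", revcomp(sequence))):
            q = np.frombuffer(query.encode(), dtype=np.uint8)
            bad = (windows != q) | ref_is_n | (q == n_byte)
            mm = bad.sum(axis=1)
            for start in np.flatnonzero(mm <= max_mm):
                hits.append(
                    AlignmentHit(
                        sequence, name, cat, int(start), int(start) + length,
                        strand, int(mm[start]),
                    )
                )
    hits.sort(
        key=lambda h: (
            catalog.priority(h.category_name),
            h.ref_name,
            h.start,
            h.strand,
        )
    )
    return hits


def align_library(collapsed, index: SeedIndex, max_mm: int = 1):
    """Align every collapsed read; returns ``[(read, hits), ...]``."""
    return [(cr, index.align(cr.sequence, max_mm)) for cr in collapsed]


def hits_frame(read_hit_pairs) -> "pd.DataFrame":
    """Tabulate hits as a headered frame for TSV export."""
    import pandas as pd

    rows = []
    for read, hits in read_hit_pairs:
        for h in hits:
            rows.append(
                {
                    "query": h.query_sequence,
                    "category": h.category_name,
                    "ref": h.ref_name,
                    "start": h.start,
                    "end": h.end,
                    "strand": h.strand,
                    "mismatches": h.mismatches,
                    "count": getattr(read, "count", 1),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "query", "category", "ref", "start", "end", "strand",
            "mismatches", "count",
        ],
    )
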
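"""Read preprocessing: adapter clipping, length filtering, collapsing.

Small-RNA libraries sequence through the insert into the 3' adapter, so the
first step is to find the adapter occurrence in each read and keep only the
insert. Clipped reads are then filtered to the piRNA length window (closed
interval, default 24-32 nt) and collapsed into unique sequences with read
counts — the atomic unit for all downstream analyses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
import re

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError


@dataclass(frozen=True)
class SmallRNARead:
    """A single read: identifier plus DNA sequence over {A,C,G,T,N}."""

    read_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CollapsedRead:
    """A unique insert sequence with its read-count multiplicity."""

    sequence: str
    count: int


@dataclass
class PreprocessParams:
    """Clipping and filtering parameters.

    The adapter is searched as a prefix match against every read suffix;
    an occurrence needs at least ``min_overlap`` aligned bases and at most
    ``floor(max_adapter_mismatch_rate * overlap)`` mismatches. The length
    window is the closed interval [len_min, len_max], default 24-32 nt.
    """

    adapter: str
    min_overlap: int = 5
    max_adapter_mismatch_rate: float = 0.1
    keep_unclipped: bool = False
    len_min: int = 24
    len_max: int = 32

    def validate(self) -> None:
        errors = []
        if not self.adapter:
            errors.append("adapter must be non-empty")
        if self.min_overlap < 1:
            errors.append("min_overlap must be >= 1")
        if not 0 < self.len_min <= self.len_max:
            errors.append("length window requires 0 < len_min <= len_max")
        if not 0.0 <= self.max_adapter_mismatch_rate < 1.0:
            errors.append("max_adapter_mismatch_rate must be in [0, 1)")
        if errors:
            raise ConfigurationError(errors)


def clip_adapter(
    read: SmallRNARead, params: PreprocessParams
) -> SmallRNARead | None:
    """Truncate ``read`` at the leftmost qualifying adapter occurrence.

    Returns the insert (read prefix before the adapter), or None when the
    adapter is not found (unless ``keep_unclipped``) or the insert is empty.
    The leftmost qualifying start wins, which avoids keeping chimeric
    inserts that happen to contain adapter-like suffixes further right.
    """
    params.validate()
    seq = read.sequence
    n = len(seq)
    adapter = params.adapter
    m = len(adapter)
    for i in range(0, n - params.min_overlap + 1):
        overlap = min(m, n - i)
        allowed = int(params.max_adapter_mismatch_rate * overlap)
        mismatches = 0
        ok = True
        for a, b in zip(seq[i : i + overlap], adapter[:overlap]):
            if a != b:
                mismatches += 1
                if mismatches > allowed:
                    ok = False
                    break
        if ok:
            if i == 0:
                return None
            return SmallRNARead(read.read_id, seq[:i])
    return read if params.keep_unclipped else None


def filter_by_length(reads, len_min: int, len_max: int):
    """Retain exactly the reads whose length lies in [len_min, len_max]."""
    if not 0 < len_min <= len_max:
        raise ConfigurationError(["length window requires 0 < len_min <= len_max"])
    return [r for r in reads if len_min <= len(r.sequence) <= len_max]


def collapse(reads) -> list[CollapsedRead]:
    """Collapse reads to unique sequences with counts.

    Output is ordered lexicographically by sequence, so collapsing is
    deterministic regardless of input order; counts sum to the input size.
    """
    counts = Counter(r.sequence for r in reads)
    return [CollapsedRead(seq, counts[seq]) for seq in sorted(counts)]


@dataclass
class PreprocessResult:
    """Outcome of clip -> drop-N -> length-filter -> collapse."""

    clipped: list[SmallRNARead]
    retained: list[SmallRNARead]
    collapsed: list[CollapsedRead]
    stats: dict = field(default_factory=dict)


def preprocess_library(
    reads, params: PreprocessParams
) -> PreprocessResult:
    """Run the full preprocessing stage on a library.

    Inserts containing N are discarded after clipping (the one-mismatch
    aligner treats N as a mismatch everywhere, so they essentially never
    map; discarding them here is explicit and counted in the stats).
    """
    params.validate()
    reads = list(reads)
    clipped = []
    n_discarded_n = 0
    for read in reads:
        insert = clip_adapter(read, params)
        if insert is None:
            continue
        if "N" in insert.sequence:
            n_discarded_n += 1
            continue
        clipped.append(insert)
    retained = filter_by_length(clipped, params.len_min, params.len_max)
    collapsed = collapse(retained)
    stats = {
        "n_input": len(reads),
        "n_clipped": len(clipped),
        "n_discarded_with_N": n_discarded_n,
        "n_retained": len(retained),
        "n_unique": len(collapsed),
    }
    return PreprocessResult(clipped, retained, collapsed, stats)


# ----------------------------------------------------------------------- IO

_COLLAPSED_HEADER = re.compile(r"^(?P<name>.*)_x(?P<count>\d+)$")


def read_fastq(path) -> list[SmallRNARead]:
    """Read a 4-line FASTQ file (qualities are ignored downstream)."""
    return [
        SmallRNARead(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_collapsed_fasta(collapsed, path) -> None:
    """Write collapsed reads as FASTA with ``seq<i>_x<count>`` headers,
    the widely used collapsed-FASTA dialect (count after ``_x``)."""
    records = [
        SeqRecord(Seq(cr.sequence), id=f"seq{i + 1}_x{cr.count}", description="")
        for i, cr in enumerate(collapsed)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_collapsed_fasta(path) -> list[CollapsedRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        match = _COLLAPSED_HEADER.match(rec.id)
        if not match:
            raise ConfigurationError(
                [f"header {rec.id!r} is not in collapsed-FASTA form name_x<count>"]
            )
        out.append(CollapsedRead(str(rec.seq).upper(), int(match["count"])))
    return out


def counts_table(collapsed) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence": [cr.sequence for cr in collapsed],
            "length": [len(cr.sequence) for cr in collapsed],
            "count": [cr.count for cr in collapsed],
        }
    )
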
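"""Synthetic testis small-RNA library generator.

Emulates the statistical structure of mouse testis small-RNA libraries:
three read populations (miRNA-like 21-23 nt, MILI-piRNA-like 25-28 nt,
MIWI-piRNA-like 29-32 nt), a configurable 5'-U bias on primary piRNAs,
planted opposite-strand ping-pong pairs on a transposon-like element with a
fixed 5'-5' overlap and a 10A bias on responders, a 3' sequencing adapter
appended to every insert, and a per-base substitution error rate. Every
generation decision is recorded in a ground-truth table so downstream
stages can be tested by parameter recovery.

Sequences are stored in the DNA alphabet (T, not U), following FASTQ
convention; U appears only in reports. Reads are emitted as sequenced:
a minus-strand read is the reverse complement of the plus-strand reference
window it derives from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import CANONICAL_ORDER, ReferenceCatalog
from .errors import ConfigurationError

_BASES = "ACGT"
_RC = str.maketrans("ACGTN", "TGCAN")

#: Illumina small-RNA 3' adapter prefix; real libraries read through into it.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCT"

TRUTH_COLUMNS = [
    "read_id",
    "population",
    "source_category",
    "source_ref",
    "source_start",
    "strand",
    "insert_len",
    "insert_seq",
    "is_pingpong_responder",
    "partner_id",
]


def revcomp(seq: str) -> str:
    """Reverse complement in the DNA alphabet (N maps to N)."""
    return seq.translate(_RC)[::-1]


def _uniform_dist(lo: int, hi: int) -> dict[int, float]:
    n = hi - lo + 1
    return {length: 1.0 / n for length in range(lo, hi + 1)}


def default_ref_sizes() -> dict:
    """Sizes of the synthetic reference sets.

    Ten 2-kb piRNA clusters (rank-weighted during sampling, emulating the
    dominance of top pachytene loci), a handful of mRNA/ncRNA/repeat/intron
    sequences, and a 6-kb LINE1-like element (full-length mouse LINE1 is
    ~6-7 kb).
    """
    return {
        "piRNA_cluster": [2000] * 10,
        "coding_RNA": [1500] * 5,
        "noncoding_RNA": [600] * 5,
        "repeat": [800] * 3,
        "intron": [1200] * 5,
        "element": 6000,
    }


@dataclass
class SimConfig:
    """Parameters of a synthetic library.

    Fractions are probabilities in [0, 1]; length distributions map insert
    length (nt) to probability and must sum to 1. ``pingpong_fraction`` is
    the fraction of each piRNA population generated as minus-strand
    responders paired to a plus-strand initiator on the element at a 5'-5'
    overlap of exactly ``pingpong_offset`` nt. ``element_fraction`` is the
    fraction of non-responder piRNA reads drawn from the element (uniformly
    on both strands, giving the ping-pong profile a flat null); the rest
    come from piRNA clusters. ``u1_fraction`` sets the probability that a
    primary piRNA insert starts with U; ``a10_fraction`` the probability
    that position 10 of a responder is A.
    """

    seed: int = 1
    n_mirna: int = 2000
    n_mili: int = 8000
    n_miwi: int = 8000
    len_dist_mirna: dict = field(default_factory=lambda: _uniform_dist(21, 23))
    len_dist_mili: dict = field(default_factory=lambda: _uniform_dist(25, 28))
    len_dist_miwi: dict = field(default_factory=lambda: _uniform_dist(29, 32))
    u1_fraction: float = 0.8
    pingpong_fraction: float = 0.1
    pingpong_offset: int = 10
    a10_fraction: float = 0.7
    element_fraction: float = 0.15
    adapter: str = DEFAULT_ADAPTER
    error_rate: float = 0.001
    ref_sizes: dict = field(default_factory=default_ref_sizes)

    # ------------------------------------------------------------ validation

    def validate(self) -> None:
        errors = []
        for name in ("n_mirna", "n_mili", "n_miwi"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        for name in (
            "u1_fraction",
            "pingpong_fraction",
            "a10_fraction",
            "element_fraction",
            "error_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                errors.append(f"{name} must be in [0, 1], got {value}")
        if self.pingpong_offset < 1:
            errors.append("pingpong_offset must be >= 1")
        if not self.adapter:
            errors.append("adapter must be non-empty")
        elif set(self.adapter) - set(_BASES):
            errors.append("adapter must be over {A,C,G,T}")
        for name in ("len_dist_mirna", "len_dist_mili", "len_dist_miwi"):
            dist = getattr(self, name)
            if not dist:
                errors.append(f"{name} is empty")
                continue
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                errors.append(f"{name} probabilities must sum to 1")
            if any(length < 1 for length in dist):
                errors.append(f"{name} has a non-positive length")
        for cat, sizes in self.ref_sizes.items():
            if cat == "element":
                if sizes <= 0:
                    errors.append("element size must be positive")
                continue
            if cat not in CANONICAL_ORDER:
                errors.append(f"unknown reference category {cat!r}")
                continue
            if not sizes or any(s <= 0 for s in sizes):
                errors.append(f"ref_sizes[{cat!r}] must be positive lengths")
        if errors:
            raise ConfigurationError(errors)

    def max_pirna_length(self) -> int:
        lengths = list(self.len_dist_mili) + list(self.len_dist_miwi)
        return max(lengths) if lengths else 0


@dataclass(frozen=True)
class SimulatedRead:
    """One sequenced read: planted insert plus 3' adapter (plus errors)."""

    read_id: str
    sequence: str


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def build_reference_catalog(config: SimConfig) -> ReferenceCatalog:
    """Generate the synthetic reference catalog for ``config``.

    One random sequence set per annotation category, in canonical priority
    order, plus a LINE1-like element appended to the repeat category (and
    recorded as the catalog's element). Deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    short = {
        "piRNA_cluster": "cluster",
        "coding_RNA": "mrna",
        "noncoding_RNA": "ncrna",
        "repeat": "repeat",
        "intron": "intron",
    }
    categories = []
    for cat in CANONICAL_ORDER:
        sizes = config.ref_sizes.get(cat, [])
        seqs = {
            f"{short[cat]}_{i + 1:02d}": _random_seq(rng, size)
            for i, size in enumerate(sizes)
        }
        categories.append((cat, seqs))
    element_name = None
    element_size = config.ref_sizes.get("element", 0)
    if element_size:
        element_name = "L1_synthetic"
        for i, (cat, seqs) in enumerate(categories):
            if cat == "repeat":
                seqs[element_name] = _random_seq(rng, element_size)
    return ReferenceCatalog(categories, element_name=element_name)


# --------------------------------------------------------------- generation


@dataclass
class _Initiator:
    read_id: str
    p5: int  # plus-strand 5' position on the element


def _force_base(rng, seq: str, pos: int, base: str, prob: float) -> str:
    """Substitute ``seq[pos]``: ``base`` with probability ``prob``, else a
    uniform draw from the other three bases. The substitution is always
    applied so the empirical fraction of ``base`` at ``pos`` converges to
    ``prob`` exactly."""
    if rng.random() < prob:
        new = base
    else:
        others = [b for b in _BASES if b != base]
        new = others[rng.integers(0, 3)]
    return seq[:pos] + new + seq[pos + 1 :]


def _apply_errors(rng, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        others = [b for b in _BASES if b != out[i]]
        out[i] = others[rng.integers(0, 3)]
    return "".join(out)


def simulate_library(
    config: SimConfig, catalog: ReferenceCatalog
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Simulate a FASTQ library and its ground-truth table.

    Returns the reads (in a deterministic order, grouped by population) and
    a truth table with one row per read recording population, source
    category/reference/coordinates, strand, the final insert sequence after
    bias forcing (but before sequencing errors), and ping-pong pairing.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 202])

    cluster_refs = list(catalog["piRNA_cluster"].items())
    nc_refs = list(catalog["noncoding_RNA"].items())
    element_name = catalog.element_name
    element = catalog.find(element_name) if element_name else None
    elen = len(element) if element else 0
    lmax = config.max_pirna_length()
    offset = config.pingpong_offset

    uses_element = (config.n_mili + config.n_miwi > 0) and (
        config.pingpong_fraction > 0 or config.element_fraction > 0
    )
    if uses_element:
        if element is None:
            raise ConfigurationError(
                ["catalog has no element but element-derived reads requested"]
            )
        if elen < lmax + offset:
            raise ConfigurationError(
                [
                    "element too short for ping-pong placement: "
                    f"length {elen} < max read {lmax} + offset {offset}"
                ]
            )

    # Rank-weighted cluster sampling (Zipf-like), emulating the dominance of
    # top pachytene piRNA-producing loci.
    cluster_w = np.array([1.0 / (i + 1) for i in range(len(cluster_refs))])
    cluster_w /= cluster_w.sum()

    reads: list[SimulatedRead | None] = []
    rows: list[dict] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"r{counter:07d}"

    def emit(read_id, insert, pop, cat, ref, start, strand, resp, partner):
        seq = _apply_errors(rng, insert + config.adapter, config.error_rate)
        reads.append(SimulatedRead(read_id, seq))
        rows.append(
            {
                "read_id": read_id,
                "population": pop,
                "source_category": cat,
                "source_ref": ref,
                "source_start": int(start),
                "strand": strand,
                "insert_len": len(insert),
                "insert_seq": insert,
                "is_pingpong_responder": bool(resp),
                "partner_id": partner or "",
            }
        )

    def draw_length(dist) -> int:
        lengths = sorted(dist)
        probs = np.array([dist[l] for l in lengths])
        return int(lengths[rng.choice(len(lengths), p=probs)])

    # ---- miRNA-like population: ncRNA-derived, 21-23 nt, no bias forcing.
    for _ in range(config.n_mirna):
        length = draw_length(config.len_dist_mirna)
        for _ in range(100):
            name, seq = nc_refs[rng.integers(0, len(nc_refs))]
            if len(seq) >= length:
                break
        else:
            raise ConfigurationError(
                ["no noncoding_RNA reference long enough for a miRNA insert"]
            )
        start = int(rng.integers(0, len(seq) - length + 1))
        emit(
            next_id(), seq[start : start + length], "mirna", "noncoding_RNA",
            name, start, "+", False, None,
        )

    # ---- piRNA populations.
    for pop, n, dist in (
        ("mili", config.n_mili, config.len_dist_mili),
        ("miwi", config.n_miwi, config.len_dist_miwi),
    ):
        if n == 0:
            continue
        # Decide role and length per read, in read order.
        roles = []
        for _ in range(n):
            length = draw_length(dist)
            if rng.random() < config.pingpong_fraction:
                roles.append(("responder", length))
            elif rng.random() < config.element_fraction:
                roles.append(("element_bg", length))
            else:
                roles.append(("cluster", length))

        # Responders need at least one plus-strand initiator on the element;
        # demote the first responder if none would otherwise exist.
        n_resp = sum(1 for r, _ in roles if r == "responder")
        n_plus_bg_expected = any(r == "element_bg" for r, _ in roles)
        if n_resp > 0 and not n_plus_bg_expected:
            idx = next(i for i, (r, _) in enumerate(roles) if r == "responder")
            roles[idx] = ("element_bg_plus", roles[idx][1])

        read_ids = [next_id() for _ in range(n)]
        initiators: list[_Initiator] = []
        pending: list[tuple[int, int]] = []  # (slot, length) for responders
        slots: list[tuple | None] = [None] * n
        n_bg_total = sum(1 for r, _ in roles if r.startswith("element_bg"))
        bg_seen = 0

        for i, (role, length) in enumerate(roles):
            if role == "responder":
                pending.append((i, length))
                continue
            if role == "cluster":
                for _ in range(100):
                    j = int(rng.choice(len(cluster_refs), p=cluster_w))
                    name, seq = cluster_refs[j]
                    if len(seq) >= length:
                        break
                else:
                    raise ConfigurationError(
                        ["no piRNA cluster long enough for the requested insert"]
                    )
                start = int(rng.integers(0, len(seq) - length + 1))
                insert = seq[start : start + length]
                insert = _force_base(rng, insert, 0, "T", config.u1_fraction)
                slots[i] = ("piRNA_cluster", name, start, "+", insert, False, None)
                continue
            # element background, uniform over both strands; the last
            # background read is forced to the plus strand if responders
            # would otherwise have no initiator
            bg_seen += 1
            if role == "element_bg_plus" or (
                n_resp > 0 and not initiators and bg_seen == n_bg_total
            ):
                strand = "+"
            else:
                strand = "+" if rng.random() < 0.5 else "-"
            start = int(rng.integers(0, elen - length + 1))
            window = element[start : start + length]
            insert = window if strand == "+" else revcomp(window)
            insert = _force_base(rng, insert, 0, "T", config.u1_fraction)
            slots[i] = ("repeat", element_name, start, strand, insert, False, None)
            if strand == "+":
                initiators.append(_Initiator(read_ids[i], start))

        for i, length in pending:
            placed = False
            for _ in range(200):
                init = initiators[int(rng.integers(0, len(initiators)))]
                q = init.p5 + offset - 1  # responder 5' end, plus coordinates
                start = q - length + 1
                if start >= 0 and q < elen:
                    placed = True
                    break
            if not placed:
                raise ConfigurationError(
                    ["could not place a responder; element too short "
                     "or initiators all too close to the element 5' end"]
                )
            insert = revcomp(element[start : q + 1])
            if length >= 10:
                insert = _force_base(rng, insert, 9, "A", config.a10_fraction)
            slots[i] = ("repeat", element_name, start, "-", insert, True, init.read_id)

        for i, slot in enumerate(slots):
            cat, name, start, strand, insert, resp, partner = slot
            emit(read_ids[i], insert, pop, cat, name, start, strand, resp, partner)

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return [r for r in reads if r is not None], truth


# ----------------------------------------------------------------------- IO


def write_fastq(reads, path) -> None:
    """Write 4-line FASTQ records with constant quality 'I' (Phred 40)."""
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(read.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"partner_id": str}, keep_default_na=False,
        na_values=[],
    )
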
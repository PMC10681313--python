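"""Ordered reference sequence catalogs.

Annotation of testis small-RNA reads is hierarchical: each read is assigned
to the first category, in catalog order, that yields an alignment. The
canonical order is piRNA clusters, then coding RNA, non-coding RNA, repeats
and introns; reads aligning to none of the provided sets fall through to the
implicit "other" sink. The order is significant and preserved everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError

CANONICAL_ORDER = (
    "piRNA_cluster",
    "coding_RNA",
    "noncoding_RNA",
    "repeat",
    "intron",
)

#: Terminal sink for reads that align to no provided sequence set.
OTHER_CATEGORY = "other"


@dataclass
class ReferenceCatalog:
    """Ordered, named categories of reference sequences.

    Parameters
    ----------
    categories
        List of ``(category_name, {ref_name: sequence})`` pairs in priority
        order. Category names must be unique, as must reference names within
        a category.
    element_name
        Name of the transposon consensus sequence used for ping-pong and
        strand-coverage analysis, if the catalog carries one (it usually
        lives inside the ``repeat`` category, as LINE1 does in RepeatMasker
        annotations).
    """

    categories: list[tuple[str, dict[str, str]]]
    element_name: str | None = None

    def __post_init__(self):
        errors = []
        names = [c for c, _ in self.categories]
        if len(set(names)) != len(names):
            errors.append("duplicate category names in catalog")
        for cat, seqs in self.categories:
            if not seqs:
                errors.append(f"category {cat!r} has no sequences")
            for ref, seq in seqs.items():
                if not seq:
                    errors.append(f"empty sequence {ref!r} in category {cat!r}")
        if errors:
            raise ConfigurationError(errors)
        self._priority = {c: i for i, (c, _) in enumerate(self.categories)}

    @property
    def category_names(self) -> list[str]:
        return [c for c, _ in self.categories]

    def priority(self, category: str) -> int:
        """Rank of a category; lower wins. The sink sorts last."""
        if category == OTHER_CATEGORY:
            return len(self.categories)
        return self._priority[category]

    def __contains__(self, category: str) -> bool:
        return category in self._priority

    def __getitem__(self, category: str) -> dict[str, str]:
        for cat, seqs in self.categories:
            if cat == category:
                return seqs
        raise KeyError(category)

    def iter_refs(self):
        """Yield ``(category, ref_name, sequence)`` in priority order."""
        for cat, seqs in self.categories:
            for ref, seq in seqs.items():
                yield cat, ref, seq

    def total_length(self) -> int:
        return sum(len(s) for _, _, s in self.iter_refs())

    def find(self, ref_name: str) -> str:
        """Return the sequence for ``ref_name``, searching all categories."""
        for _, ref, seq in self.iter_refs():
            if ref == ref_name:
                return seq
        raise KeyError(ref_name)

    # ------------------------------------------------------------------ IO

    def write(self, directory) -> dict[str, Path]:
        """Write one multi-FASTA per category; returns category -> path."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for cat, seqs in self.categories:
            path = directory / f"{cat}.fasta"
            records = [
                SeqRecord(Seq(s), id=name, description="")
                for name, s in seqs.items()
            ]
            SeqIO.write(records, str(path), "fasta")
            paths[cat] = path
        return paths

    @classmethod
    def from_fasta(
        cls, ordered_paths, element_name: str | None = None
    ) -> "ReferenceCatalog":
        """Build a catalog from an ordered list of ``(category, fasta_path)``."""
        categories = []
        for cat, path in ordered_paths:
            seqs = {}
            for rec in SeqIO.parse(str(path), "fasta"):
                if rec.id in seqs:
                    raise ConfigurationError(
                        [f"duplicate reference name {rec.id!r} in {path}"]
                    )
                seqs[rec.id] = str(rec.seq).upper()
            categories.append((cat, seqs))
        return cls(categories, element_name=element_name)
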
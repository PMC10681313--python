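"""Normalized summary statistics for small-RNA libraries.

Two normalization schemes are used, following how testis libraries are
reported: total-RNA libraries are normalized by their miRNA counts (reads
of 21-23 nt after clipping), so piRNA abundance is expressed relative to a
population unaffected by piRNA-pathway genotype; immunoprecipitation (IP)
libraries are normalized by their total read counts. The miRNA count is
defined purely by length — every clipped read of 21-23 nt, with no
requirement that it map to an annotated miRNA locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError, DataError

NORMALIZER_KINDS = ("mirna_counts", "total_reads", "none")


def _weight(read) -> int:
    return getattr(read, "count", 1)


def mirna_count(clipped_reads, len_min: int = 21, len_max: int = 23) -> int:
    """Total multiplicity of clipped reads in the miRNA length window."""
    return sum(
        _weight(r) for r in clipped_reads if len_min <= len(r.sequence) <= len_max
    )


@dataclass
class LengthSpectrum:
    """Per-length abundance over a display window, with its normalizer."""

    counts: dict[int, float]
    normalizer_kind: str
    normalizer_value: float

    @property
    def normalized(self) -> dict[int, float]:
        return {l: c / self.normalizer_value for l, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        lengths = sorted(self.counts)
        return pd.DataFrame(
            {
                "length": lengths,
                "count": [self.counts[l] for l in lengths],
                "abundance": [self.normalized[l] for l in lengths],
            }
        )


def _check_normalizer(kind: str, value) -> float:
    if kind not in NORMALIZER_KINDS:
        raise ConfigurationError(
            [f"normalizer_kind must be one of {NORMALIZER_KINDS}, got {kind!r}"]
        )
    if kind == "none":
        return 1.0
    if value is None or value <= 0:
        raise DataError(
            f"normalizer_kind={kind!r} requires a positive normalizer_value, "
            f"got {value!r}"
        )
    return float(value)


def length_spectrum(
    reads,
    normalizer_kind: str = "none",
    normalizer_value: float | None = None,
    window: tuple[int, int] = (15, 40),
) -> LengthSpectrum:
    """Count-weighted per-length abundance divided by the normalizer.

    The window (default 15-40 nt) only pads the spectrum with explicit
    zeros for display; observed lengths outside it are still included.
    """
    value = _check_normalizer(normalizer_kind, normalizer_value)
    counts = {l: 0.0 for l in range(window[0], window[1] + 1)}
    for r in reads:
        counts[len(r.sequence)] = counts.get(len(r.sequence), 0.0) + _weight(r)
    return LengthSpectrum(counts, normalizer_kind, value)


def first_nt_composition(reads) -> dict[str, float]:
    """Count-weighted fractions of the 5' base, in the RNA alphabet.

    DNA T is reported as U; fractions sum to 1.
    """
    reads = list(reads)
    if not reads:
        raise DataError("cannot compute first-nt composition of an empty set")
    totals = {"A": 0.0, "C": 0.0, "G": 0.0, "U": 0.0}
    grand = 0
    for r in reads:
        base = r.sequence[0]
        base = "U" if base == "T" else base
        w = _weight(r)
        if base in totals:
            totals[base] += w
            grand += w
    if grand == 0:
        raise DataError("no reads with an unambiguous first base")
    return {b: v / grand for b, v in totals.items()}


def cluster_counts(
    annotated,
    top_n: int = 50,
    normalizer_kind: str = "mirna_counts",
    normalizer_value: float | None = None,
    category: str = "piRNA_cluster",
    catalog=None,
) -> pd.DataFrame:
    """Normalized per-cluster read counts, sorted descending, top-N.

    A read with k hits in the winning cluster category contributes
    count/k to each hit's cluster, conserving read mass across clusters.
    """
    if catalog is not None and category not in catalog:
        raise DataError(f"catalog has no {category!r} category")
    value = _check_normalizer(normalizer_kind, normalizer_value)
    acc: dict[str, float] = {}
    for ar in annotated:
        if ar.assigned_category != category or not ar.hits:
            continue
        share = ar.read.count / len(ar.hits)
        for h in ar.hits:
            acc[h.ref_name] = acc.get(h.ref_name, 0.0) + share
    frame = pd.DataFrame(
        {
            "cluster": list(acc.keys()),
            "count": list(acc.values()),
        }
    )
    frame["normalized_count"] = frame["count"] / value
    frame = frame.sort_values(
        ["count", "cluster"], ascending=[False, True], ignore_index=True
    )
    return frame.head(top_n)


def compare_spectra(
    spectrum_a: LengthSpectrum, spectrum_b: LengthSpectrum
) -> pd.DataFrame:
    """Per-length ratio table b/a (a is the control library).

    Lengths with zero abundance in a get an undefined ratio (NaN, never
    infinity). Both spectra must share the same normalizer kind, otherwise
    the ratio would mix units.
    """
    if spectrum_a.normalizer_kind != spectrum_b.normalizer_kind:
        raise ConfigurationError(
            [
                "cannot compare spectra with different normalizer kinds: "
                f"{spectrum_a.normalizer_kind!r} vs {spectrum_b.normalizer_kind!r}"
            ]
        )
    a = spectrum_a.normalized
    b = spectrum_b.normalized
    lengths = sorted(set(a) | set(b))
    rows = []
    for l in lengths:
        va = a.get(l, 0.0)
        vb = b.get(l, 0.0)
        ratio = vb / va if va > 0 else float("nan")
        rows.append({"length": l, "a": va, "b": vb, "ratio": ratio})
    return pd.DataFrame(rows)
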
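"""Ping-pong 5'-5' overlap profile and transposon strand coverage.

The ping-pong amplification cycle leaves a positional fingerprint: a
responder piRNA is produced by slicing across from an initiator bound to
the opposite strand, so the 5' ends of the pair overlap by exactly 10 nt.
Given the 5' positions of reads on both strands of an element, the profile
reports, for each overlap offset k in 1..K, the percentage of opposite-
strand pair weight whose 5'-5' overlap equals k.

Overlap convention: with a plus-strand 5' end at plus coordinate p and a
minus-strand 5' end at plus coordinate q, the overlap is k = q - p + 1, so
a canonical ping-pong pair gives k = 10. Pair weight is the product of the
two reads' weights (abundance weighting); unique-pair weighting (each
distinct sequence counts once) is available via ``weighting="unique"``.
Multi-hit reads contribute to every one of their element hits with
fractional weight 1/k_hits, consistent with the cluster-count metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import five_prime_position
from .errors import ConfigurationError, DataError


@dataclass
class PingPongProfile:
    """Percent of opposite-strand pair weight per 5'-5' overlap offset."""

    offsets: np.ndarray  # 1..K
    percentages: np.ndarray  # sums to 100 when total_pair_weight > 0
    total_pair_weight: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "percent_of_pairs": self.percentages}
        )


@dataclass
class StrandCoverage:
    """Per-position 5'-end density along an element, by orientation."""

    sense: np.ndarray
    antisense: np.ndarray
    normalizer_kind: str
    normalizer_value: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(len(self.sense)),
                "sense": self.sense,
                "antisense": self.antisense,
            }
        )


def collect_five_primes(
    read_hit_pairs, element_name: str, weighting: str = "abundance"
):
    """Weighted 5'-end positions of reads on one element.

    ``read_hit_pairs`` is ``[(read, hits), ...]`` as from `align_library`;
    only hits on ``element_name`` are used. Returns a list of
    ``(strand, position, weight)`` with multi-hit apportioning applied.
    """
    if weighting not in ("abundance", "unique"):
        raise ConfigurationError(
            [f"weighting must be 'abundance' or 'unique', got {weighting!r}"]
        )
    out = []
    for read, hits in read_hit_pairs:
        ehits = [h for h in hits if h.ref_name == element_name]
        if not ehits:
            continue
        base = getattr(read, "count", 1) if weighting == "abundance" else 1.0
        share = base / len(ehits)
        for h in ehits:
            out.append((h.strand, five_prime_position(h), share))
    return out


def pingpong_profile(five_primes, k_max: int = 20) -> PingPongProfile:
    """Compute the 5'-5' overlap profile from weighted 5' positions.

    For every plus-strand 5' position p (weight w+) and minus-strand 5'
    position q (weight w-), the pair contributes w+ * w- at offset
    k = q - p + 1 when 1 <= k <= k_max. Percentages are taken over the
    total weight inside 1..k_max. No opposite-strand pairs in range is not
    an error: the profile is all-zero with total weight 0.
    """
    if k_max < 1:
        raise ConfigurationError(["k_max must be >= 1"])
    offsets = np.arange(1, k_max + 1)
    five_primes = list(five_primes)
    if not five_primes:
        return PingPongProfile(offsets, np.zeros(k_max), 0.0)
    max_pos = max(pos for _, pos, _ in five_primes)
    size = max_pos + 1
    w_plus = np.zeros(size)
    w_minus = np.zeros(size)
    for strand, pos, weight in five_primes:
        if pos < 0:
            raise DataError(f"negative 5' position {pos}")
        if strand == "+":
            w_plus[pos] += weight
        else:
            w_minus[pos] += weight
    pair = np.zeros(k_max)
    for k in range(1, k_max + 1):
        if k - 1 >= size:
            break
        # sum over p of w_plus[p] * w_minus[p + k - 1]
        pair[k - 1] = float(w_plus[: size - (k - 1)] @ w_minus[k - 1 :])
    total = float(pair.sum())
    if total > 0:
        percentages = 100.0 * pair / total
    else:
        percentages = np.zeros(k_max)
    return PingPongProfile(offsets, percentages, total)


def pingpong_zscore(profile: PingPongProfile, focal_offset: int = 10) -> float:
    """Peak summary: (focal value - mean of other offsets) / their sd.

    Returns NaN (reported as undefined) when the sd of the other offsets
    is zero — a flat profile and a single-spike profile are both degenerate
    for this statistic.
    """
    if len(profile.offsets) < 5:
        raise ConfigurationError(["z-score needs at least 5 offsets"])
    where = np.flatnonzero(profile.offsets == focal_offset)
    if where.size == 0:
        raise ConfigurationError(
            [f"focal offset {focal_offset} outside profile range"]
        )
    idx = int(where[0])
    others = np.delete(profile.percentages, idx)
    sd = float(others.std(ddof=1))
    if sd == 0.0:
        return math.nan
    return (float(profile.percentages[idx]) - float(others.mean())) / sd


def strand_coverage(
    five_primes,
    element_length: int,
    normalizer_kind: str = "total_reads",
    normalizer_value: float = 1.0,
) -> StrandCoverage:
    """Normalized per-position 5'-end density on each strand of an element."""
    if normalizer_value is None or normalizer_value <= 0:
        raise DataError("strand coverage requires a positive normalizer")
    sense = np.zeros(element_length)
    antisense = np.zeros(element_length)
    for strand, pos, weight in five_primes:
        if not 0 <= pos < element_length:
            raise DataError(
                f"5' position {pos} outside element of length {element_length}"
            )
        if strand == "+":
            sense[pos] += weight
        else:
            antisense[pos] += weight
    return StrandCoverage(
        sense / normalizer_value,
        antisense / normalizer_value,
        normalizer_kind,
        float(normalizer_value),
    )
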
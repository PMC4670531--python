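"""Length-distribution summaries of contig and gene sets."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from contigdedup.io import ContigRecord


@dataclass(frozen=True)
class LengthSummary:
    """Count, min, median, N50 and mean of a set of sequence lengths.

    N50 uses the cumulative convention: the length of the sequence at
    which the descending-sorted cumulative sum first reaches at least
    half of the total bases.  Median is the lower middle value for even
    n, so every reported statistic is an attained length.
    """

    n: int
    min_len: int
    median_len: int
    n50: int
    mean_len: float


def summarize_lengths(contigs: Sequence[ContigRecord]) -> LengthSummary:
    """Summarise the length distribution of a non-empty contig set."""
    if not contigs:
        raise ValueError("cannot summarise an empty contig set")
    lengths = np.sort(np.array([c.length for c in contigs], dtype=np.int64))

    desc = lengths[::-1]
    half = lengths.sum() / 2.0
    n50 = int(desc[np.searchsorted(np.cumsum(desc), half)])

    # lower median for even n
    median = int(lengths[(len(lengths) - 1) // 2])
    return LengthSummary(
        n=len(lengths),
        min_len=int(lengths[0]),
        median_len=median,
        n50=n50,
        mean_len=float(lengths.mean()),
    )


def summary_row(name: str, s: LengthSummary) -> str:
    """One TSV row: set name, count, min, median, N50, mean (integer)."""
    return f"{name}\t{s.n}\t{s.min_len}\t{s.median_len}\t{s.n50}\t{round(s.mean_len)}"


SUMMARY_HEADER = "set\tn\tmin_len\tmedian_len\tn50\tmean_len"
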
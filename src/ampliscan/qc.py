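"""Concatenation-path quality control for long (V1-V3) amplicons.

Read pairs spanning an amplicon too long to merge are instead
quality-truncated, trimmed to a fixed length (270 bp each), screened on
the expected error of the concatenated 540 bp, and concatenated (the
reverse read stays in as-sequenced orientation: downstream annotation
treats the two halves as independent evidence).

Quality truncation is the 3'-end partial-sums algorithm used by standard
adapter/quality trimmers: scanning from the 3' end, accumulate
(cutoff - Q) per base and cut where the running sum is maximal and
positive.  Expected error is the usual sum of per-base error
probabilities, EE = sum 10^(-Q/10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class QualityRead:
    """A read with per-base Phred scores."""

    id: str
    sequence: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if not isinstance(self.quals, tuple):
            object.__setattr__(self, "quals", tuple(self.quals))
        if len(self.sequence) != len(self.quals):
            raise QCError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quals)}"
            )
        if any(q < 0 or q > 93 for q in self.quals):
            raise QCError(f"read {self.id!r}: Phred scores must be in [0, 93]")

    def __len__(self) -> int:
        return len(self.sequence)

    def prefix(self, n: int) -> "QualityRead":
        return QualityRead(self.id, self.sequence[:n], self.quals[:n])


@dataclass(frozen=True)
class QCParams:
    """Concatenation-filter parameters: Phred cutoff for 3' truncation,
    fixed per-read trim length, and the expected-error ceiling applied to
    the concatenated product."""

    q_cutoff: int = 15
    trim_len: int = 270
    max_ee: float = 4.0

    def __post_init__(self) -> None:
        if self.max_ee <= 0:
            raise QCError("max_ee must be positive")
        if self.trim_len <= 0:
            raise QCError("trim_len must be positive")

    @property
    def concat_len(self) -> int:
        return 2 * self.trim_len


@dataclass(frozen=True)
class FilterOutcome:
    status: str  # kept | rejected_short | rejected_ee
    concatenated: Optional[QualityRead] = None
    ee_value: Optional[float] = None

    @property
    def kept(self) -> bool:
        return self.status == "kept"


def quality_truncate(read: QualityRead, q_cutoff: int = 15) -> QualityRead:
    """3'-end quality truncation by the partial-sums method.

    From the 3' end, accumulate (q_cutoff - Q); the read is cut at the
    position where the running sum is maximal and positive (ties favour
    the shortest removed suffix).  A read whose running sum never goes
    positive is returned unchanged; an all-bad read becomes empty.  The
    output is always a prefix of the input.
    """
    best_sum = 0
    best_pos = len(read)
    running = 0
    for i in range(len(read) - 1, -1, -1):
        running += q_cutoff - read.quals[i]
        if running > best_sum:
            best_sum = running
            best_pos = i
    return read.prefix(best_pos)


def expected_errors(quals: Sequence[int]) -> float:
    """Expected number of sequencing errors implied by Phred scores:
    sum over bases of 10^(-Q/10).  Empty input yields 0."""
    arr = np.asarray(quals, dtype=float)
    if arr.size == 0:
        return 0.0
    if (arr < 0).any():
        raise QCError("negative Phred score")
    return float(np.power(10.0, -arr / 10.0).sum())


def concat_filter(
    fwd: QualityRead, rev: QualityRead, params: QCParams = QCParams()
) -> FilterOutcome:
    """Quality-truncate, length-check, EE-screen, and concatenate a pair.

    Both reads are 3'-quality-truncated; if either truncated read is
    shorter than ``trim_len`` the pair is rejected as short (a read of
    exactly ``trim_len`` passes).  Surviving reads are cut to exactly
    ``trim_len``, and the pair is rejected when the expected error over
    the concatenated 2 x trim_len bases exceeds ``max_ee``.  The reverse
    read is concatenated as sequenced, without reverse complementing.
    """
    f = quality_truncate(fwd, params.q_cutoff)
    r = quality_truncate(rev, params.q_cutoff)
    if len(f) < params.trim_len or len(r) < params.trim_len:
        return FilterOutcome("rejected_short")
    f = f.prefix(params.trim_len)
    r = r.prefix(params.trim_len)
    quals = f.quals + r.quals
    ee = expected_errors(quals)
    if ee > params.max_ee:
        return FilterOutcome("rejected_ee", ee_value=ee)
    concatenated = QualityRead(fwd.id, f.sequence + r.sequence, quals)
    return FilterOutcome("kept", concatenated=concatenated, ee_value=ee)


def read_fastq(path) -> list[QualityRead]:
    """Read Sanger/Phred+33 FASTQ into :class:`QualityRead` objects."""
    return [
        QualityRead(
            rec.id, str(rec.seq).upper(), tuple(rec.letter_annotations["phred_quality"])
        )
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: Iterable[QualityRead], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual_str = "".join(chr(q + 33) for q in read.quals)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual_str}\n")


def filter_pairs(
    fwd_reads: Sequence[QualityRead],
    rev_reads: Sequence[QualityRead],
    params: QCParams = QCParams(),
) -> list[tuple[QualityRead, QualityRead, FilterOutcome]]:
    """Apply :func:`concat_filter` pairwise to two parallel read lists."""
    if len(fwd_reads) != len(rev_reads):
        raise QCError(
            f"forward/reverse read counts differ: {len(fwd_reads)} vs {len(rev_reads)}"
        )
    return [(f, r, concat_filter(f, r, params)) for f, r in zip(fwd_reads, rev_reads)]
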
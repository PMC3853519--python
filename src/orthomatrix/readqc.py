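"""Read-quality filtering and assembly summary metrics.

The quality rule mirrors the RNA-Seq screen the pipeline assumes upstream of
assembly: a read is discarded when its Phred score is not greater than a
threshold (default 20) at strictly more than a given fraction of positions
(default 90%).  Assembly quality is summarized by contig count, median
length, total bases and N50; the k-mer grid enumerates the multi-k assembly
sweep (k = 52..96 in steps of two gives the canonical 23 runs per sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

import numpy as np
from Bio import SeqIO

from .errors import EmptyInputError, InvalidParameterError, MalformedRecordError


@dataclass
class QualityRead:
    """One read with per-base Phred scores."""

    id: str
    bases: str
    quals: list[int]
    description: str = ""

    def validate(self) -> None:
        if len(self.bases) != len(self.quals):
            raise MalformedRecordError(
                f"read {self.id!r}: {len(self.bases)} bases but {len(self.quals)} quality scores"
            )
        if self.quals and (min(self.quals) < 0 or max(self.quals) > 60):
            raise MalformedRecordError(f"read {self.id!r}: Phred scores outside [0, 60]")


@dataclass
class FilterParams:
    """Quality-filter parameters: Phred threshold and offending fraction."""

    q_threshold: int = 20
    bad_fraction: float = 0.90

    def __post_init__(self) -> None:
        if not (0 < self.bad_fraction <= 1):
            raise InvalidParameterError("bad_fraction must be in (0, 1]")
        if self.q_threshold < 0:
            raise InvalidParameterError("q_threshold must be non-negative")


@dataclass
class ContigSet:
    lengths: list[int]

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.lengths):
            raise InvalidParameterError("contig lengths must be positive")


@dataclass
class KmerSweep:
    k_min: int
    k_max: int
    step: int

    def __post_init__(self) -> None:
        if self.k_min > self.k_max:
            raise InvalidParameterError("k_min must be <= k_max")
        if self.step <= 0:
            raise InvalidParameterError("step must be positive")
        if (self.k_max - self.k_min) % self.step != 0:
            raise InvalidParameterError("(k_max - k_min) must be divisible by step")


@dataclass
class AssemblyMetrics:
    count: int
    median_length: float
    total_bases: int
    n50: int


def _chastity_failed(read: QualityRead) -> bool:
    # CASAVA 1.8 header: "<id> <read>:<is_filtered Y/N>:<control>:<index>"
    fields = read.description.split()
    if len(fields) >= 2:
        parts = fields[1].split(":")
        if len(parts) >= 2 and parts[1] == "Y":
            return True
    return False


def phred_filter(
    reads: Iterable[QualityRead],
    params: FilterParams | None = None,
    skip_chastity_failed: bool = False,
) -> tuple[list[QualityRead], int]:
    """Discard reads with Phred <= threshold at > bad_fraction of positions.

    The comparison is strict on both sides, matching the rule "not greater
    than 20 at greater than 90% of positions": a 100-bp read with exactly 90
    low-quality positions is kept.  Order of kept reads is preserved.
    Returns (kept reads, number discarded).  With ``skip_chastity_failed``,
    reads whose CASAVA 1.8 header flag is "Y" are discarded up front (the
    flag is instrument-generated; it is honored, never recomputed).
    """
    if params is None:
        params = FilterParams()
    kept: list[QualityRead] = []
    discarded = 0
    for read in reads:
        read.validate()
        if skip_chastity_failed and _chastity_failed(read):
            discarded += 1
            continue
        n = len(read.quals)
        bad = sum(1 for q in read.quals if q <= params.q_threshold)
        if n > 0 and bad / n > params.bad_fraction:
            discarded += 1
        else:
            kept.append(read)
    return kept, discarded


def assembly_metrics(contigs: ContigSet) -> AssemblyMetrics:
    """Contig count, median length, total bases, and N50.

    N50 is the standard descending-cumulative statistic: the largest length L
    such that contigs of length >= L together contain at least half of all
    assembled bases.
    """
    if not contigs.lengths:
        raise EmptyInputError("empty contig set")
    lengths = sorted(contigs.lengths, reverse=True)
    total = sum(lengths)
    half = total / 2
    acc = 0
    n50 = lengths[-1]
    for l in lengths:
        acc += l
        if acc >= half:
            n50 = l
            break
    return AssemblyMetrics(
        count=len(lengths),
        median_length=float(np.median(lengths)),
        total_bases=total,
        n50=n50,
    )


def kmer_grid(sweep: KmerSweep) -> list[int]:
    """Inclusive arithmetic sequence of k values for the multi-k sweep."""
    return list(range(sweep.k_min, sweep.k_max + 1, sweep.step))


def read_fastq(handle: TextIO) -> Iterator[QualityRead]:
    """Parse Phred+33 FASTQ into QualityRead records."""
    for rec in SeqIO.parse(handle, "fastq"):
        yield QualityRead(
            id=rec.id,
            bases=str(rec.seq),
            quals=list(rec.letter_annotations["phred_quality"]),
            description=rec.description,
        )


def write_fastq(reads: Iterable[QualityRead], handle: TextIO) -> int:
    """Write QualityRead records as Phred+33 FASTQ; returns count written."""
    n = 0
    for read in reads:
        read.validate()
        quals = "".join(chr(q + 33) for q in read.quals)
        handle.write(f"@{read.description or read.id}\n{read.bases}\n+\n{quals}\n")
        n += 1
    return n
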
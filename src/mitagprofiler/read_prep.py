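"""Read-pair merging and quality trimming.

Mirrors the preprocessing of overlapping 2×108 bp libraries: mates from a
~175 bp insert are merged over their best overlap (lowest mismatch ratio,
ties to the longer overlap), then trimmed so that — with ``bad_fraction``
0 — no base below the quality cutoff survives, and anything shorter than
``min_length`` is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b
_N = ord("N")


@dataclass
class ReadRecord:
    """A single read: sequence plus per-base Phred scores."""

    id: str
    sequence: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int64)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if set(self.sequence) - set("ACGTN"):
            raise ValueError(f"{self.id}: sequence alphabet outside ACGTN")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MergePolicy:
    """Overlap-merging parameters (defaults follow the FLASH merger, with
    the maximum overlap raised to the expected insert size)."""

    min_overlap: int = 10
    max_overlap: int = 175
    max_mismatch_ratio: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.min_overlap <= self.max_overlap:
            raise ValueError("need 0 < min_overlap <= max_overlap")
        if not 0.0 <= self.max_mismatch_ratio <= 1.0:
            raise ValueError("max_mismatch_ratio must be in [0, 1]")


@dataclass(frozen=True)
class TrimPolicy:
    """Quality-trimming parameters: ``bad_fraction = 0`` means no base below
    ``quality_cutoff`` is tolerated anywhere in the retained read."""

    min_length: int = 90
    bad_fraction: float = 0.0
    quality_cutoff: int = 13

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not 0.0 <= self.bad_fraction <= 1.0:
            raise ValueError("bad_fraction must be in [0, 1]")


def _revcomp(seq: np.ndarray) -> np.ndarray:
    return _COMP[seq[::-1]]


def merge_pair(r1: ReadRecord, r2: ReadRecord,
               policy: MergePolicy = MergePolicy()) -> ReadRecord | None:
    """Merge an innie pair into one read, or return None if no acceptable
    overlap exists.

    The mate is reverse-complemented, candidate overlaps in
    ``[min_overlap, max_overlap]`` are scored by mismatch ratio
    (N counts as a mismatch), and the best-scoring overlap wins if its
    ratio is within ``max_mismatch_ratio``.  Disagreeing positions take
    the higher-quality base.
    """
    if len(r1) == 0 or len(r2) == 0:
        raise ValueError("cannot merge empty reads")
    s1 = np.frombuffer(r1.sequence.encode(), dtype=np.uint8)
    q1 = r1.qualities
    s2 = _revcomp(np.frombuffer(r2.sequence.encode(), dtype=np.uint8))
    q2 = r2.qualities[::-1]
    n1, n2 = len(s1), len(s2)

    best_ratio, best_o = None, None
    for o in range(policy.min_overlap, min(policy.max_overlap, n1, n2) + 1):
        a, b = s1[n1 - o:], s2[:o]
        mm = int(np.count_nonzero((a != b) | (a == _N) | (b == _N)))
        ratio = mm / o
        if best_ratio is None or ratio < best_ratio or (ratio == best_ratio and o > best_o):
            best_ratio, best_o = ratio, o
    if best_ratio is None or best_ratio > policy.max_mismatch_ratio:
        return None

    o = best_o
    a, b = s1[n1 - o:].copy(), s2[:o]
    qa, qb = q1[n1 - o:].copy(), q2[:o]
    take_b = qb > qa  # ties keep the forward read's base
    cons = np.where(take_b, b, a)
    cons_q = np.maximum(qa, qb)
    disagree = a != b
    cons_q[disagree] = np.where(take_b[disagree], qb[disagree], qa[disagree])

    seq = np.concatenate([s1[: n1 - o], cons, s2[o:]])
    qual = np.concatenate([q1[: n1 - o], cons_q, q2[o:]])
    return ReadRecord(r1.id, seq.tobytes().decode(), qual)


def quality_trim(read: ReadRecord,
                 policy: TrimPolicy = TrimPolicy()) -> ReadRecord | None:
    """Trim to the best window satisfying the bad-base tolerance; None when
    nothing of ``min_length`` survives.

    With ``bad_fraction = 0`` (the strict setting used throughout) this is
    exactly the longest contiguous run free of sub-cutoff bases and Ns.
    """
    bad = (read.qualities < policy.quality_cutoff) | (
        np.frombuffer(read.sequence.encode(), dtype=np.uint8) == _N
    )
    n = len(bad)
    if n == 0:
        return None
    if policy.bad_fraction == 0.0:
        edges = np.flatnonzero(bad)
        bounds = np.concatenate([[-1], edges, [n]])
        runs = np.diff(bounds) - 1
        k = int(np.argmax(runs))
        start, length = bounds[k] + 1, int(runs[k])
    else:
        # sliding window keeping bad-base fraction within tolerance
        start = length = 0
        left = count = 0
        for right in range(n):
            count += bad[right]
            while count > policy.bad_fraction * (right - left + 1):
                count -= bad[left]
                left += 1
            if right - left + 1 > length:
                start, length = left, right - left + 1
    if length < policy.min_length:
        return None
    return ReadRecord(
        read.id,
        read.sequence[start:start + length],
        read.qualities[start:start + length],
    )


@dataclass
class PrepStats:
    """Per-stage read accounting; conservative by construction."""

    pairs_in: int = 0
    merged: int = 0
    unmerged_discarded: int = 0
    trimmed_out: int = 0
    trim_discarded: int = 0
    merged_lengths: list = field(default_factory=list)

    @property
    def mean_length(self) -> float:
        return float(np.mean(self.merged_lengths)) if self.merged_lengths else 0.0

    @property
    def sd_length(self) -> float:
        return float(np.std(self.merged_lengths)) if self.merged_lengths else 0.0

    def summary(self) -> dict:
        return {
            "pairs_in": self.pairs_in,
            "merged": self.merged,
            "unmerged_discarded": self.unmerged_discarded,
            "reads_out": self.trimmed_out,
            "trim_discarded": self.trim_discarded,
            "mean_merged_length": round(self.mean_length, 2),
            "sd_merged_length": round(self.sd_length, 2),
        }


def prep_reads(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    merge_policy: MergePolicy = MergePolicy(),
    trim_policy: TrimPolicy = TrimPolicy(),
) -> tuple[list[ReadRecord], PrepStats]:
    """Merge then trim every pair; unmergeable pairs are discarded."""
    stats = PrepStats()
    out: list[ReadRecord] = []
    for r1, r2 in pairs:
        stats.pairs_in += 1
        merged = merge_pair(r1, r2, merge_policy)
        if merged is None:
            stats.unmerged_discarded += 1
            continue
        stats.merged += 1
        stats.merged_lengths.append(len(merged))
        trimmed = quality_trim(merged, trim_policy)
        if trimmed is None:
            stats.trim_discarded += 1
            continue
        stats.trimmed_out += 1
        out.append(trimmed)
    return out, stats


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(
            rec.id,
            str(rec.seq).upper(),
            np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int64),
        )


def read_fastq_pairs(r1_path: str | Path,
                     r2_path: str | Path) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    yield from zip(read_fastq(r1_path), read_fastq(r2_path), strict=True)


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(int(q) + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")
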
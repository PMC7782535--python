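"""Paired-end read merging and adapter trimming.

The merger reconstructs the sequenced fragment from an overlapping read
pair by scanning every candidate overlap length and taking the one with
the fewest mismatches (ties broken toward the longer overlap).  No
statistical significance test is applied: the pipeline is configured to
accept any overlap whose mismatch rate is within tolerance, which matches
running an overlap merger with the significance test disabled.

Adapter trimming removes the library adapters that flank every insert:
a 5' adapter whose suffix may appear at the read start and a 3' adapter
whose prefix may appear at the read end.  Trimming runs to a fixed point
so it is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .sequtil import encode, revcomp, rna_to_dna

logger = logging.getLogger(__name__)

#: inserts shorter than this after trimming are excluded downstream
MIN_INSERT_LEN = 18

#: library adapters, stored as DNA
THREE_PRIME_ADAPTER = rna_to_dna("UCUGGAAUUCUCGGGUGCCAAGGAACUCC")
FIVE_PRIME_ADAPTER = rna_to_dna("GUUCAGAGUUCUACAGUCCGACGAUC")


@dataclass(frozen=True)
class ReadPair:
    id: str
    r1_seq: str
    r2_seq: str
    r1_qual: str | None = None
    r2_qual: str | None = None

    def __post_init__(self) -> None:
        if not self.r1_seq or not self.r2_seq:
            raise ValueError(f"read pair {self.id!r}: empty sequence")
        if self.r1_qual is not None and len(self.r1_qual) != len(self.r1_seq):
            raise ValueError(f"read pair {self.id!r}: r1 quality length mismatch")
        if self.r2_qual is not None and len(self.r2_qual) != len(self.r2_seq):
            raise ValueError(f"read pair {self.id!r}: r2 quality length mismatch")


@dataclass(frozen=True)
class MergedRead:
    id: str
    sequence: str
    overlap_len: int
    merged: bool
    too_short: bool = False  # set by trim_adapters when insert < MIN_INSERT_LEN


@dataclass(frozen=True)
class MergeParams:
    min_overlap: int = 30
    max_mismatch_rate_in_overlap: float = 0.1
    statistical_test_enabled: bool = False  # kept off: matches -p 1.0 semantics

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not (0.0 <= self.max_mismatch_rate_in_overlap <= 1.0):
            raise ValueError("max_mismatch_rate_in_overlap must be in [0, 1]")
        if self.statistical_test_enabled:
            raise NotImplementedError(
                "statistical overlap testing is not implemented; "
                "pure overlap merging is used"
            )


@dataclass(frozen=True)
class AdapterSpec:
    three_prime: str = THREE_PRIME_ADAPTER
    five_prime: str = FIVE_PRIME_ADAPTER
    min_adapter_match: int = 8

    def __post_init__(self) -> None:
        if not self.three_prime or not self.five_prime:
            raise ValueError("adapters must be non-empty")


def merge_pair(pair: ReadPair, params: MergeParams = MergeParams()) -> MergedRead:
    """Merge an overlapping read pair into a single fragment sequence.

    All overlap lengths ``o`` in ``[min_overlap, min(len(r1), len(r2))]``
    between the r1 suffix and the reverse-complemented-r2 prefix are
    scored; the overlap with the fewest mismatches wins (ties -> longest).
    At mismatching overlap positions the base with the higher quality is
    kept; without qualities the r1 base wins.
    """
    r1 = pair.r1_seq.upper()
    rc2 = revcomp(pair.r2_seq.upper())
    a1, a2 = encode(r1), encode(rc2)
    max_o = min(len(r1), len(rc2))
    if params.min_overlap > max_o:
        return MergedRead(pair.id, "", 0, merged=False)

    best_o, best_mm = -1, None
    for o in range(params.min_overlap, max_o + 1):
        mm = int(np.count_nonzero(a1[len(r1) - o:] != a2[:o]))
        if best_mm is None or mm < best_mm or (mm == best_mm and o > best_o):
            best_o, best_mm = o, mm

    if best_mm / best_o > params.max_mismatch_rate_in_overlap:
        return MergedRead(pair.id, "", 0, merged=False)

    o = best_o
    if best_mm == 0:
        seq = r1 + rc2[o:]
    else:
        q1 = pair.r1_qual[len(r1) - o:] if pair.r1_qual else None
        q2 = pair.r2_qual[::-1][:o] if pair.r2_qual else None
        overlap = list(r1[len(r1) - o:])
        for k in range(o):
            if overlap[k] != rc2[k]:
                if q1 is not None and q2 is not None and q2[k] > q1[k]:
                    overlap[k] = rc2[k]
        seq = r1[:len(r1) - o] + "".join(overlap) + rc2[o:]
    return MergedRead(pair.id, seq, o, merged=True)


def _allowed_mismatches(k: int) -> int:
    # short matches must be exact; longer ones tolerate sequencing errors
    return 0 if k < 12 else k // 8


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _longest_prefix_match(seq: str, adapter_prefix_of: str, min_match: int) -> int:
    """Longest k >= min_match such that seq ends with adapter_prefix_of[:k]
    (within the per-length mismatch allowance)."""
    for k in range(min(len(seq), len(adapter_prefix_of)), min_match - 1, -1):
        if _hamming(seq[len(seq) - k:], adapter_prefix_of[:k]) <= _allowed_mismatches(k):
            return k
    return 0


def _longest_suffix_match(seq: str, adapter_suffix_of: str, min_match: int) -> int:
    """Longest k >= min_match such that seq starts with adapter_suffix_of[-k:]
    (within the per-length mismatch allowance)."""
    for k in range(min(len(seq), len(adapter_suffix_of)), min_match - 1, -1):
        if _hamming(seq[:k], adapter_suffix_of[len(adapter_suffix_of) - k:]) \
                <= _allowed_mismatches(k):
            return k
    return 0


def trim_adapters(read: MergedRead, spec: AdapterSpec = AdapterSpec()) -> MergedRead:
    """Strip library adapters from a merged read (idempotent).

    Removes the longest 5' prefix matching a suffix of the 5' adapter and
    the longest 3' suffix matching a prefix of the 3' adapter, requiring at
    least ``min_adapter_match`` exactly matching bases; repeats until no
    further match so trimming is a fixed point.  Reads shorter than
    ``MIN_INSERT_LEN`` afterwards are flagged ``too_short``.
    """
    seq = read.sequence
    while True:
        k5 = _longest_suffix_match(seq, spec.five_prime, spec.min_adapter_match)
        if k5:
            seq = seq[k5:]
        k3 = _longest_prefix_match(seq, spec.three_prime, spec.min_adapter_match)
        if k3:
            seq = seq[:len(seq) - k3]
        if not k5 and not k3:
            break
    return replace(read, sequence=seq, too_short=len(seq) < MIN_INSERT_LEN)


# ---------------------------------------------------------------------------
# FASTQ plumbing
# ---------------------------------------------------------------------------

def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPair]:
    """Stream read pairs from two FASTQ files (plain or gzipped)."""
    import gzip

    def _open(p):
        p = str(p)
        return gzip.open(p, "rt") if p.endswith(".gz") else open(p)

    def _records(fh):
        while True:
            header = fh.readline().strip()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            yield header[1:].split()[0], seq, qual

    with _open(r1_path) as f1, _open(r2_path) as f2:
        for (id1, s1, q1), (id2, s2, q2) in zip(_records(f1), _records(f2)):
            base = id1.removesuffix("/1")
            if base != id2.removesuffix("/2"):
                raise ValueError(f"unpaired FASTQ records: {id1!r} vs {id2!r}")
            yield ReadPair(base, s1, s2, q1 or None, q2 or None)


def write_fastq(reads: Iterable[MergedRead], out: str | Path) -> Path:
    out = Path(out)
    with open(out, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
    return out


def prepare_reads(
    pairs: Iterable[ReadPair],
    merge_params: MergeParams = MergeParams(),
    adapter_spec: AdapterSpec | None = AdapterSpec(),
) -> tuple[list[MergedRead], dict[str, int]]:
    """Merge and (optionally) trim a stream of read pairs.

    Returns the surviving reads and a funnel summary
    (pairs_in / merged / trimmed_ok / dropped_unmerged / dropped_short).
    """
    out: list[MergedRead] = []
    stats = {"pairs_in": 0, "merged": 0, "trimmed_ok": 0,
             "dropped_unmerged": 0, "dropped_short": 0}
    for pair in pairs:
        stats["pairs_in"] += 1
        merged = merge_pair(pair, merge_params)
        if not merged.merged:
            stats["dropped_unmerged"] += 1
            continue
        stats["merged"] += 1
        if adapter_spec is not None:
            merged = trim_adapters(merged, adapter_spec)
        if merged.too_short:
            stats["dropped_short"] += 1
            continue
        stats["trimmed_ok"] += 1
        out.append(merged)
    logger.info("read prep funnel: %s", stats)
    return out, stats
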
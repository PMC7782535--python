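"""Chimera calling from arm alignments.

A read is called chimeric when it carries (1) a partial alignment to some
mature miRNA and to some mRNA, and (2) the two aligned read intervals do
not overlap.  When several arm pairs qualify, the pair with the highest
total score wins (ties: smaller inter-arm gap, then lexicographic
(miRNA id, transcript id)); by default at most one chimera is emitted per
read.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .aligner import ArmAlignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChimeraCall:
    read_id: str
    mirna_arm: ArmAlignment
    mrna_arm: ArmAlignment
    inter_arm_gap: int
    orientation: str  # 'miRNA-5prime' or 'miRNA-3prime'

    def __post_init__(self) -> None:
        if self.inter_arm_gap < 0:
            raise ValueError(f"read {self.read_id!r}: arm intervals overlap")
        if self.mirna_arm.subject_class != "miRNA":
            raise ValueError("mirna_arm must be a miRNA-class alignment")
        if self.mrna_arm.subject_class != "mRNA":
            raise ValueError("mrna_arm must be an mRNA-class alignment")


def _pair_geometry(mi: ArmAlignment, tx: ArmAlignment) -> tuple[int, str] | None:
    """(gap, orientation) for a disjoint arm pair, or None if overlapping."""
    (ms, me), (ts, te) = mi.read_interval, tx.read_interval
    if me <= ts:
        return ts - me, "miRNA-5prime"
    if te <= ms:
        return ms - te, "miRNA-3prime"
    return None


def call_chimeras(
    arms_by_read: Mapping[str, list[ArmAlignment]],
    max_gap: int = 10,
    all_pairs: bool = False,
) -> list[ChimeraCall]:
    """Apply the two chimera selection rules to per-read arm alignments.

    For every read, all (miRNA arm, mRNA arm) pairs with disjoint read
    intervals and inter-arm gap <= ``max_gap`` are enumerated; the best
    pair per read is emitted unless ``all_pairs`` is set.  Output is
    ordered by read id.
    """
    calls: list[ChimeraCall] = []
    for read_id in sorted(arms_by_read):
        arms = arms_by_read[read_id]
        mirna_arms = [a for a in arms if a.subject_class == "miRNA"]
        mrna_arms = [a for a in arms if a.subject_class == "mRNA"]
        candidates: list[tuple[tuple, ChimeraCall]] = []
        for mi in mirna_arms:
            for tx in mrna_arms:
                geom = _pair_geometry(mi, tx)
                if geom is None:
                    continue
                gap, orientation = geom
                if gap > max_gap:
                    continue
                call = ChimeraCall(read_id, mi, tx, gap, orientation)
                key = (-(mi.score + tx.score), gap, mi.subject_id, tx.subject_id)
                candidates.append((key, call))
        if not candidates:
            continue
        candidates.sort(key=lambda kc: kc[0])
        if all_pairs:
            calls.extend(c for _, c in candidates)
        else:
            calls.append(candidates[0][1])
    return calls


def select_mirna_hybrids(calls: Iterable[ChimeraCall], mirna_id: str) -> list[ChimeraCall]:
    """Subset of calls whose miRNA arm matches ``mirna_id`` (order preserved)."""
    calls = list(calls)
    out = [c for c in calls if c.mirna_arm.subject_id == mirna_id]
    if calls and not out:
        logger.warning("no chimeras involve miRNA %r", mirna_id)
    return out


def aggregate_hybrids(calls: Iterable[ChimeraCall]) -> pd.DataFrame:
    """Group chimera calls per (miRNA, transcript).

    Returns a table with hybrid_count and the number of distinct
    transcript-arm subject intervals, ordered by count descending then ids.
    """
    counts: Counter = Counter()
    intervals: dict[tuple[str, str], set] = {}
    for c in calls:
        key = (c.mirna_arm.subject_id, c.mrna_arm.subject_id)
        counts[key] += 1
        intervals.setdefault(key, set()).add(c.mrna_arm.subject_interval)
    rows = [
        {
            "mirna_id": mirna_id,
            "transcript_id": tx_id,
            "hybrid_count": n,
            "distinct_site_intervals": len(intervals[(mirna_id, tx_id)]),
        }
        for (mirna_id, tx_id), n in counts.items()
    ]
    rows.sort(key=lambda r: (-r["hybrid_count"], r["mirna_id"], r["transcript_id"]))
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "transcript_id", "hybrid_count", "distinct_site_intervals"],
    )
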
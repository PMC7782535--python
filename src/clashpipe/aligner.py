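"""Alignment engines.

Two distinct jobs share this module:

* :func:`filter_contiguous` — an end-to-end matcher that removes every
  merged read explainable as one contiguous reference window (either
  strand, small indels allowed).  Reads surviving this filter are the
  candidate chimeras.  The same engine, via :func:`place_reads`, places
  IP reads on transcripts for region counting.

* :func:`local_align` — a word-seeded, banded, affine-gap local aligner
  that reports partial ("arm") alignments of a read against the miRNA or
  the mRNA reference class, with Karlin-Altschul style E-values.

Scoring defaults follow classic blastn conventions (+2/-3, gap -5/-2,
word size 7) and are fully configurable.  E-values use ungapped
Karlin-Altschul estimates for that scheme (lambda=0.625, K=0.41); tests
rely only on their monotonicity and thresholding behaviour, not on
agreement with any external tool.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from math import exp
from typing import Iterable, Literal

import numpy as np

from .read_prep import MergedRead
from .reference_io import ReferenceSet
from .sequtil import encode, revcomp

logger = logging.getLogger(__name__)

SubjectClass = Literal["miRNA", "mRNA"]


@dataclass(frozen=True)
class AlignParams:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    word_size: int = 7
    evalue_max: float = 10.0
    search_both_strands: bool = True
    min_arm_len: int = 12
    ka_lambda: float = 0.625
    ka_K: float = 0.41

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if self.min_arm_len < self.word_size:
            raise ValueError("min_arm_len must be >= word_size")


#: printed search parameters: permissive threshold for the short miRNA arms,
#: strict threshold for the mRNA arms
MIRNA_ALIGN_PARAMS = AlignParams(evalue_max=10.0)
MRNA_ALIGN_PARAMS = AlignParams(evalue_max=0.1)


@dataclass(frozen=True)
class ArmAlignment:
    """A local alignment of a read sub-interval to one reference subject."""

    read_id: str
    read_interval: tuple[int, int]        # [qstart, qend) on the read
    subject_id: str
    subject_interval: tuple[int, int]     # [sstart, send) forward subject coords
    strand: str                           # '+' or '-'
    score: int
    evalue: float
    identity: float
    subject_class: SubjectClass
    aln_length: int = 0
    mismatches: int = 0
    gaps: int = 0
    # per-column alignment path in oriented subject coordinates:
    # (qpos, spos, score_delta) with -1 for the unconsumed side of a gap
    path: tuple = field(default=(), compare=False, repr=False)
    subject_len: int = field(default=0, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.score <= 0:
            raise ValueError("emitted alignments must have positive score")
        qs, qe = self.read_interval
        if qe <= qs:
            raise ValueError("empty read interval")


def evalue_for(score: int, m: int, n: int, params: AlignParams) -> float:
    """Karlin-Altschul E-value for a local score against a search space."""
    return params.ka_K * m * n * exp(-params.ka_lambda * score)


# ---------------------------------------------------------------------------
# banded affine-gap local alignment
# ---------------------------------------------------------------------------

NEG = -(10 ** 9)


def banded_local_align(
    q: np.ndarray,
    s: np.ndarray,
    dlo: int,
    dhi: int,
    params: AlignParams,
) -> tuple | None:
    """Best local alignment of q vs s restricted to diagonals j-i in [dlo, dhi].

    Returns (score, qstart, qend, sstart, send, matches, mismatches, gaps,
    aln_length) or None if no positive-scoring cell exists.  Bases encoded
    via :func:`sequtil.encode`; code 4 (N) never matches.
    """
    lq, ls = len(q), len(s)
    w = dhi - dlo + 1
    if w <= 0 or lq == 0 or ls == 0:
        return None
    ma, mi = params.match, params.mismatch
    go, ge = params.gap_open + params.gap_extend, params.gap_extend

    H = np.zeros((lq, w), dtype=np.int32)
    E = np.full((lq, w), NEG, dtype=np.int32)  # gap consuming subject (moves in j)
    F = np.full((lq, w), NEG, dtype=np.int32)  # gap consuming query (moves in i)
    # pointers: H 0=local start, 1=diag-from-H, 2=close-E, 3=close-F
    #           E/F True=extend, False=open-from-H
    PH = np.zeros((lq, w), dtype=np.int8)
    PE = np.zeros((lq, w), dtype=bool)
    PF = np.zeros((lq, w), dtype=bool)
    best, bi, bk = 0, -1, -1

    for i in range(lq):
        qi = q[i]
        jlo = max(0, i + dlo)
        jhi = min(ls - 1, i + dhi)
        for j in range(jlo, jhi + 1):
            k = j - i - dlo
            sub = ma if (qi == s[j] and qi != 4) else mi

            e = NEG
            if k >= 1 and j >= 1:
                e_open = H[i, k - 1] + go
                e_ext = E[i, k - 1] + ge
                e = max(e_open, e_ext)
                PE[i, k] = e_ext >= e_open
            f = NEG
            if i >= 1 and k + 1 < w:
                f_open = H[i - 1, k + 1] + go
                f_ext = F[i - 1, k + 1] + ge
                f = max(f_open, f_ext)
                PF[i, k] = f_ext >= f_open
            if i >= 1 and j >= 1 and H[i - 1, k] > 0:
                d = H[i - 1, k] + sub
                dptr = 1
            else:
                d = sub
                dptr = 0
            h = max(0, d, e, f)
            if h == 0:
                ptr = 0
            elif h == d:
                ptr = dptr
            elif h == e:
                ptr = 2
            else:
                ptr = 3
            H[i, k], E[i, k], F[i, k], PH[i, k] = h, e, f, ptr
            if h > best:
                best, bi, bk = h, i, k

    if best <= 0:
        return None

    # traceback via stored pointers, recording the column path
    i, k = bi, bk
    state = "H"
    matches = mismatches = gaps = aln_len = 0
    qend = bi + 1
    send = bi + bk + dlo + 1
    qstart = sstart = 0
    cols: list[tuple[int, int, int]] = []
    while True:
        j = i + k + dlo
        if state == "H":
            ptr = PH[i, k]
            if ptr in (0, 1):
                hit = q[i] == s[j] and q[i] != 4
                if hit:
                    matches += 1
                else:
                    mismatches += 1
                aln_len += 1
                cols.append((i, j, ma if hit else mi))
                if ptr == 0:
                    qstart, sstart = i, j
                    break
                i -= 1  # diagonal move: k unchanged
            elif ptr == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            gaps += 1
            aln_len += 1
            cols.append((-1, j, ge if PE[i, k] else go))
            if not PE[i, k]:
                state = "H"
            k -= 1
        else:  # F
            gaps += 1
            aln_len += 1
            cols.append((i, -1, ge if PF[i, k] else go))
            if not PF[i, k]:
                state = "H"
            i -= 1
            k += 1
    cols.reverse()
    return (best, qstart, qend, sstart, send, matches, mismatches, gaps, aln_len,
            tuple(cols))


# ---------------------------------------------------------------------------
# subject indexing and local search
# ---------------------------------------------------------------------------

class SubjectIndex:
    """Word index over one reference class (both strands when requested)."""

    def __init__(
        self,
        subjects: list[tuple[str, str]],
        word_size: int,
        both_strands: bool = True,
    ) -> None:
        self.word_size = word_size
        self.subjects = subjects
        self.oriented: list[tuple[str, str, np.ndarray, int]] = []
        self.kmers: dict[str, list[tuple[int, int]]] = {}
        self.total_len = 0
        for sid, seq in subjects:
            strands = [("+", seq)]
            if both_strands:
                strands.append(("-", revcomp(seq)))
            for strand, oseq in strands:
                idx = len(self.oriented)
                self.oriented.append((sid, strand, encode(oseq), len(seq)))
                self.total_len += len(oseq)
                for p in range(len(oseq) - word_size + 1):
                    kmer = oseq[p:p + word_size]
                    if "N" in kmer:
                        continue
                    self.kmers.setdefault(kmer, []).append((idx, p))

    @classmethod
    def for_class(
        cls, refs: ReferenceSet, subject_class: SubjectClass, params: AlignParams
    ) -> "SubjectIndex":
        if subject_class == "miRNA":
            subjects = [(m.id, m.sequence) for m in refs.mirnas]
        else:
            subjects = [(t.id, t.sequence) for t in refs.transcripts]
        return cls(subjects, params.word_size, params.search_both_strands)


_BAND_PAD = 8    # extra diagonals explored around seeded diagonals
_DIAG_GAP = 6    # seeds whose diagonals differ by <= this share one band
_PREFILTER_MARGIN = 4   # slack added to the ungapped bound before skipping a cluster


def _kadane_diag_score(q: np.ndarray, s: np.ndarray, diag: int, params: AlignParams) -> int:
    """Best ungapped run score of q vs s along one diagonal (j = i + diag)."""
    i0 = max(0, -diag)
    i1 = min(len(q), len(s) - diag)
    if i1 <= i0:
        return 0
    qs = q[i0:i1]
    ss = s[i0 + diag:i1 + diag]
    hits = (qs == ss) & (qs != 4)
    best = run = 0
    ma, mi = params.match, params.mismatch
    for h in hits.tolist():
        run = run + ma if h else run + mi
        if run < 0:
            run = 0
        elif run > best:
            best = run
    return best


def _diag_clusters(diags: list[int]) -> list[tuple[int, int]]:
    diags = sorted(set(diags))
    out = []
    lo = hi = diags[0]
    for d in diags[1:]:
        if d - hi <= _DIAG_GAP:
            hi = d
        else:
            out.append((lo, hi))
            lo = hi = d
    out.append((lo, hi))
    return out


def local_align(
    read: MergedRead,
    refs: ReferenceSet,
    params: AlignParams,
    subject_class: SubjectClass,
    index: SubjectIndex | None = None,
) -> list[ArmAlignment]:
    """Seeded local alignments of one read against a reference class.

    Exact shared words of length ``word_size`` seed banded affine-gap
    extension; hits shorter than ``min_arm_len`` on the read or with
    E-value above ``evalue_max`` are suppressed, and overlapping hits to
    the same subject are reduced to the best-scoring one.
    """
    if index is None:
        index = SubjectIndex.for_class(refs, subject_class, params)
    w = index.word_size
    seq = read.sequence
    if len(seq) < w:
        return []
    q = encode(seq)
    m = len(seq)
    n = index.total_len

    seeds: dict[int, list[int]] = {}
    for i in range(m - w + 1):
        kmer = seq[i:i + w]
        if "N" in kmer:
            continue
        for idx, p in index.kmers.get(kmer, ()):
            seeds.setdefault(idx, []).append(p - i)

    # smallest score that can pass the E-value threshold: used to prune
    # single-seed chance clusters before running the DP
    score_min = math.ceil(math.log(params.ka_K * m * n / params.evalue_max)
                          / params.ka_lambda)

    raw: list[ArmAlignment] = []
    for idx, diags in seeds.items():
        sid, strand, s_arr, s_len = index.oriented[idx]
        for lo, hi in _diag_clusters(diags):
            bound = max(
                _kadane_diag_score(q, s_arr, d, params) for d in sorted(set(diags))
                if lo <= d <= hi
            )
            if bound + _PREFILTER_MARGIN < score_min:
                continue
            res = banded_local_align(q, s_arr, lo - _BAND_PAD, hi + _BAND_PAD, params)
            if res is None:
                continue
            score, qs, qe, ss, se, mt, mm, gp, al, path = res
            if qe - qs < params.min_arm_len:
                continue
            ev = evalue_for(score, m, n, params)
            if ev > params.evalue_max:
                continue
            if strand == "-":
                ss, se = s_len - se, s_len - ss
            raw.append(ArmAlignment(
                read_id=read.id, read_interval=(qs, qe), subject_id=sid,
                subject_interval=(ss, se), strand=strand, score=score,
                evalue=ev, identity=mt / al if al else 0.0,
                subject_class=subject_class,
                aln_length=al, mismatches=mm, gaps=gp,
                path=path, subject_len=s_len,
            ))

    # reduce overlapping hits to the same subject to the best-scoring one
    raw.sort(key=lambda a: (-a.score, a.evalue, a.subject_id, a.read_interval))
    kept: list[ArmAlignment] = []
    for hit in raw:
        clash = any(
            k.subject_id == hit.subject_id
            and k.read_interval[0] < hit.read_interval[1]
            and hit.read_interval[0] < k.read_interval[1]
            for k in kept
        )
        if not clash:
            kept.append(hit)
    return kept


def trim_arm(
    arm: ArmAlignment,
    params: AlignParams,
    qstart: int | None = None,
    qend: int | None = None,
) -> ArmAlignment | None:
    """Restrict an arm alignment's read interval along its stored path.

    Used to resolve chance co-extension of two arms across a ligation
    junction: columns outside [qstart, qend) are dropped and the
    best-scoring remaining prefix/suffix of the path is kept, with score,
    identity and E-value updated exactly.  Returns None when the trimmed
    arm falls below ``min_arm_len`` or loses all positive score.
    """
    cols = list(arm.path)
    if not cols:
        return None
    if qend is not None:
        cut = next((ix for ix, c in enumerate(cols) if c[0] >= qend), len(cols))
        cols = cols[:cut]
        # best-scoring prefix of what remains
        run = best = 0
        best_ix = 0
        for ix, c in enumerate(cols):
            run += c[2]
            if run > best:
                best, best_ix = run, ix + 1
        cols = cols[:best_ix]
    if qstart is not None:
        keep_from = 0
        for ix, c in enumerate(cols):
            if c[0] != -1 and c[0] < qstart:
                keep_from = ix + 1
        cols = cols[keep_from:]
        run = best = 0
        best_ix = len(cols)
        for ix in range(len(cols) - 1, -1, -1):
            run += cols[ix][2]
            if run > best:
                best, best_ix = run, ix
        cols = cols[best_ix:]
    qpos = [c[0] for c in cols if c[0] != -1]
    spos = [c[1] for c in cols if c[1] != -1]
    if not qpos or not spos:
        return None
    score = sum(c[2] for c in cols)
    if score <= 0:
        return None
    qs, qe = min(qpos), max(qpos) + 1
    if qe - qs < params.min_arm_len:
        return None
    ss, se = min(spos), max(spos) + 1
    if arm.strand == "-":
        ss, se = arm.subject_len - se, arm.subject_len - ss
    matches = sum(1 for c in cols if c[0] != -1 and c[1] != -1 and c[2] > 0)
    mismatches = sum(1 for c in cols if c[0] != -1 and c[1] != -1 and c[2] < 0)
    gaps = sum(1 for c in cols if c[0] == -1 or c[1] == -1)
    al = len(cols)
    # E = K m n exp(-lambda S): rescale from the original hit
    ev = arm.evalue * exp(params.ka_lambda * (arm.score - score))
    if ev > params.evalue_max:
        return None
    return replace(
        arm, read_interval=(qs, qe), subject_interval=(ss, se), score=score,
        evalue=ev, identity=matches / al if al else 0.0,
        aln_length=al, mismatches=mismatches, gaps=gaps, path=tuple(cols),
    )


def refine_junction_overlaps(
    arms_by_read: dict[str, list[ArmAlignment]],
    params_mirna: AlignParams,
    params_mrna: AlignParams,
    max_overlap: int = 16,
) -> dict[str, list[ArmAlignment]]:
    """Add junction-trimmed arm variants for slightly overlapping arm pairs.

    A true ligation junction often lets both flanking alignments extend a
    few chance-matching bases past it, so the two arms overlap on the
    read and fail the disjointness rule.  For every (miRNA arm, mRNA arm)
    pair overlapping by 1..max_overlap nt, the best split point is found
    by exact path trimming and the two trimmed arms are appended to the
    read's arm list (originals are kept).
    """
    out: dict[str, list[ArmAlignment]] = {}
    for read_id, arms in arms_by_read.items():
        new = list(arms)
        mirna_arms = [a for a in arms if a.subject_class == "miRNA"]
        mrna_arms = [a for a in arms if a.subject_class == "mRNA"]
        for mi_arm in mirna_arms:
            for tx_arm in mrna_arms:
                first, second = sorted(
                    (mi_arm, tx_arm), key=lambda a: a.read_interval
                )
                ov = first.read_interval[1] - second.read_interval[0]
                if not (0 < ov <= max_overlap):
                    continue
                p_first = params_mirna if first.subject_class == "miRNA" else params_mrna
                p_second = params_mirna if second.subject_class == "miRNA" else params_mrna
                best = None
                for x in range(second.read_interval[0], first.read_interval[1] + 1):
                    a = trim_arm(first, p_first, qend=x)
                    b = trim_arm(second, p_second, qstart=x)
                    if a is None or b is None:
                        continue
                    if best is None or a.score + b.score > best[0]:
                        best = (a.score + b.score, a, b)
                if best is not None:
                    new.extend(best[1:])
        # drop exact duplicates while keeping order
        seen = set()
        dedup = []
        for a in new:
            key = (a.subject_class, a.subject_id, a.read_interval, a.score)
            if key not in seen:
                seen.add(key)
                dedup.append(a)
        out[read_id] = dedup
    return out


# ---------------------------------------------------------------------------
# contiguous end-to-end matching
# ---------------------------------------------------------------------------

@dataclass
class _Segment:
    subject_id: str
    kind: str          # 'transcript' or 'miRNA'
    strand: str
    offset: int        # start in the concatenated array
    length: int


class ContiguousMatcher:
    """Vectorised end-to-end matcher over the whole reference set.

    Finds, for a read, the reference window with the fewest mismatches
    across all subjects and strands; a band-limited (|shift| <= 2) check
    handles small indels near the best seeded diagonals.
    """

    def __init__(self, refs: ReferenceSet, include_mirnas: bool = True) -> None:
        parts: list[np.ndarray] = []
        self.segments: list[_Segment] = []
        offset = 0
        sources: list[tuple[str, str, str]] = [
            (t.id, "transcript", t.sequence) for t in refs.transcripts
        ]
        if include_mirnas:
            sources += [(mi.id, "miRNA", mi.sequence) for mi in refs.mirnas]
        for sid, kind, seq in sources:
            for strand in ("+", "-"):
                oseq = seq if strand == "+" else revcomp(seq)
                arr = encode(oseq)
                self.segments.append(_Segment(sid, kind, strand, offset, len(arr)))
                parts.append(arr)
                offset += len(arr)
        self.concat = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        self._valid_cache: dict[int, np.ndarray] = {}

    def _valid_starts(self, read_len: int) -> np.ndarray:
        mask = self._valid_cache.get(read_len)
        if mask is None:
            nwin = max(len(self.concat) - read_len + 1, 0)
            mask = np.zeros(nwin, dtype=bool)
            for seg in self.segments:
                hi = seg.offset + seg.length - read_len + 1
                if hi > seg.offset:
                    mask[seg.offset:min(hi, nwin)] = True
            self._valid_cache[read_len] = mask
        return mask

    def _segment_at(self, start: int) -> _Segment:
        for seg in self.segments:
            if seg.offset <= start < seg.offset + seg.length:
                return seg
        raise IndexError(start)

    def _ungapped_profile(self, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        L = len(q)
        if len(self.concat) < L:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
        windows = np.lib.stride_tricks.sliding_window_view(self.concat, L)
        mm = (windows != q).sum(axis=1)
        return mm, self._valid_starts(L)

    def best_ungapped(self, read_seq: str) -> tuple[int, int] | None:
        """(mismatches, concat start) of the best full-length window, or None."""
        q = encode(read_seq)
        mm, valid = self._ungapped_profile(q)
        if not valid.any():
            return None
        mm = np.where(valid, mm, np.iinfo(np.int64).max)
        s = int(np.argmin(mm))
        return int(mm[s]), s

    def _banded_mismatches(self, q: np.ndarray, start: int, max_shift: int = 2) -> int:
        """Min mismatches aligning q near concat[start:] with |shift| <= max_shift."""
        L = len(q)
        seg = self._segment_at(start)
        lo = max(seg.offset, start - max_shift)
        hi = min(seg.offset + seg.length, start + L + max_shift)
        s_arr = self.concat[lo:hi]
        off = start - lo
        INF = 10 ** 6
        shifts = list(range(-max_shift, max_shift + 1))
        # dp[sh]: min mismatches after consuming q[:i], next read base pairs
        # with subject offset i+sh; indels are free but |total shift| <= 2
        dp = {sh: 0 for sh in shifts}  # window start itself may be shifted
        for i in range(L):
            # deletion in read: skip a subject base (shift +1), no read consumed
            for sh in shifts[1:]:
                if dp[sh - 1] < dp[sh]:
                    dp[sh] = dp[sh - 1]
            nxt = {sh: INF for sh in shifts}
            for sh in shifts:
                cost = dp[sh]
                if cost >= INF:
                    continue
                j = off + i + sh
                ok = 0 <= j < len(s_arr) and q[i] == s_arr[j] and q[i] != 4
                sub = cost + (0 if ok else 1)
                if sub < nxt[sh]:
                    nxt[sh] = sub
                # insertion in read: q[i] unpaired, shift -1
                if sh - 1 in nxt and cost < nxt[sh - 1]:
                    nxt[sh - 1] = cost
            dp = nxt
        return min(dp.values())

    def is_contiguous(self, read_seq: str, max_mismatch_rate: float) -> bool:
        L = len(read_seq)
        thresh = int(max_mismatch_rate * L)
        best = self.best_ungapped(read_seq)
        if best is not None and best[0] <= thresh:
            return True
        # indel-tolerant pass: split-read seeding on half profiles
        q = encode(read_seq)
        h = L // 2
        if h < 8:
            return False
        q1, q2 = q[:h], q[h:]
        mm1, v1 = self._ungapped_profile(q1)
        mm2, v2 = self._ungapped_profile(q2)
        if not v1.any() or not v2.any():
            return False
        INF = np.iinfo(np.int64).max // 4
        mm1 = np.where(v1, mm1, INF)
        mm2 = np.where(v2, mm2, INF)
        for delta in (-2, -1, 1, 2):
            if h + delta < 0:
                continue
            shifted = mm2[h + delta:]
            if len(shifted) == 0:
                continue
            comb = mm1[:len(shifted)] + shifted
            if len(comb) == 0:
                continue
            s = int(np.argmin(comb))
            if comb[s] <= thresh + 2 and self._banded_mismatches(q, s) <= thresh:
                return True
        return False

    def place(self, read_seq: str, max_mismatch_rate: float):
        """Best end-to-end placement (subject_id, kind, strand, interval) or None."""
        L = len(read_seq)
        best = self.best_ungapped(read_seq)
        if best is None or best[0] > int(max_mismatch_rate * L):
            return None
        mm, start = best
        seg = self._segment_at(start)
        pos = start - seg.offset
        if seg.strand == "+":
            interval = (pos, pos + L)
        else:
            interval = (seg.length - (pos + L), seg.length - pos)
        return seg.subject_id, seg.kind, seg.strand, interval, mm


def filter_contiguous(
    reads: Iterable[MergedRead],
    refs: ReferenceSet,
    max_mismatch_rate: float = 0.06,
    matcher: ContiguousMatcher | None = None,
) -> list[MergedRead]:
    """Drop reads explainable as one contiguous reference match.

    A read is removed when some single reference window (any transcript or
    miRNA, either strand) covers it end to end with mismatch rate at most
    ``max_mismatch_rate`` and no indel longer than 2 nt; survivors are
    returned in input order.
    """
    if matcher is None:
        matcher = ContiguousMatcher(refs)
    out = [r for r in reads if not matcher.is_contiguous(r.sequence, max_mismatch_rate)]
    return out


def place_reads(
    reads: Iterable[MergedRead],
    refs: ReferenceSet,
    max_mismatch_rate: float = 0.06,
) -> list[tuple[str, str, tuple[int, int]]]:
    """End-to-end transcript placements (read_id, transcript_id, interval).

    Used for IP libraries: each read is assigned its best contiguous
    transcript window; unplaceable reads are skipped.
    """
    matcher = ContiguousMatcher(refs, include_mirnas=False)
    out = []
    for r in reads:
        hit = matcher.place(r.sequence, max_mismatch_rate)
        if hit is None:
            continue
        subject_id, kind, strand, interval, _mm = hit
        out.append((r.id, subject_id, interval))
    return out
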
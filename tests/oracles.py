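"""Independent brute-force oracles used to validate the package.

These deliberately avoid the package's own algorithms: full-matrix
dynamic programming, exhaustive enumeration, and plain-loop statistics.
"""

from __future__ import annotations

import math

NEG = -(10 ** 9)


# ---------------------------------------------------------------------------
# full Smith-Waterman with affine gaps (no banding, no seeding)
# ---------------------------------------------------------------------------

def sw_full(q: str, s: str, match=2, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Exhaustive local alignment; returns (best_score, path).

    path is a list of (qpos, spos) diagonal steps plus ('gap',) markers,
    ordered from alignment start to end; used to measure the longest
    exact run of the optimum.
    """
    lq, ls = len(q), len(s)
    go = gap_open + gap_extend
    ge = gap_extend
    H = [[0] * (ls + 1) for _ in range(lq + 1)]
    E = [[NEG] * (ls + 1) for _ in range(lq + 1)]
    F = [[NEG] * (ls + 1) for _ in range(lq + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, lq + 1):
        for j in range(1, ls + 1):
            E[i][j] = max(H[i][j - 1] + go, E[i][j - 1] + ge)
            F[i][j] = max(H[i - 1][j] + go, F[i - 1][j] + ge)
            sub = match if (q[i - 1] == s[j - 1] and q[i - 1] != "N") else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best == 0:
        return 0, []
    # traceback (diag preferred, then E, then F) for run-length inspection
    path = []
    i, j, state = bi, bj, "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i][j]
            if h == 0:
                break
            sub = match if (q[i - 1] == s[j - 1] and q[i - 1] != "N") else mismatch
            if H[i - 1][j - 1] + sub == h or (H[i - 1][j - 1] == 0 and sub == h):
                path.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif E[i][j] == h:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            path.append(("gap",))
            if E[i][j] == E[i][j - 1] + ge:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:
            path.append(("gap",))
            if F[i][j] == F[i - 1][j] + ge:
                i -= 1
            else:
                i -= 1
                state = "H"
    path.reverse()
    return best, path


def longest_exact_run(q: str, s: str, path) -> int:
    run = best = 0
    for step in path:
        if len(step) == 2 and q[step[0]] == s[step[1]] and q[step[0]] != "N":
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


# ---------------------------------------------------------------------------
# exhaustive contiguous-window check
# ---------------------------------------------------------------------------

def has_contiguous_window(read: str, subjects: list[str], max_mismatch_rate: float) -> bool:
    """True if some full-length window of any subject (either strand)
    matches the read with mismatch rate <= max_mismatch_rate (no indels)."""
    comp = str.maketrans("ACGTN", "TGCAN")
    L = len(read)
    thresh = int(max_mismatch_rate * L)
    for subj in subjects:
        for seq in (subj, subj.translate(comp)[::-1]):
            for start in range(len(seq) - L + 1):
                mm = sum(1 for a, b in zip(read, seq[start:start + L])
                         if a != b or a == "N")
                if mm <= thresh:
                    return True
    return False


# ---------------------------------------------------------------------------
# exhaustive chimera-pair enumeration (rules 1+2 plus tie-breaks)
# ---------------------------------------------------------------------------

def enumerate_chimeras(arms, max_gap=10):
    """Best (miRNA, mRNA) arm pair for one read, or None.

    Applies: partial alignment to a miRNA AND an mRNA (rule 1) with
    non-overlapping read intervals (rule 2), gap <= max_gap; maximal total
    score, ties to smaller gap then (miRNA id, transcript id).
    """
    candidates = []
    for mi in arms:
        if mi.subject_class != "miRNA":
            continue
        for tx in arms:
            if tx.subject_class != "mRNA":
                continue
            (ms, me), (ts, te) = mi.read_interval, tx.read_interval
            if me <= ts:
                gap = ts - me
            elif te <= ms:
                gap = ms - te
            else:
                continue
            if gap > max_gap:
                continue
            candidates.append(
                ((-(mi.score + tx.score), gap, mi.subject_id, tx.subject_id), mi, tx, gap)
            )
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[0])
    _, mi, tx, gap = candidates[0]
    return mi, tx, gap


# ---------------------------------------------------------------------------
# brute-force trimmed mean of M-values
# ---------------------------------------------------------------------------

def _avg_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tmm_oracle(counts: list[list[int]], samples: list[str],
               m_trim=0.30, a_trim=0.05) -> dict[str, float]:
    """Plain-loop TMM factors; counts is genes x samples."""
    n_samples = len(samples)
    lib = [sum(counts[g][c] for g in range(len(counts))) for c in range(n_samples)]
    # reference: upper quartile of scaled counts closest to the mean
    uqs = []
    for c in range(n_samples):
        scaled = sorted(x[c] / lib[c] for x in counts)
        # linear-interpolation quantile at 0.75 (matches pandas default)
        pos = 0.75 * (len(scaled) - 1)
        lo = math.floor(pos)
        hi = math.ceil(pos)
        uqs.append(scaled[lo] + (scaled[hi] - scaled[lo]) * (pos - lo))
    mean_uq = sum(uqs) / n_samples
    ref = min(range(n_samples), key=lambda c: (abs(uqs[c] - mean_uq), c))

    log2 = math.log2
    raw = []
    for c in range(n_samples):
        if c == ref:
            raw.append(1.0)
            continue
        ms, as_, ws = [], [], []
        for g in range(len(counts)):
            x, r = counts[g][c], counts[g][ref]
            if x <= 0 or r <= 0:
                continue
            p, pr = x / lib[c], r / lib[ref]
            ms.append(log2(p / pr))
            as_.append(0.5 * log2(p * pr))
            ws.append((lib[c] - x) / (lib[c] * x) + (lib[ref] - r) / (lib[ref] * r))
        if not ms:
            raw.append(1.0)
            continue
        n = len(ms)
        lo_m = math.floor(n * m_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * a_trim) + 1
        hi_a = n + 1 - lo_a
        rm = _avg_ranks(ms)
        ra = _avg_ranks(as_)
        kept = [g for g in range(n)
                if lo_m <= rm[g] <= hi_m and lo_a <= ra[g] <= hi_a]
        if not kept or sum(ws[g] for g in kept) == 0:
            raw.append(1.0)
            continue
        f = sum(ws[g] * ms[g] for g in kept) / sum(ws[g] for g in kept)
        raw.append(2.0 ** f)
    log_mean = sum(math.log(f) for f in raw) / n_samples
    geo = math.exp(log_mean)
    return {samples[c]: raw[c] / geo for c in range(n_samples)}


# ---------------------------------------------------------------------------
# brute-force region counting
# ---------------------------------------------------------------------------

def count_oracle(placements, regions):
    """Exhaustive interval-overlap counting with the TAR-priority rule."""
    out = {}
    for sample_id, tx_id, (rs, re) in placements:
        tx_regions = [r for r in regions if r.transcript_id == tx_id]
        if not tx_regions:
            continue
        best = None
        for r in tx_regions:
            ov = min(re, r.tar[1]) - max(rs, r.tar[0])
            if ov > 0:
                key = (-ov, r.tar[0], r.site_id)
                if best is None or key < best:
                    best = key
        if best is not None:
            out[(sample_id, f"{best[2]}:TAR")] = out.get(
                (sample_id, f"{best[2]}:TAR"), 0) + 1
            continue
        in_nt = any(
            min(re, ne) - max(rs, ns) > 0
            for ns, ne in tx_regions[0].nt3utr
        )
        if in_nt:
            key = (sample_id, f"{tx_id}:NT3UTR")
            out[key] = out.get(key, 0) + 1
    return out
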
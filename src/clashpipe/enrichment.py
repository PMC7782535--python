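"""Target-region enrichment statistic for AGO2-IP libraries.

Each predicted site is widened from its 5' end to a fixed-width extended
target region (TAR) inside the 3'-UTR; the rest of the UTR is the
non-target region (NT3UTR).  Per sample, the local enrichment of a site
is ``log2(TAR count / NT3UTR count)`` (with an optional pseudocount and
optional TMM-scaled library normalization); candidate targets are then
ranked by the drop in local enrichment from wild-type to knockout IP
samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference_io import ReferenceSet, TargetSite, TranscriptRecord

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

DEFAULT_TAR_WIDTH = 100


# ---------------------------------------------------------------------------
# region algebra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionPair:
    """A site's extended target region and its transcript's non-target UTR."""

    site_id: str
    transcript_id: str
    tar: Interval
    nt3utr: tuple[Interval, ...]

    def __post_init__(self) -> None:
        ts, te = self.tar
        if te <= ts:
            raise ValueError(f"site {self.site_id!r}: empty TAR")
        for ns, ne in self.nt3utr:
            if ns < te and ts < ne:
                raise ValueError(f"site {self.site_id!r}: NT3UTR overlaps TAR")


def extend_tar(site: TargetSite, transcript: TranscriptRecord,
               width: int = DEFAULT_TAR_WIDTH) -> Interval:
    """Extend a site's 5' end upstream to ``width`` nt, clipped to the UTR.

    Sites already at least ``width`` nt wide are returned unchanged.
    """
    start, end = site.interval
    if end - start >= width:
        return (start, end)
    utr_start = transcript.utr3[0]
    return (max(utr_start, end - width), end)


def _subtract(interval: Interval, holes: Sequence[Interval]) -> list[Interval]:
    """interval minus the union of holes, as sorted disjoint intervals."""
    s, e = interval
    pieces = [(s, e)]
    for hs, he in sorted(holes):
        nxt = []
        for ps, pe in pieces:
            if he <= ps or pe <= hs:
                nxt.append((ps, pe))
                continue
            if ps < hs:
                nxt.append((ps, hs))
            if he < pe:
                nxt.append((he, pe))
        pieces = nxt
    return pieces


def build_region_pairs(
    refs: ReferenceSet, width: int = DEFAULT_TAR_WIDTH
) -> list[RegionPair]:
    """Extend every site to a TAR and derive per-transcript NT3UTR regions.

    The NT3UTR of a transcript is its 3'-UTR minus the union of all TARs
    on that transcript, so ``|NT3UTR| + |union of TARs| = |utr3|``.
    """
    tars_by_tx: dict[str, list[tuple[TargetSite, Interval]]] = {}
    for site in refs.sites:
        tx = refs.transcript(site.transcript_id)
        tars_by_tx.setdefault(tx.id, []).append((site, extend_tar(site, tx, width)))

    out: list[RegionPair] = []
    for tx_id, pairs in tars_by_tx.items():
        tx = refs.transcript(tx_id)
        all_tars = [tar for _, tar in pairs]
        nt3utr = tuple(_subtract(tx.utr3, all_tars))
        for site, tar in pairs:
            out.append(RegionPair(site.site_id, tx_id, tar, nt3utr))
    out.sort(key=lambda r: (r.transcript_id, r.tar, r.site_id))
    return out


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Region counts (rows) by sample (columns) with genotype labels."""

    values: pd.DataFrame                  # integer counts
    genotypes: dict[str, str]             # sample -> 'IPWT' | 'IPKO'

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.genotypes)
        if missing:
            raise ValueError(f"samples without genotype label: {sorted(missing)}")
        bad = set(self.genotypes.values()) - {"IPWT", "IPKO"}
        if bad:
            raise ValueError(f"unknown genotype labels: {sorted(bad)}")

    def samples_of(self, genotype: str) -> list[str]:
        return [s for s in self.values.columns if self.genotypes[s] == genotype]


def _overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def count_regions(
    placements: Iterable[tuple[str, str, Interval]],
    regions: Sequence[RegionPair],
    genotypes: Mapping[str, str] | None = None,
) -> CountMatrix:
    """Count read placements into TAR and NT3UTR rows.

    A read counts toward a region when it overlaps it by >= 1 nt; a read
    overlapping both a TAR and NT3UTR counts toward the TAR only (the TAR
    with the largest overlap when several qualify, leftmost on ties).
    Each read counts at most once per transcript.  NT3UTR counts are kept
    per transcript (one shared row per transcript, ``<tx>:NT3UTR``),
    since all sites on a transcript share the same non-target region.
    """
    by_tx: dict[str, list[RegionPair]] = {}
    for r in regions:
        by_tx.setdefault(r.transcript_id, []).append(r)

    rows = [f"{r.site_id}:TAR" for r in regions]
    rows += sorted({f"{tx}:NT3UTR" for tx in by_tx})
    counts: dict[str, dict[str, int]] = {}

    for sample_id, tx_id, interval in placements:
        col = counts.setdefault(sample_id, dict.fromkeys(rows, 0))
        tx_regions = by_tx.get(tx_id)
        if not tx_regions:
            continue
        best = None  # (-overlap, tar_start, row)
        for r in tx_regions:
            ov = _overlap(interval, r.tar)
            if ov > 0:
                key = (-ov, r.tar[0], f"{r.site_id}:TAR")
                if best is None or key < best:
                    best = key
        if best is not None:
            col[best[2]] += 1
            continue
        if any(_overlap(interval, nt) > 0 for nt in tx_regions[0].nt3utr):
            col[f"{tx_id}:NT3UTR"] += 1

    samples = sorted(counts)
    df = pd.DataFrame({s: counts[s] for s in samples}, index=rows).fillna(0).astype(int)
    if genotypes is None:
        genotypes = {s: ("IPWT" if "WT" in s else "IPKO") for s in samples}
    return CountMatrix(df, dict(genotypes))


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _upper_quartiles(values: pd.DataFrame) -> pd.Series:
    lib = values.sum(axis=0)
    return (values / lib).quantile(0.75)


def tmm_factors(
    matrix: CountMatrix | pd.DataFrame,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, geometric mean 1.

    The reference sample is the one whose upper-quartile (of library-size
    scaled counts) is closest to the mean upper-quartile.  For each other
    sample, gene-wise M and A values against the reference are computed on
    genes with nonzero counts in both; the top and bottom ``m_trim`` of M
    and ``a_trim`` of A are trimmed (rank-based, average ties) and the
    factor is 2 to the precision-weighted mean of the surviving M values.
    """
    values = matrix.values if isinstance(matrix, CountMatrix) else matrix
    if values.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = values.sum(axis=0).astype(float)
    if (lib == 0).any():
        zero = list(lib.index[lib == 0])
        raise ValueError(f"all-zero samples: {zero}")

    uq = _upper_quartiles(values)
    ref = (uq - uq.mean()).abs().idxmin()
    r = values[ref].to_numpy(dtype=float)
    nr = lib[ref]

    factors = {}
    for sample in values.columns:
        if sample == ref:
            factors[sample] = 1.0
            continue
        x = values[sample].to_numpy(dtype=float)
        n = lib[sample]
        keep = (x > 0) & (r > 0)
        if not keep.any():
            factors[sample] = 1.0
            continue
        xs, rs = x[keep], r[keep]
        m = np.log2((xs / n) / (rs / nr))
        a = 0.5 * np.log2((xs / n) * (rs / nr))
        w = (n - xs) / (n * xs) + (nr - rs) / (nr * rs)

        ng = len(m)
        lo_m = math.floor(ng * m_trim) + 1
        hi_m = ng + 1 - lo_m
        lo_a = math.floor(ng * a_trim) + 1
        hi_a = ng + 1 - lo_a
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not sel.any() or w[sel].sum() == 0:
            factors[sample] = 1.0
            continue
        f = np.sum(w[sel] * m[sel]) / np.sum(w[sel])
        if not np.isfinite(f):
            f = 0.0
        factors[sample] = float(2.0 ** f)

    fs = pd.Series(factors)[values.columns]
    fs /= np.exp(np.mean(np.log(fs)))
    return fs


def library_scales(matrix: CountMatrix, factors: pd.Series | None = None) -> pd.Series:
    """Relative effective library sizes (TMM-scaled, geometric mean 1)."""
    lib = matrix.values.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors
    return lib / np.exp(np.mean(np.log(lib)))


# ---------------------------------------------------------------------------
# local enrichment and ranking
# ---------------------------------------------------------------------------

def local_enrichment(
    tar_count: float,
    nt3utr_count: float,
    pseudocount: float = 0.5,
    scale: float = 1.0,
) -> float:
    """``log2((tar/f + c)/(nt3utr/f + c))`` for one sample."""
    if tar_count < 0 or nt3utr_count < 0:
        raise ValueError("counts must be non-negative")
    num = tar_count / scale + pseudocount
    den = nt3utr_count / scale + pseudocount
    if den == 0:
        return math.inf if num > 0 else 0.0
    if num == 0:
        return -math.inf
    return math.log2(num / den)


@dataclass
class EnrichmentRecord:
    site_id: str
    transcript_id: str
    tar: Interval
    counts: dict[str, tuple[int, int]]        # sample -> (tar, nt3utr)
    le: dict[str, float] = field(default_factory=dict)
    delta: float = float("nan")
    rank: int = -1


def compute_enrichment(
    matrix: CountMatrix,
    regions: Sequence[RegionPair],
    pseudocount: float = 0.5,
    scales: pd.Series | None = None,
    per_kb: bool = False,
) -> list[EnrichmentRecord]:
    """Per-site, per-sample local enrichment from a region count matrix.

    ``scales`` are relative effective library sizes (see
    :func:`library_scales`); None means no between-sample normalization.
    ``per_kb`` divides counts by region length in kb before the ratio.
    """
    records = []
    for r in regions:
        tar_row = f"{r.site_id}:TAR"
        nt_row = f"{r.transcript_id}:NT3UTR"
        counts: dict[str, tuple[int, int]] = {}
        le: dict[str, float] = {}
        tar_len = r.tar[1] - r.tar[0]
        nt_len = sum(e - s for s, e in r.nt3utr)
        for sample in matrix.values.columns:
            t = int(matrix.values.at[tar_row, sample])
            n = int(matrix.values.at[nt_row, sample]) if nt_row in matrix.values.index else 0
            counts[sample] = (t, n)
            f = float(scales[sample]) if scales is not None else 1.0
            tv, nv = float(t), float(n)
            if per_kb:
                tv = tv / (tar_len / 1000.0)
                nv = nv / (nt_len / 1000.0) if nt_len else 0.0
            le[sample] = local_enrichment(tv, nv, pseudocount, f)
        records.append(EnrichmentRecord(r.site_id, r.transcript_id, r.tar, counts, le))
    return records


def rank_targets(
    records: list[EnrichmentRecord],
    matrix: CountMatrix,
    le_filter_threshold: float = 1.0,
    filter_mode: str = "wt_min",
) -> pd.DataFrame:
    """Contrast WT against KO local enrichment and rank candidate targets.

    ``delta = mean LE(WT) - mean LE(KO)``; rank 1 is the site losing the
    most IP signal in the knockout.  Filter modes: ``wt_min`` keeps sites
    with mean WT LE >= threshold (default; a true target is enriched in
    WT), ``literal_lt`` keeps sites with mean WT LE < 1, ``ko_max`` keeps
    sites with mean KO LE <= threshold.  Ties are broken by mean WT LE
    (descending) then site id.
    """
    wt = matrix.samples_of("IPWT")
    ko = matrix.samples_of("IPKO")
    if not wt or not ko:
        raise ValueError("need at least one IPWT and one IPKO sample")

    rows = []
    for rec in records:
        wt_le = float(np.mean([rec.le[s] for s in wt]))
        ko_le = float(np.mean([rec.le[s] for s in ko]))
        rec.delta = wt_le - ko_le
        if filter_mode == "wt_min" and wt_le < le_filter_threshold:
            continue
        if filter_mode == "literal_lt" and not (wt_le < 1.0):
            continue
        if filter_mode == "ko_max" and ko_le > le_filter_threshold:
            continue
        rows.append((rec, wt_le, ko_le))

    rows.sort(key=lambda t: (-t[0].delta, -t[1], t[0].site_id))
    table = []
    for rank, (rec, wt_le, ko_le) in enumerate(rows, start=1):
        rec.rank = rank
        row = {
            "site_id": rec.site_id,
            "transcript_id": rec.transcript_id,
            "tar_start": rec.tar[0],
            "tar_end": rec.tar[1],
            "wt_le": wt_le,
            "ko_le": ko_le,
            "delta": rec.delta,
            "rank": rank,
        }
        for s in list(wt) + list(ko):
            row[f"{s}_tar"] = rec.counts[s][0]
            row[f"{s}_nt3utr"] = rec.counts[s][1]
            row[f"{s}_le"] = rec.le[s]
        table.append(row)
    return pd.DataFrame(table)
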
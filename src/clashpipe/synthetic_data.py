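"""Synthetic reference and library generator with known ground truth.

Generates random miRNA/transcript references, plants seed-complementary
target sites in 3'-UTRs, and simulates two library types:

* IP libraries — 3'-UTR fragments whose sampling density is multiplied
  inside true-site TARs by a genotype-dependent fold (high in WT, unity
  in KO), converted to overlapping read pairs with substitution errors.

* Ligation (chimera) libraries — hybrid inserts made of a full or
  3'-truncated miRNA concatenated with a target-proximal UTR fragment,
  flanked by the library adapters, mixed with contiguous background
  fragments.

Every generator is a pure function of the configuration: identical
configs produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from .enrichment import DEFAULT_TAR_WIDTH, extend_tar
from .read_prep import FIVE_PRIME_ADAPTER, THREE_PRIME_ADAPTER, ReadPair
from .reference_io import MatureMiRNA, ReferenceSet, TargetSite, TranscriptRecord
from .sequtil import revcomp

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

SITE_LEN = 22
_UPSTREAM_LEN = 150          # non-UTR transcript prefix
_SLOT_MARGIN = DEFAULT_TAR_WIDTH  # head room inside each site slot for the TAR


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_mirnas: int = 8
    n_transcripts: int = 10
    utr3_len: int = 400
    n_true_sites: int = 5
    n_decoy_sites: int = 15
    wt_tar_fold: float = 8.0
    ko_tar_fold: float = 1.0
    n_ip_reads_per_sample: int = 20000
    n_samples_per_genotype: int = 2
    n_clash_reads: int = 2000
    chimera_fraction: float = 0.2
    background_fraction: float | None = None  # defaults to 1 - chimera_fraction
    error_rate: float = 0.01
    read_len: int = 101
    fragment_len_range: tuple[int, int] = (30, 60)

    def __post_init__(self) -> None:
        if self.wt_tar_fold < 1 or self.ko_tar_fold < 1:
            raise ValueError("enrichment folds must be >= 1")
        if not (0.0 <= self.chimera_fraction <= 1.0):
            raise ValueError("chimera_fraction must be in [0, 1]")
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValueError("error_rate must be in [0, 1]")
        lo, hi = self.fragment_len_range
        if not (0 < lo <= hi):
            raise ValueError("bad fragment_len_range")

    def fold(self, genotype: str) -> float:
        return self.wt_tar_fold if genotype == "WT" else self.ko_tar_fold


@dataclass
class TruthTable:
    """Ground truth for generated references and libraries."""

    true_sites: dict[str, str] = field(default_factory=dict)   # site_id -> miRNA id
    site_folds: dict[tuple[str, str], float] = field(default_factory=dict)
    read_labels: dict[str, tuple] = field(default_factory=dict)

    def is_true_site(self, site_id: str) -> bool:
        return site_id in self.true_sites


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    """Substitution errors: each base replaced by a different base w.p. error_rate."""
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    if len(hits) == 0:
        return seq
    for i in hits:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# references
# ---------------------------------------------------------------------------

def _seed_complement(mirna_seq: str) -> str:
    """Reverse complement of miRNA positions 2-8 (the canonical site match)."""
    return revcomp(mirna_seq[1:8])


def gen_references(cfg: SimConfig) -> tuple[ReferenceSet, TruthTable]:
    """Random references with planted true sites and seed-free decoy sites.

    True sites carry the reverse complement of the owning miRNA's seed
    (nt 2-8) plus a 5-nt 3'-compensatory complement; decoy site sequences
    contain no seed complement of any miRNA.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    mirnas = []
    seen: set[str] = set()
    while len(mirnas) < cfg.n_mirnas:
        seq = _rand_seq(rng, int(rng.integers(20, 24)))
        if seq in seen:
            continue
        seen.add(seq)
        mirnas.append(MatureMiRNA(f"syn-miR-{len(mirnas) + 1:03d}", seq))
    seed_comps = {_seed_complement(m.sequence) for m in mirnas}

    n_sites = cfg.n_true_sites + cfg.n_decoy_sites
    sites_per_tx = -(-n_sites // cfg.n_transcripts)  # ceil
    slot = cfg.utr3_len // max(sites_per_tx, 1)
    if slot < _SLOT_MARGIN + SITE_LEN + 2:
        raise ValueError(
            f"utr3_len={cfg.utr3_len} too small for {n_sites} sites over "
            f"{cfg.n_transcripts} transcripts"
        )

    tx_seqs = [
        list(_rand_seq(rng, _UPSTREAM_LEN + cfg.utr3_len))
        for _ in range(cfg.n_transcripts)
    ]
    utr3 = (_UPSTREAM_LEN, _UPSTREAM_LEN + cfg.utr3_len)

    # slots in round-robin transcript order; site kind order is shuffled
    kinds = ["true"] * cfg.n_true_sites + ["decoy"] * cfg.n_decoy_sites
    kinds = [kinds[i] for i in rng.permutation(n_sites)]

    sites: list[TargetSite] = []
    truth = TruthTable()
    for i, kind in enumerate(kinds):
        tx_idx = i % cfg.n_transcripts
        slot_idx = i // cfg.n_transcripts
        slot_start = utr3[0] + slot_idx * slot
        jitter_hi = slot - SITE_LEN
        start = slot_start + int(rng.integers(_SLOT_MARGIN, jitter_hi + 1))
        end = start + SITE_LEN
        site_id = f"site-{i + 1:03d}"
        tx_id = f"tx-{tx_idx + 1:03d}"
        if kind == "true":
            mi = mirnas[int(rng.integers(0, cfg.n_mirnas))]
            site_seq = list(_rand_seq(rng, SITE_LEN))
            comp3 = revcomp(mi.sequence[12:17])
            site_seq[2:2 + len(comp3)] = list(comp3)
            seed = _seed_complement(mi.sequence)
            site_seq[13:13 + len(seed)] = list(seed)
            truth.true_sites[site_id] = mi.id
            truth.site_folds[(site_id, "WT")] = cfg.wt_tar_fold
            truth.site_folds[(site_id, "KO")] = cfg.ko_tar_fold
        else:
            while True:
                site_seq = list(_rand_seq(rng, SITE_LEN))
                s = "".join(site_seq)
                if not any(sc in s for sc in seed_comps):
                    break
            truth.site_folds[(site_id, "WT")] = 1.0
            truth.site_folds[(site_id, "KO")] = 1.0
        tx_seqs[tx_idx][start:end] = site_seq
        sites.append(TargetSite(site_id, tx_id, (start, end), kind))

    transcripts = [
        TranscriptRecord(f"tx-{i + 1:03d}", "".join(tx_seqs[i]), utr3)
        for i in range(cfg.n_transcripts)
    ]
    refs = ReferenceSet(mirnas, transcripts, sites)
    return refs, truth


# ---------------------------------------------------------------------------
# IP libraries
# ---------------------------------------------------------------------------

@dataclass
class IPLibrary:
    sample_id: str
    genotype: str
    pairs: list[ReadPair]
    placements: list[tuple[str, str, tuple[int, int]]]  # (sample, tx, interval)


def _fragment_to_pair(
    rng: np.random.Generator, read_id: str, frag: str, read_len: int, error_rate: float
) -> ReadPair:
    r1 = _mutate(rng, frag[:read_len], error_rate)
    r2 = _mutate(rng, revcomp(frag)[:read_len], error_rate)
    q1, q2 = "I" * len(r1), "I" * len(r2)
    return ReadPair(read_id, r1, r2, q1, q2)


def simulate_ip_library(
    refs: ReferenceSet,
    truth: TruthTable,
    cfg: SimConfig,
    genotype: str,
    replicate: int = 0,
    emit_reads: bool = True,
) -> IPLibrary:
    """One IP sample: UTR fragments piled up at true-site TARs.

    Per-position sampling weight inside the TAR of a true site is the
    genotype's fold; elsewhere 1.  ``emit_reads=False`` skips read-pair
    construction (placements only), for fast statistic-level simulations.
    """
    if genotype not in ("WT", "KO"):
        raise ValueError(f"unknown genotype {genotype!r}")
    sample_id = f"{genotype}-{chr(65 + replicate)}-IP"
    rng = np.random.default_rng([cfg.seed, 2, 0 if genotype == "WT" else 1, replicate])
    fold = cfg.fold(genotype)

    # concatenated per-position weights over every transcript's 3'-UTR
    tx_ids, offsets, weights = [], [], []
    offset = 0
    for tx in refs.transcripts:
        us, ue = tx.utr3
        w = np.ones(ue - us)
        for site in refs.sites_on(tx.id):
            if truth.is_true_site(site.site_id):
                ts, te = extend_tar(site, tx)
                w[ts - us:te - us] = fold
        tx_ids.append(tx.id)
        offsets.append((offset, offset + len(w), us, ue))
        weights.append(w)
        offset += len(w)
    wall = np.concatenate(weights)
    wall /= wall.sum()

    n = cfg.n_ip_reads_per_sample
    anchors = rng.choice(len(wall), size=n, p=wall)
    flens = rng.integers(cfg.fragment_len_range[0], cfg.fragment_len_range[1] + 1, size=n)

    placements: list[tuple[str, str, tuple[int, int]]] = []
    pairs: list[ReadPair] = []
    starts_bounds = np.array([o[0] for o in offsets])
    for i in range(n):
        a = int(anchors[i])
        k = int(np.searchsorted(starts_bounds, a, side="right") - 1)
        o_start, _o_end, us, ue = offsets[k]
        tx = refs.transcripts[k]
        pos = us + (a - o_start)
        flen = min(int(flens[i]), ue - us)
        start = min(pos, ue - flen)
        interval = (start, start + flen)
        placements.append((sample_id, tx.id, interval))
        if emit_reads:
            frag = tx.sequence[interval[0]:interval[1]]
            pairs.append(_fragment_to_pair(
                rng, f"{sample_id}:r{i:06d}", frag, cfg.read_len, cfg.error_rate
            ))
    return IPLibrary(sample_id, genotype, pairs, placements)


# ---------------------------------------------------------------------------
# ligation (chimera) libraries
# ---------------------------------------------------------------------------

@dataclass
class ClashLibrary:
    pairs: list[ReadPair]
    truth: TruthTable


def simulate_clash_library(
    refs: ReferenceSet, truth: TruthTable, cfg: SimConfig
) -> ClashLibrary:
    """Adapter-flanked hybrid and background inserts as overlapping pairs.

    Hybrids: a full or 3'-truncated miRNA (>= 14 nt) joined to a UTR
    fragment overlapping a true site, in random orientation.  Background:
    contiguous UTR or miRNA fragments.  All inserts are flanked by the 5'
    and 3' library adapters before error injection and pair splitting.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    true_site_list = [s for s in refs.sites if truth.is_true_site(s.site_id)]
    if cfg.chimera_fraction > 0 and not true_site_list:
        raise ValueError("no true sites to build hybrids from")

    out = TruthTable(true_sites=dict(truth.true_sites),
                     site_folds=dict(truth.site_folds))
    pairs: list[ReadPair] = []
    for i in range(cfg.n_clash_reads):
        read_id = f"clash:r{i:06d}"
        if rng.random() < cfg.chimera_fraction:
            site = true_site_list[int(rng.integers(0, len(true_site_list)))]
            mi = refs.mirna(truth.true_sites[site.site_id])
            tx = refs.transcript(site.transcript_id)
            keep = int(rng.integers(14, len(mi.sequence) + 1))
            mi_part = mi.sequence[:keep]
            tl = int(rng.integers(25, 41))
            us, ue = tx.utr3
            lo = max(us, site.interval[0] - tl + 8)
            hi = min(site.interval[1] - 8, ue - tl)
            start = int(rng.integers(lo, max(lo, hi) + 1))
            frag = tx.sequence[start:start + tl]
            if rng.random() < 0.5:
                insert = mi_part + frag
            else:
                insert = frag + mi_part
            out.read_labels[read_id] = ("hybrid", mi.id, tx.id, site.site_id)
        else:
            if rng.random() < 0.5 and refs.mirnas:
                mi = refs.mirnas[int(rng.integers(0, len(refs.mirnas)))]
                keep = int(rng.integers(16, len(mi.sequence) + 1))
                insert = mi.sequence[:keep]
            else:
                tx = refs.transcripts[int(rng.integers(0, len(refs.transcripts)))]
                us, ue = tx.utr3
                bl = int(rng.integers(30, 62))
                start = int(rng.integers(us, ue - bl + 1))
                insert = tx.sequence[start:start + bl]
            out.read_labels[read_id] = ("background",)
        fragment = FIVE_PRIME_ADAPTER + insert + THREE_PRIME_ADAPTER
        pairs.append(_fragment_to_pair(rng, read_id, fragment, cfg.read_len, cfg.error_rate))
    return ClashLibrary(pairs, out)


# ---------------------------------------------------------------------------
# on-disk plumbing
# ---------------------------------------------------------------------------

def write_pairs_fastq(pairs: Iterable[ReadPair], r1_path: str | Path, r2_path: str | Path):
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.r1_seq}\n+\n{p.r1_qual or 'I' * len(p.r1_seq)}\n")
            f2.write(f"@{p.id}/2\n{p.r2_seq}\n+\n{p.r2_qual or 'I' * len(p.r2_seq)}\n")
    return Path(r1_path), Path(r2_path)


def write_truth_table(truth: TruthTable, out: str | Path) -> Path:
    out = Path(out)
    with open(out, "w") as fh:
        fh.write("#read_id\tlabel\tmirna_id\ttranscript_id\tsite_id\n")
        for read_id in sorted(truth.read_labels):
            label = truth.read_labels[read_id]
            if label[0] == "hybrid":
                fh.write(f"{read_id}\thybrid\t{label[1]}\t{label[2]}\t{label[3]}\n")
            else:
                fh.write(f"{read_id}\tbackground\t.\t.\t.\n")
    return out


def write_placements_table(placements, out: str | Path) -> Path:
    out = Path(out)
    with open(out, "w") as fh:
        fh.write("#sample_id\ttranscript_id\tstart\tend\n")
        for sample_id, tx_id, (s, e) in placements:
            fh.write(f"{sample_id}\t{tx_id}\t{s}\t{e}\n")
    return out
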
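"""Reference ingest and tabular input/output.

Handles the four reference inputs (mature miRNA FASTA, transcript FASTA,
3'-UTR interval table, target-site table) and all tabular pipeline outputs.
Every writer has a matching reader so that write->read is the identity on
valid records.

Coordinate convention: 0-based half-open, transcript-relative, everywhere
in memory.  The blast-style hit table is the single exception on disk
(1-based inclusive, converted at the boundary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .sequtil import check_alphabet, rna_to_dna

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA reference sequence (stored as DNA)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"miRNA {self.id!r}: empty sequence")
        check_alphabet(self.sequence, f"miRNA {self.id!r}")
        if not (18 <= len(self.sequence) <= 25):
            logger.warning(
                "miRNA %s has atypical length %d nt (typical 18-25)",
                self.id, len(self.sequence),
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript sequence with its annotated 3'-UTR interval."""

    id: str
    sequence: str
    utr3: tuple[int, int]  # [start, end) in transcript coordinates

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        check_alphabet(self.sequence, f"transcript {self.id!r}")
        s, e = self.utr3
        if not (0 <= s < e <= len(self.sequence)):
            raise ValueError(
                f"transcript {self.id!r}: utr3 {self.utr3} outside [0, {len(self.sequence)})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TargetSite:
    """A candidate miRNA target site on a transcript 3'-UTR."""

    site_id: str
    transcript_id: str
    interval: tuple[int, int]  # [start, end), transcript coordinates
    source_label: str = "."

    def __post_init__(self) -> None:
        s, e = self.interval
        if e <= s:
            raise ValueError(f"site {self.site_id!r}: empty interval {self.interval}")


@dataclass
class ReferenceSet:
    """All references needed by the pipeline."""

    mirnas: list[MatureMiRNA] = field(default_factory=list)
    transcripts: list[TranscriptRecord] = field(default_factory=list)
    sites: list[TargetSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._mirna_by_id = {m.id: m for m in self.mirnas}
        self._tx_by_id = {t.id: t for t in self.transcripts}
        if len(self._mirna_by_id) != len(self.mirnas):
            raise ValueError("duplicate miRNA ids in reference set")
        if len(self._tx_by_id) != len(self.transcripts):
            raise ValueError("duplicate transcript ids in reference set")
        seen: set[tuple[str, tuple[int, int]]] = set()
        for site in self.sites:
            tx = self._tx_by_id.get(site.transcript_id)
            if tx is None:
                raise ValueError(
                    f"site {site.site_id!r} references unknown transcript "
                    f"{site.transcript_id!r}"
                )
            key = (site.transcript_id, site.interval)
            if key in seen:
                raise ValueError(f"duplicate site {key} in reference set")
            seen.add(key)

    def mirna(self, mirna_id: str) -> MatureMiRNA:
        return self._mirna_by_id[mirna_id]

    def transcript(self, transcript_id: str) -> TranscriptRecord:
        return self._tx_by_id[transcript_id]

    def sites_on(self, transcript_id: str) -> list[TargetSite]:
        return [s for s in self.sites if s.transcript_id == transcript_id]


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _read_fasta(path: str | Path) -> list[tuple[str, str]]:
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    ids = [r[0] for r in records]
    dups = {i for i in ids if ids.count(i) > 1}
    if dups:
        raise ValueError(f"{path}: duplicate FASTA ids {sorted(dups)}")
    return records


def _read_tsv_rows(path: str | Path) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    return rows


def load_references(
    mirna_fasta: str | Path,
    transcript_fasta: str | Path,
    utr_table: str | Path,
    site_table: str | Path,
) -> ReferenceSet:
    """Load and validate the full reference set.

    The UTR table is a 3-column TSV (transcript_id, utr3_start, utr3_end);
    the site table is BED-like (transcript_id, start, end, site_id, source).
    U residues in either FASTA are converted to T.  Sites extending beyond
    the transcript's 3'-UTR are clipped with a warning; sites clipped to an
    empty interval are dropped with a warning.
    """
    mirnas = [MatureMiRNA(i, rna_to_dna(s)) for i, s in _read_fasta(mirna_fasta)]

    utr: dict[str, tuple[int, int]] = {}
    for row in _read_tsv_rows(utr_table):
        if len(row) < 3:
            raise ValueError(f"{utr_table}: malformed row {row}")
        tx_id, s, e = row[0], int(row[1]), int(row[2])
        if tx_id in utr:
            raise ValueError(f"{utr_table}: duplicate transcript id {tx_id!r}")
        utr[tx_id] = (s, e)

    transcripts = []
    for tx_id, seq in _read_fasta(transcript_fasta):
        if tx_id not in utr:
            raise ValueError(f"transcript {tx_id!r} missing from UTR table {utr_table}")
        transcripts.append(TranscriptRecord(tx_id, rna_to_dna(seq), utr[tx_id]))
    tx_by_id = {t.id: t for t in transcripts}

    sites: list[TargetSite] = []
    seen_site_ids: set[str] = set()
    for row in _read_tsv_rows(site_table):
        if len(row) < 4:
            raise ValueError(f"{site_table}: malformed row {row}")
        tx_id, start, end = row[0], int(row[1]), int(row[2])
        site_id = row[3]
        source = row[4] if len(row) > 4 else "."
        if site_id in seen_site_ids:
            raise ValueError(f"{site_table}: duplicate site id {site_id!r}")
        seen_site_ids.add(site_id)
        tx = tx_by_id.get(tx_id)
        if tx is None:
            raise ValueError(f"site {site_id!r} references unknown transcript {tx_id!r}")
        us, ue = tx.utr3
        cs, ce = max(start, us), min(end, ue)
        if (cs, ce) != (start, end):
            logger.warning(
                "site %s [%d,%d) extends beyond 3'-UTR [%d,%d) of %s; clipped to [%d,%d)",
                site_id, start, end, us, ue, tx_id, cs, ce,
            )
        if ce <= cs:
            logger.warning("site %s clipped to an empty interval; dropped", site_id)
            continue
        sites.append(TargetSite(site_id, tx_id, (cs, ce), source))

    refs = ReferenceSet(mirnas, transcripts, sites)
    logger.info(
        "loaded references: %d miRNAs, %d transcripts, %d sites",
        len(mirnas), len(transcripts), len(sites),
    )
    return refs


# ---------------------------------------------------------------------------
# reference writers (used by the simulator CLI)
# ---------------------------------------------------------------------------

def write_fasta(records: Iterable[tuple[str, str]], out: str | Path) -> Path:
    out = Path(out)
    with open(out, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    return out


def write_utr_table(transcripts: Iterable[TranscriptRecord], out: str | Path) -> Path:
    out = Path(out)
    with open(out, "w") as fh:
        fh.write("#transcript_id\tutr3_start\tutr3_end\n")
        for t in transcripts:
            fh.write(f"{t.id}\t{t.utr3[0]}\t{t.utr3[1]}\n")
    return out


def write_site_table(sites: Iterable[TargetSite], out: str | Path) -> Path:
    out = Path(out)
    with open(out, "w") as fh:
        fh.write("#transcript_id\tstart\tend\tsite_id\tsource\n")
        for s in sites:
            fh.write(
                f"{s.transcript_id}\t{s.interval[0]}\t{s.interval[1]}\t"
                f"{s.site_id}\t{s.source_label}\n"
            )
    return out


# ---------------------------------------------------------------------------
# chimera table
# ---------------------------------------------------------------------------

_CHIMERA_COLUMNS = [
    "read_id",
    "mirna_id", "mirna_qstart", "mirna_qend",
    "mirna_sstart", "mirna_send", "mirna_strand",
    "mirna_identity", "mirna_score", "mirna_evalue",
    "mirna_aln_len", "mirna_mismatches", "mirna_gaps",
    "transcript_id", "tx_qstart", "tx_qend",
    "tx_sstart", "tx_send", "tx_strand",
    "tx_identity", "tx_score", "tx_evalue",
    "tx_aln_len", "tx_mismatches", "tx_gaps",
    "inter_arm_gap", "orientation",
]


def write_chimera_table(calls, out: str | Path) -> Path:
    """Write chimera calls as TSV, one row per call.

    Rows are ordered by (read id, miRNA-arm read start) for determinism.
    """
    out = Path(out)
    ordered = sorted(calls, key=lambda c: (c.read_id, c.mirna_arm.read_interval[0]))
    with open(out, "w") as fh:
        fh.write("#" + "\t".join(_CHIMERA_COLUMNS) + "\n")
        for c in ordered:
            mi, tx = c.mirna_arm, c.mrna_arm
            fh.write("\t".join(str(v) for v in [
                c.read_id,
                mi.subject_id, mi.read_interval[0], mi.read_interval[1],
                mi.subject_interval[0], mi.subject_interval[1], mi.strand,
                f"{mi.identity:.6g}", mi.score, f"{mi.evalue:.6g}",
                mi.aln_length, mi.mismatches, mi.gaps,
                tx.subject_id, tx.read_interval[0], tx.read_interval[1],
                tx.subject_interval[0], tx.subject_interval[1], tx.strand,
                f"{tx.identity:.6g}", tx.score, f"{tx.evalue:.6g}",
                tx.aln_length, tx.mismatches, tx.gaps,
                c.inter_arm_gap, c.orientation,
            ]) + "\n")
    return out


def read_chimera_table(path: str | Path):
    """Inverse of :func:`write_chimera_table`."""
    from .aligner import ArmAlignment
    from .chimera import ChimeraCall

    calls = []
    for row in _read_tsv_rows(path):
        d = dict(zip(_CHIMERA_COLUMNS, row))
        mi = ArmAlignment(
            read_id=d["read_id"],
            read_interval=(int(d["mirna_qstart"]), int(d["mirna_qend"])),
            subject_id=d["mirna_id"],
            subject_interval=(int(d["mirna_sstart"]), int(d["mirna_send"])),
            strand=d["mirna_strand"],
            score=int(d["mirna_score"]),
            evalue=float(d["mirna_evalue"]),
            identity=float(d["mirna_identity"]),
            subject_class="miRNA",
            aln_length=int(d["mirna_aln_len"]),
            mismatches=int(d["mirna_mismatches"]),
            gaps=int(d["mirna_gaps"]),
        )
        tx = ArmAlignment(
            read_id=d["read_id"],
            read_interval=(int(d["tx_qstart"]), int(d["tx_qend"])),
            subject_id=d["transcript_id"],
            subject_interval=(int(d["tx_sstart"]), int(d["tx_send"])),
            strand=d["tx_strand"],
            score=int(d["tx_score"]),
            evalue=float(d["tx_evalue"]),
            identity=float(d["tx_identity"]),
            subject_class="mRNA",
            aln_length=int(d["tx_aln_len"]),
            mismatches=int(d["tx_mismatches"]),
            gaps=int(d["tx_gaps"]),
        )
        calls.append(ChimeraCall(
            read_id=d["read_id"], mirna_arm=mi, mrna_arm=tx,
            inter_arm_gap=int(d["inter_arm_gap"]), orientation=d["orientation"],
        ))
    return calls


# ---------------------------------------------------------------------------
# blast "-m 8"-style hit table (1-based inclusive on disk)
# ---------------------------------------------------------------------------

_HIT_COLUMNS = [
    "read_id", "subject_id", "identity", "length", "mismatches", "gaps",
    "qstart", "qend", "sstart", "send", "evalue", "score",
]


def write_hit_table(hits, out: str | Path) -> Path:
    """Write arm alignments in a blast tabular-like format.

    Coordinates on disk are 1-based inclusive; minus-strand hits carry
    sstart > send, as blastn does.
    """
    out = Path(out)
    with open(out, "w") as fh:
        fh.write("#" + "\t".join(_HIT_COLUMNS) + "\n")
        for h in hits:
            qs, qe = h.read_interval
            ss, se = h.subject_interval
            if h.strand == "+":
                s1, s2 = ss + 1, se
            else:
                s1, s2 = se, ss + 1
            aln_len = h.aln_length
            fh.write("\t".join(str(v) for v in [
                h.read_id, h.subject_id, f"{h.identity * 100:.2f}", aln_len,
                h.mismatches, h.gaps, qs + 1, qe, s1, s2,
                f"{h.evalue:.3g}", h.score,
            ]) + "\n")
    return out


# ---------------------------------------------------------------------------
# aggregate and enrichment tables (pandas-backed)
# ---------------------------------------------------------------------------

def write_table(df, out: str | Path) -> Path:
    """Write a pandas DataFrame as a '#'-headed TSV."""
    out = Path(out)
    with open(out, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)
    return out


def read_table(path: str | Path):
    """Inverse of :func:`write_table`."""
    import pandas as pd

    with open(path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#").split("\t")
        return pd.read_csv(fh, sep="\t", names=header, header=None)
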
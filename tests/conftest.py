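import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from clashpipe.reference_io import (
    MatureMiRNA,
    ReferenceSet,
    TargetSite,
    TranscriptRecord,
)
from clashpipe.sequtil import revcomp


@pytest.fixture
def toy_refs() -> ReferenceSet:
    """Two miRNAs, two transcripts, two sites; handcrafted and tiny."""
    mir_a = MatureMiRNA("miR-a", "ACGTACGTACGTACGTACGTAC")      # 22 nt
    mir_b = MatureMiRNA("miR-b", "TTGGCCAATTGGCCAATTGGCC")      # 22 nt
    import random

    rng = random.Random(42)
    body1 = "".join(rng.choice("ACGT") for _ in range(300))
    body2 = "".join(rng.choice("ACGT") for _ in range(300))
    tx1 = TranscriptRecord("tx-1", body1, (50, 300))
    tx2 = TranscriptRecord("tx-2", body2, (50, 300))
    sites = [
        TargetSite("s1", "tx-1", (200, 222), "toy"),
        TargetSite("s2", "tx-2", (100, 122), "toy"),
    ]
    return ReferenceSet([mir_a, mir_b], [tx1, tx2], sites)


@pytest.fixture
def ref_files(tmp_path, toy_refs):
    """The toy reference set written to disk in the supported formats."""
    from clashpipe.reference_io import write_fasta, write_site_table, write_utr_table

    mirna_fasta = tmp_path / "mirnas.fasta"
    tx_fasta = tmp_path / "transcripts.fasta"
    write_fasta(((m.id, m.sequence) for m in toy_refs.mirnas), mirna_fasta)
    write_fasta(((t.id, t.sequence) for t in toy_refs.transcripts), tx_fasta)
    utr = write_utr_table(toy_refs.transcripts, tmp_path / "utr3.tsv")
    sites = write_site_table(toy_refs.sites, tmp_path / "sites.tsv")
    return dict(
        mirna_fasta=mirna_fasta, transcript_fasta=tx_fasta,
        utr_table=utr, site_table=sites,
    )


def make_arm(
    read_id="r1",
    read_interval=(0, 22),
    subject_id="miR-a",
    subject_class="miRNA",
    score=40,
    subject_interval=None,
    strand="+",
    evalue=1e-6,
):
    """Convenience constructor for ArmAlignment test objects."""
    from clashpipe.aligner import ArmAlignment

    if subject_interval is None:
        subject_interval = (0, read_interval[1] - read_interval[0])
    length = read_interval[1] - read_interval[0]
    return ArmAlignment(
        read_id=read_id, read_interval=read_interval, subject_id=subject_id,
        subject_interval=subject_interval, strand=strand, score=score,
        evalue=evalue, identity=1.0, subject_class=subject_class,
        aln_length=length, mismatches=0, gaps=0,
    )
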
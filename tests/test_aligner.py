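import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clashpipe.aligner import (
    AlignParams,
    ContiguousMatcher,
    SubjectIndex,
    banded_local_align,
    evalue_for,
    filter_contiguous,
    local_align,
    place_reads,
    trim_arm,
)
from clashpipe.read_prep import MergedRead
from clashpipe.reference_io import MatureMiRNA, ReferenceSet, TranscriptRecord
from clashpipe.sequtil import encode, revcomp

import oracles

WIDE_OPEN = AlignParams(evalue_max=1e12, min_arm_len=7)


def _read(seq, rid="r"):
    return MergedRead(rid, seq, 30, merged=True)


def _refs_single_tx(tx_seq):
    mi = MatureMiRNA("m-pad", "ACGT" * 5)  # inert filler so the set is non-empty
    tx = TranscriptRecord("tx", tx_seq, (0, len(tx_seq)))
    return ReferenceSet([mi], [tx], [])


def _rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestAlignParams:
    def test_word_size_floor(self):
        with pytest.raises(ValueError):
            AlignParams(word_size=3)

    def test_min_arm_len_vs_word_size(self):
        with pytest.raises(ValueError):
            AlignParams(min_arm_len=5)

    def test_evalue_positive(self):
        with pytest.raises(ValueError):
            AlignParams(evalue_max=0)


class TestEvalue:
    def test_decreasing_in_score(self):
        p = AlignParams()
        evs = [evalue_for(s, 50, 1000, p) for s in range(10, 60)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_increasing_in_search_space(self):
        p = AlignParams()
        evs = [evalue_for(30, 50, n, p) for n in (100, 1000, 10000)]
        assert evs[0] < evs[1] < evs[2]


class TestBandedVsOracle:
    @pytest.mark.parametrize("seed", range(30))
    def test_full_band_equals_full_sw(self, seed):
        rng = random.Random(seed)
        q = _rand_seq(rng, rng.randint(20, 60))
        s = _rand_seq(rng, rng.randint(30, 100))
        frag = list(q[rng.randint(0, 5):rng.randint(15, len(q))])
        for _ in range(rng.randint(0, 3)):
            i = rng.randrange(len(frag))
            op = rng.random()
            if op < 0.5:
                frag[i] = rng.choice("ACGT")
            elif op < 0.75:
                frag.insert(i, rng.choice("ACGT"))
            else:
                del frag[i]
        pos = rng.randint(0, max(0, len(s) - len(frag)))
        s = s[:pos] + "".join(frag) + s[pos + len(frag):]
        oracle, _ = oracles.sw_full(q, s)
        got = banded_local_align(encode(q), encode(s), -len(q), len(s), WIDE_OPEN)
        assert (got[0] if got else 0) == oracle

    def test_path_score_consistency(self):
        rng = random.Random(1)
        q = _rand_seq(rng, 40)
        s = q[5:35] + _rand_seq(rng, 30)
        res = banded_local_align(encode(q), encode(s), -len(q), len(s), WIDE_OPEN)
        score, qs, qe, ss, se, mt, mm, gp, al, path = res
        assert sum(c[2] for c in path) == score
        assert mt + mm + gp == al == len(path)


class TestLocalAlign:
    def test_exact_mirna_copy_one_hit(self):
        rng = random.Random(2)
        mi = MatureMiRNA("miR-x", _rand_seq(rng, 22))
        tx = TranscriptRecord("tx", _rand_seq(rng, 200), (0, 200))
        refs = ReferenceSet([mi], [tx], [])
        read = _read(_rand_seq(rng, 10) + mi.sequence + _rand_seq(rng, 15))
        hits = local_align(read, refs, AlignParams(evalue_max=10), "miRNA")
        assert len(hits) == 1
        h = hits[0]
        assert h.read_interval == (10, 32)
        assert h.subject_interval == (0, 22)
        assert h.identity == 1.0
        assert h.strand == "+"
        assert h.subject_class == "miRNA"

    def test_no_shared_word_no_hits(self):
        mi = MatureMiRNA("miR-x", "A" * 22)
        tx = TranscriptRecord("tx", "A" * 100, (0, 100))
        refs = ReferenceSet([mi], [tx], [])
        read = _read("C" * 40)
        assert local_align(read, refs, AlignParams(), "miRNA") == []
        assert local_align(read, refs, AlignParams(), "mRNA") == []

    def test_minus_strand_hit_maps_to_forward_coords(self):
        rng = random.Random(4)
        tx_seq = _rand_seq(rng, 150)
        refs = _refs_single_tx(tx_seq)
        # read contains the reverse complement of tx[40:70)
        read = _read(_rand_seq(rng, 8) + revcomp(tx_seq[40:70]) + _rand_seq(rng, 8))
        hits = local_align(read, refs, AlignParams(evalue_max=0.1), "mRNA")
        minus = [h for h in hits if h.strand == "-"]
        assert minus
        ss, se = minus[0].subject_interval
        # the planted window is contained (chance matches may extend the hit)
        assert ss <= 40 and se >= 70
        assert minus[0].score >= 60

    def test_planted_match_scores_match_oracle(self):
        """Toy case from the module contract: 18-nt match with one mismatch."""
        rng = random.Random(6)
        subject = _rand_seq(rng, 30)
        core = list(subject[6:24])
        core[9] = "A" if core[9] != "A" else "C"
        read = _rand_seq(rng, 12) + "".join(core) + _rand_seq(rng, 10)
        refs = _refs_single_tx(subject)
        oracle, _ = oracles.sw_full(read, subject)
        hits = local_align(_read(read), refs, WIDE_OPEN, "mRNA")
        plus = [h for h in hits if h.strand == "+"]
        assert plus and max(h.score for h in plus) == oracle

    def test_evalue_threshold_suppresses_weak_hits(self):
        rng = random.Random(8)
        tx_seq = _rand_seq(rng, 2000)
        refs = _refs_single_tx(tx_seq)
        read = _read(tx_seq[100:114] + _rand_seq(rng, 30))  # 14-nt arm
        strict = local_align(_read(read.sequence), refs,
                             AlignParams(evalue_max=1e-9), "mRNA")
        loose = local_align(_read(read.sequence), refs,
                            AlignParams(evalue_max=10), "mRNA")
        assert len(strict) <= len(loose)
        assert all(h.evalue <= 1e-9 for h in strict)

    def test_overlapping_hits_same_subject_reduced(self):
        rng = random.Random(10)
        tx_seq = _rand_seq(rng, 300)
        refs = _refs_single_tx(tx_seq)
        read = _read(tx_seq[50:90])
        hits = local_align(_read(read.sequence), refs, WIDE_OPEN, "mRNA")
        by_subject = [h for h in hits if h.subject_id == "tx"]
        for i, a in enumerate(by_subject):
            for b in by_subject[i + 1:]:
                overlap = (a.read_interval[0] < b.read_interval[1]
                           and b.read_interval[0] < a.read_interval[1])
                assert not overlap

    def test_min_arm_len_enforced(self):
        rng = random.Random(12)
        tx_seq = _rand_seq(rng, 500)
        refs = _refs_single_tx(tx_seq)
        read = _read(tx_seq[10:50])
        hits = local_align(_read(read.sequence), refs,
                           AlignParams(min_arm_len=20, evalue_max=10), "mRNA")
        assert all(h.read_interval[1] - h.read_interval[0] >= 20 for h in hits)


class TestSeededEquivalence:
    """Seeded aligner vs exhaustive DP when the optimum has a >= word-size run."""

    @pytest.mark.parametrize("seed", range(40))
    def test_best_score_equality(self, seed):
        rng = random.Random(1000 + seed)
        subject = _rand_seq(rng, rng.randint(40, 100))
        read_len = rng.randint(20, 60)
        core_len = rng.randint(12, min(read_len, len(subject)) - 2)
        spos = rng.randint(0, len(subject) - core_len)
        core = list(subject[spos:spos + core_len])
        for _ in range(rng.randint(0, 2)):
            i = rng.randrange(len(core))
            if rng.random() < 0.7:
                core[i] = rng.choice("ACGT")
            elif rng.random() < 0.5 and len(core) > 13:
                del core[i]
            else:
                core.insert(i, rng.choice("ACGT"))
        pad = read_len - len(core)
        left = rng.randint(0, max(pad, 0)) if pad > 0 else 0
        read = _rand_seq(rng, left) + "".join(core) + _rand_seq(rng, max(pad - left, 0))

        best, path = oracles.sw_full(read, subject)
        if best == 0 or oracles.longest_exact_run(read, subject, path) < 7:
            pytest.skip("optimum lacks a seed-length exact run")
        refs = _refs_single_tx(subject)
        hits = [h for h in local_align(_read(read), refs, WIDE_OPEN, "mRNA")
                if h.strand == "+"]
        assert hits and max(h.score for h in hits) == best


class TestTrimArm:
    def test_trim_shortens_and_rescores(self):
        rng = random.Random(20)
        subject = _rand_seq(rng, 60)
        read = subject[10:40] + _rand_seq(rng, 10)
        refs = _refs_single_tx(subject)
        [hit] = [h for h in local_align(_read(read), refs, WIDE_OPEN, "mRNA")
                 if h.strand == "+"]
        trimmed = trim_arm(hit, WIDE_OPEN, qend=20)
        assert trimmed is not None
        assert trimmed.read_interval == (0, 20)
        assert trimmed.score == 40  # 20 matches at +2
        assert trimmed.evalue > hit.evalue

    def test_trim_below_min_arm_len_returns_none(self):
        rng = random.Random(21)
        subject = _rand_seq(rng, 60)
        read = subject[10:40]
        refs = _refs_single_tx(subject)
        [hit] = [h for h in local_align(_read(read), refs, WIDE_OPEN, "mRNA")
                 if h.strand == "+"]
        assert trim_arm(hit, AlignParams(min_arm_len=12, evalue_max=1e12),
                        qend=5) is None


class TestContiguityFilter:
    def _refs(self, seed=0):
        rng = random.Random(seed)
        tx1 = TranscriptRecord("t1", _rand_seq(rng, 400), (0, 400))
        tx2 = TranscriptRecord("t2", _rand_seq(rng, 400), (0, 400))
        mi = MatureMiRNA("m1", _rand_seq(rng, 22))
        return ReferenceSet([mi], [tx1, tx2], [])

    def test_exact_substring_removed(self):
        refs = self._refs()
        read = _read(refs.transcripts[0].sequence[100:150])
        assert filter_contiguous([read], refs) == []

    def test_minus_strand_substring_removed(self):
        refs = self._refs()
        read = _read(revcomp(refs.transcripts[0].sequence[100:150]))
        assert filter_contiguous([read], refs) == []

    def test_mirna_fragment_removed(self):
        refs = self._refs()
        read = _read(refs.mirnas[0].sequence)
        assert filter_contiguous([read], refs) == []

    def test_chimeric_concatenation_retained(self):
        refs = self._refs()
        read = _read(refs.mirnas[0].sequence
                     + refs.transcripts[1].sequence[50:80])
        # oracle: no single contiguous window explains the read
        subjects = [t.sequence for t in refs.transcripts] + [
            m.sequence for m in refs.mirnas]
        assert not oracles.has_contiguous_window(read.sequence, subjects, 0.06)
        assert filter_contiguous([read], refs) == [read]

    def test_empty_input(self):
        assert filter_contiguous([], self._refs()) == []

    def test_small_indel_still_removed(self):
        refs = self._refs()
        window = refs.transcripts[0].sequence[100:150]
        read = _read(window[:25] + window[26:])  # 1-nt deletion
        assert filter_contiguous([read], refs) == []

    def test_survivors_keep_input_order(self):
        refs = self._refs()
        rng = random.Random(99)
        keep1 = _read(refs.mirnas[0].sequence
                      + refs.transcripts[1].sequence[50:80], "a")
        drop = _read(refs.transcripts[0].sequence[10:60], "b")
        keep2 = _read(refs.mirnas[0].sequence
                      + refs.transcripts[0].sequence[200:230], "c")
        out = filter_contiguous([keep1, drop, keep2], refs)
        assert [r.id for r in out] == ["a", "c"]

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_oracle(self, seed):
        refs = self._refs(seed)
        rng = random.Random(500 + seed)
        subjects = [t.sequence for t in refs.transcripts] + [
            m.sequence for m in refs.mirnas]
        reads = []
        for i in range(10):
            kind = rng.random()
            if kind < 0.4:
                start = rng.randint(0, 350)
                seq = refs.transcripts[rng.randint(0, 1)].sequence[start:start + 40]
            elif kind < 0.6:
                seq = list(refs.transcripts[0].sequence[100:140])
                for _ in range(rng.randint(0, 3)):
                    p = rng.randrange(len(seq))
                    seq[p] = rng.choice("ACGT")
                seq = "".join(seq)
            else:
                seq = _rand_seq(rng, 40)
            reads.append(_read(seq, f"r{i}"))
        got = {r.id for r in filter_contiguous(reads, refs, 0.06)}
        # oracle ignores indels, so only check the no-indel decision boundary
        expect = {r.id for r in reads
                  if not oracles.has_contiguous_window(r.sequence, subjects, 0.06)}
        # our filter may additionally drop indel-contiguous reads; none here
        assert got == expect


class TestPlaceReads:
    def test_placement_recovers_fragment_coordinates(self):
        rng = random.Random(30)
        tx = TranscriptRecord("t1", _rand_seq(rng, 400), (0, 400))
        refs = ReferenceSet([], [tx], [])
        read = _read(tx.sequence[120:170], "p1")
        placed = place_reads([read], refs)
        assert placed == [("p1", "t1", (120, 170))]

    def test_unplaceable_read_skipped(self):
        rng = random.Random(31)
        tx = TranscriptRecord("t1", _rand_seq(rng, 400), (0, 400))
        refs = ReferenceSet([], [tx], [])
        read = _read(_rand_seq(random.Random(99), 50), "junk")
        assert place_reads([read], refs) == []
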
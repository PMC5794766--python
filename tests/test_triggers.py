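import numpy as np
import pytest

from trigger_forge import triggers as tg
from trigger_forge.seq import OrfAnnotation, SequenceRecord, principal_orf, reverse_complement
from trigger_forge.synth import SynthSpec, generate_transcriptome

from .oracles import brute_windows


def random_nt(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


@pytest.fixture(scope="module")
def transcript_with_orf():
    recs, orfs = generate_transcriptome(
        SynthSpec(seed=77, n_transcripts=1, length_range=(1200, 1400))
    )
    return recs[0], orfs[0]


class TestEnumerateWindows:
    def test_strict_margin_boundary(self, transcript_with_orf):
        rec, orf = transcript_with_orf
        ws, _ = tg.enumerate_windows(rec, orf, step=1)
        assert ws, "fixture must admit windows"
        for w in ws:
            assert w.start - orf.start > 70
            assert orf.end - w.end > 70
        # a start at distance exactly 70 must never appear; 71 is legal
        starts = {w.start - orf.start for w in ws}
        assert 70 not in starts
        assert min(starts) == 71

    def test_all_at_transcript_has_no_accepted_windows(self):
        seq = "ATG" + "AAT" * 200 + "TAA"
        rec = SequenceRecord("at", seq)
        orf = OrfAnnotation("at", 0, len(seq))
        ws, _ = tg.enumerate_windows(rec, orf, step=1)
        assert [w for w in ws if w.accepted] == []

    def test_short_orf_yields_reason_code(self):
        seq = "ATG" + "GCA" * 80 + "TAA"  # interior too short for margins+200
        rec = SequenceRecord("s", seq)
        orf = OrfAnnotation("s", 0, len(seq))
        ws, reason = tg.enumerate_windows(rec, orf, step=1)
        assert ws == [] and reason == "orf_too_short"

    def test_step1_equals_brute_force(self, transcript_with_orf):
        rec, orf = transcript_with_orf
        ws, _ = tg.enumerate_windows(rec, orf, step=1)
        got = {(w.start, w.end) for w in ws if w.accepted}
        assert got == brute_windows(rec.residues, orf.start, orf.end)

    def test_gc_bounds_inclusive(self):
        # engineered interior: windows of exactly 40% and 60% GC exist
        rng = np.random.default_rng(5)
        block40 = ("GC" + "AT" * 4) * 30  # 300 nt at exactly 40% GC? no: 2GC/10 = 20%
        # build explicit 200-nt runs: 80 GC + 120 AT -> 40%; 120 GC + 80 AT -> 60%
        win40 = "G" * 40 + "ATAT" * 30 + "C" * 40  # 200 nt, 80 GC
        win60 = "G" * 60 + "ATAT" * 20 + "C" * 60  # 200 nt, 120 GC
        assert len(win40) == len(win60) == 200
        filler = random_nt(rng, 71)
        body = filler + win40 + win60 + filler
        ncod = len(body) // 3 * 3
        seq = "ATG" + body[:ncod] + "TAA"
        # keep the reading frame stop-free is irrelevant: pass the ORF explicitly
        rec = SequenceRecord("gc", seq)
        orf = OrfAnnotation("gc", 0, len(seq) // 3 * 3)
        ws, _ = tg.enumerate_windows(rec, orf, step=1)
        gcs = {round(w.gc_pct, 4) for w in ws if w.accepted}
        assert 40.0 in gcs and 60.0 in gcs
        assert all(40.0 <= w.gc_pct <= 60.0 for w in ws)

    def test_n_window_flagged_not_dropped(self, transcript_with_orf):
        rec, orf = transcript_with_orf
        residues = list(rec.residues)
        ws0, _ = tg.enumerate_windows(rec, orf, step=10)
        target = ws0[0]
        residues[target.start + 5] = "N"
        recN = SequenceRecord(rec.id, "".join(residues))
        wsN, _ = tg.enumerate_windows(recN, orf, step=10)
        flagged = [w for w in wsN if "contains_N" in w.flags]
        assert flagged and all("N" in w.sequence(recN) for w in flagged)


class TestScreenWindows:
    @pytest.fixture()
    def screening_setup(self, transcript_with_orf):
        rec, orf = transcript_with_orf
        ws, _ = tg.enumerate_windows(rec, orf, step=10)
        accepted = [w for w in ws if w.accepted]
        return rec, accepted

    def test_planted_21mer_flagged_and_20mer_passes(self, screening_setup):
        rec, ws = screening_setup
        w = ws[0]
        probe21 = w.sequence(rec)[10:31]
        rng = np.random.default_rng(6)
        bg = random_nt(rng, 300)
        offdb = {"bee": [SequenceRecord("bee_t1", bg + probe21 + bg)]}
        out = tg.screen_windows([w], rec, offdb)
        assert "offtarget_hit" in out[0].flags
        offdb20 = {"bee": [SequenceRecord("bee_t1", bg + probe21[:20] + bg)]}
        out20 = tg.screen_windows([w], rec, offdb20)
        assert "offtarget_hit" not in out20[0].flags

    def test_revcomp_strand_also_screened(self, screening_setup):
        rec, ws = screening_setup
        w = ws[0]
        probe = reverse_complement(w.sequence(rec)[20:45])
        offdb = {"mouse": [SequenceRecord("m1", "ACGT" * 20 + probe + "TTTT" * 20)]}
        out = tg.screen_windows([w], rec, offdb)
        assert "offtarget_hit" in out[0].flags

    def test_monotone_in_k(self, screening_setup):
        rec, ws = screening_setup
        w = ws[0]
        probe22 = w.sequence(rec)[40:62]
        offdb = {"bee": [SequenceRecord("b", "AC" * 50 + probe22 + "GT" * 50)]}
        at21 = tg.screen_windows([w], rec, offdb,
                                 constraints=tg.TriggerConstraints(offtarget_k=21))
        at22 = tg.screen_windows([w], rec, offdb,
                                 constraints=tg.TriggerConstraints(offtarget_k=22))
        assert "offtarget_hit" in at22[0].flags
        assert "offtarget_hit" in at21[0].flags  # flagged at 22 => flagged at 21

    def test_motif_exclusion(self, screening_setup):
        rec, ws = screening_setup
        w = ws[0]
        motif = w.sequence(rec)[:6]
        with pytest.warns(UserWarning):  # empty off-target set also warns
            out = tg.screen_windows([w], rec, {}, exclusion_motifs=[motif])
        assert "excluded_motif" in out[0].flags

    def test_empty_offtarget_warns_and_passes(self, screening_setup):
        rec, ws = screening_setup
        with pytest.warns(UserWarning):
            out = tg.screen_windows(ws, rec, {})
        assert all(w.accepted for w in out)


class TestRankWindows:
    def _win(self, start, length, gc):
        return tg.TriggerWindow("t", start, start + length, gc, 100, 100)

    def test_gc_closest_to_50_first(self):
        ranked = tg.rank_windows([self._win(0, 300, 58.0), self._win(400, 300, 50.0)])
        assert ranked[0].gc_pct == 50.0

    def test_equal_gc_longer_first(self):
        ranked = tg.rank_windows([self._win(0, 300, 55.0), self._win(400, 480, 55.0)])
        assert ranked[0].length == 480

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        wins = [self._win(int(rng.integers(0, 5000)), int(rng.integers(200, 500)),
                          float(rng.uniform(40, 60))) for _ in range(30)]
        a = tg.rank_windows(wins)
        perm = [wins[i] for i in rng.permutation(len(wins))]
        b = tg.rank_windows(perm)
        assert [(w.start, w.end) for w in a] == [(w.start, w.end) for w in b]

    def test_flagged_window_rejected(self):
        w = tg.TriggerWindow("t", 0, 300, 50.0, 100, 100, frozenset({"contains_N"}))
        with pytest.raises(ValueError):
            tg.rank_windows([w])


class TestDeriveSubregions:
    def test_split_mode_disjoint_children(self, transcript_with_orf):
        rec, orf = transcript_with_orf
        ws, _ = tg.enumerate_windows(rec, orf, step=10)
        parent = next(w for w in ws if w.accepted and w.length >= 400)
        kids = tg.derive_subregions(parent, rec, "non_overlapping_split",
                                    [180, 180], orf=orf)
        (a, b) = (kids[0].window, kids[1].window)
        assert a.end <= b.start
        assert kids[0].label == "v1" and kids[1].label == "v2"
        assert a.start >= parent.start and b.end <= parent.end
        assert all(k.relation == "disjoint_sibling" for k in kids)

    def test_nested_identical_degenerate(self, transcript_with_orf):
        rec, orf = transcript_with_orf
        ws, _ = tg.enumerate_windows(rec, orf, step=10)
        parent = next(w for w in ws if w.accepted)
        kids = tg.derive_subregions(parent, rec, "nested", [parent.length], orf=orf)
        assert kids[0].relation == "identical"

    def test_child_longer_than_parent_is_error(self, transcript_with_orf):
        rec, orf = transcript_with_orf
        ws, _ = tg.enumerate_windows(rec, orf, step=10)
        parent = next(w for w in ws if w.accepted)
        with pytest.raises(ValueError):
            tg.derive_subregions(parent, rec, "nested", [parent.length + 10])


class TestT7Template:
    def test_both_primers_start_with_promoter(self):
        t = tg.make_t7_template("ATGCATGCATGCATGCATGCATGC", 20)
        assert t.fwd_primer.startswith("TAATACGACTCACTATAGGGAGA")
        assert t.rev_primer.startswith("TAATACGACTCACTATAGGGAGA")
        assert len(tg.T7_PROMOTER) == 23

    def test_reverse_primer_body_is_revcomp_of_three_prime_end(self):
        t = tg.make_t7_template("ATGGGGGGGGGGGGGGGGGCAT", 3)
        assert t.rev_primer == tg.T7_PROMOTER + "ATG"

    def test_insert_too_short(self):
        with pytest.raises(ValueError):
            tg.make_t7_template("ATG", 20)
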
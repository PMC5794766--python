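"""dsRNA trigger-window enumeration, screening, ranking, sub-region
derivation, and T7 synthesis templates.

A trigger window is a candidate dsRNA region inside a transcript's principal
ORF. The design constraints: length 200-500 nt, GC between 40 and 60
percent (inclusive), and a distance of strictly more than 70 nt between the
window and both the ATG and the stop codon. Off-target screening flags any
window sharing a contiguous match of 21 nt or longer (either strand of the
dsRNA) with any sequence in a non-target transcriptome set.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

from .seq import (
    BedInterval,
    OrfAnnotation,
    SequenceRecord,
    gc_content,
    reverse_complement,
)

T7_PROMOTER = "TAATACGACTCACTATAGGGAGA"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[GC]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass
class TriggerConstraints:
    """Published design constraints for dsRNA trigger windows."""

    len_min: int = 200
    len_max: int = 500
    gc_min: float = 40.0
    gc_max: float = 60.0
    orf_margin: int = 70  # strict: distance to ATG/stop must exceed this
    offtarget_k: int = 21

    def __post_init__(self) -> None:
        if self.len_min > self.len_max:
            raise ValueError("len_min must not exceed len_max")
        if self.gc_min > self.gc_max:
            raise ValueError("gc_min must not exceed gc_max")
        if self.orf_margin < 0:
            raise ValueError("orf_margin must be >= 0")


@dataclass(frozen=True)
class TriggerWindow:
    """A candidate dsRNA region, 0-based half-open on the transcript."""

    transcript_id: str
    start: int
    end: int
    gc_pct: float
    margin_5: int  # window.start - orf.start
    margin_3: int  # orf.end - window.end
    flags: frozenset[str] = frozenset()
    rank_score: float = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def accepted(self) -> bool:
        return not self.flags

    def sequence(self, transcript: SequenceRecord) -> str:
        return transcript.residues[self.start : self.end]


def enumerate_windows(
    transcript: SequenceRecord,
    orf: OrfAnnotation,
    constraints: TriggerConstraints | None = None,
    step: int = 10,
    exclusion_intervals: Sequence[tuple[int, int]] = (),
) -> tuple[list[TriggerWindow], str | None]:
    """All candidate windows at the given enumeration step.

    Emitted windows satisfy length, GC (inclusive bounds) and the strict
    margin rule; windows containing N or intersecting an exclusion interval
    are emitted carrying flags rather than silently dropped. Returns
    (windows, reason) where reason is a code when no window is geometrically
    possible. Order is deterministic: by start, then length.
    """
    c = constraints or TriggerConstraints()
    if orf.seq_id != transcript.id:
        raise ValueError("ORF does not belong to this transcript")
    if step < 1:
        raise ValueError("step must be >= 1")
    lo = orf.start + c.orf_margin + 1
    hi = orf.end - c.orf_margin - 1  # exclusive bound for window end
    if hi - lo < c.len_min:
        return [], "orf_too_short"
    # prefix sums so step=1 enumeration stays linear per window
    res = transcript.residues
    gc_pre = [0] * (len(res) + 1)
    n_pre = [0] * (len(res) + 1)
    for i, ch in enumerate(res):
        gc_pre[i + 1] = gc_pre[i] + (ch in "GC")
        n_pre[i + 1] = n_pre[i] + (ch == "N")
    windows: list[TriggerWindow] = []
    for start in range(lo, hi - c.len_min + 1, step):
        for length in range(c.len_min, c.len_max + 1, step):
            end = start + length
            if end > hi:
                break
            gc = 100.0 * (gc_pre[end] - gc_pre[start]) / length
            if not (c.gc_min <= gc <= c.gc_max):
                continue
            flags = set()
            if n_pre[end] - n_pre[start]:
                flags.add("contains_N")
            if any(start < e and s < end for s, e in exclusion_intervals):
                flags.add("excluded_motif")
            windows.append(
                TriggerWindow(
                    transcript.id, start, end, gc,
                    start - orf.start, orf.end - end, frozenset(flags),
                )
            )
    return windows, None


def _motif_regex(motif: str) -> re.Pattern[str]:
    try:
        return re.compile("".join(_IUPAC[ch] for ch in motif.upper()))
    except KeyError as exc:
        raise ValueError(f"motif {motif!r}: illegal IUPAC symbol {exc}") from None


def screen_windows(
    windows: Sequence[TriggerWindow],
    transcript: SequenceRecord,
    offtarget_dbs: Mapping[str, Sequence[SequenceRecord]],
    exclusion_motifs: Sequence[str] = (),
    constraints: TriggerConstraints | None = None,
) -> list[TriggerWindow]:
    """Resolve off-target and motif flags on candidate windows.

    A window gains ``offtarget_hit`` iff it shares a contiguous match of at
    least ``offtarget_k`` nt — on either strand of the dsRNA — with any
    sequence in any off-target set. It gains ``excluded_motif`` iff a
    supplied IUPAC motif occurs inside it. Screening against an empty
    off-target collection passes every window but warns.
    """
    c = constraints or TriggerConstraints()
    if not offtarget_dbs or all(len(v) == 0 for v in offtarget_dbs.values()):
        warnings.warn("off-target screen ran against an empty set; every window passes",
                      stacklevel=2)
    patterns = [_motif_regex(m) for m in exclusion_motifs]
    # a shared match of >= k nt exists iff a shared k-mer exists, so one
    # k-mer set over the off-target collection decides every window
    k = c.offtarget_k
    offtarget_kmers: set[str] = set()
    for db in offtarget_dbs.values():
        for rec in db:
            s = rec.residues
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                if "N" not in kmer:
                    offtarget_kmers.add(kmer)
    out: list[TriggerWindow] = []
    for w in windows:
        flags = set(w.flags)
        seq = w.sequence(transcript)
        strands = (seq, reverse_complement(seq))
        if offtarget_kmers and any(
            s[i : i + k] in offtarget_kmers
            for s in strands
            for i in range(len(s) - k + 1)
        ):
            flags.add("offtarget_hit")
        if any(p.search(seq) for p in patterns):
            flags.add("excluded_motif")
        out.append(replace(w, flags=frozenset(flags)))
    return out


def rank_windows(windows: Sequence[TriggerWindow]) -> list[TriggerWindow]:
    """Order accepted windows: GC closest to 50% first, then longer, then
    leftmost. The rank score is |GC - 50| (lower is better); ordering is
    total and stable under input permutation."""
    for w in windows:
        if not w.accepted:
            raise ValueError(f"rank_windows got a flagged window at {w.start}")
    scored = [replace(w, rank_score=abs(w.gc_pct - 50.0)) for w in windows]
    scored.sort(key=lambda w: (w.rank_score, -w.length, w.start))
    return scored


@dataclass(frozen=True)
class Subregion:
    """A derived child window ("version") of a parent trigger."""

    label: str
    window: TriggerWindow
    relation: Literal["nested", "disjoint_sibling", "identical"]


def derive_subregions(
    parent: TriggerWindow,
    transcript: SequenceRecord,
    mode: Literal["nested", "non_overlapping_split"],
    lengths: Sequence[int],
    constraints: TriggerConstraints | None = None,
    orf: OrfAnnotation | None = None,
) -> list[Subregion]:
    """Derive labelled sub-region versions (v1, v2, ...) of a parent window.

    ``nested`` places each child at the parent start (a child equal to the
    parent is the degenerate "identical" relation); ``non_overlapping_split``
    tiles disjoint children left to right. Children are re-validated against
    the constraints and flagged rather than dropped when they fail.
    """
    c = constraints or TriggerConstraints()
    for ln in lengths:
        if ln > parent.length:
            raise ValueError(f"child length {ln} exceeds parent ({parent.length})")
    if mode == "non_overlapping_split" and sum(lengths) > parent.length:
        raise ValueError("children do not fit disjointly in the parent")
    children: list[Subregion] = []
    cursor = parent.start
    for i, ln in enumerate(lengths, start=1):
        if mode == "nested":
            start = parent.start
        else:
            start = cursor
            cursor += ln
        end = start + ln
        seq = transcript.residues[start:end]
        gc = gc_content(seq)
        flags = set()
        if not (c.len_min <= ln <= c.len_max):
            flags.add("length_out_of_range")
        if not (c.gc_min <= gc <= c.gc_max):
            flags.add("gc_out_of_range")
        if "N" in seq:
            flags.add("contains_N")
        m5 = start - (orf.start if orf else parent.start - parent.margin_5)
        m3 = (orf.end if orf else parent.end + parent.margin_3) - end
        if orf is not None and (m5 <= c.orf_margin or m3 <= c.orf_margin):
            flags.add("margin_violation")
        child = TriggerWindow(parent.transcript_id, start, end, gc, m5, m3, frozenset(flags))
        # containment check: the child is literally a substring of the parent
        assert seq in parent.sequence(transcript)
        relation: Literal["nested", "disjoint_sibling", "identical"]
        if mode == "nested":
            relation = "identical" if ln == parent.length else "nested"
        else:
            relation = "disjoint_sibling"
        children.append(Subregion(f"v{i}", child, relation))
    return children


@dataclass(frozen=True)
class T7Template:
    """PCR template design for in vitro dsRNA synthesis: both primers carry
    the phage T7 promoter at their 5' ends so both strands transcribe."""

    insert: str
    fwd_primer: str
    rev_primer: str
    promoter: str = T7_PROMOTER

    @property
    def fwd_primer_tail(self) -> str:
        return self.promoter

    @property
    def rev_primer_tail(self) -> str:
        return self.promoter


def make_t7_template(insert: str, primer_body_len: int = 20) -> T7Template:
    """Forward primer: promoter + the insert's first ``primer_body_len`` nt;
    reverse primer: promoter + reverse complement of its last
    ``primer_body_len`` nt."""
    if len(insert) < primer_body_len:
        raise ValueError("insert shorter than the primer body")
    fwd = T7_PROMOTER + insert[:primer_body_len]
    rev = T7_PROMOTER + reverse_complement(insert[-primer_body_len:])
    return T7Template(insert, fwd, rev)


def windows_to_bed(windows: Iterable[TriggerWindow]) -> list[BedInterval]:
    return [
        BedInterval(w.transcript_id, w.start, w.end,
                    f"win_{w.transcript_id}_{w.start}_{w.end}",
                    0.0 if w.rank_score != w.rank_score else w.rank_score, "+")
        for w in windows
    ]
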
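"""Maximal shared contiguous matches and pairwise identity.

The off-target rule this module exists for: a dsRNA trigger can silence an
unintended transcript if the two share a contiguous identical stretch at
least as long as a siRNA (21 nt). The engine therefore enumerates *maximal*
shared substrings of length >= k between sequence pairs — maximal meaning
that extending the matched stretch by one position in both sequences, in
either direction, breaks the equality or runs off an end.

Engine: a k-mer anchor index over one sequence with bidirectional extension
and left-maximality de-duplication, near-linear in practice. A quadratic
diagonal-scan oracle lives in the test suite, not here.

N is treated as matching nothing, including another N.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seq import SequenceRecord, reverse_complement

Strands = Literal["sense_only", "both"]


@dataclass(frozen=True)
class SharedMatch:
    """A maximal identical substring shared by sequences ``id_a`` and ``id_b``.

    ``pos_a``/``pos_b`` are 0-based starts. For ``strand == "revcomp"``,
    ``pos_b`` is the start on b's forward strand of the segment whose reverse
    complement equals ``a[pos_a : pos_a + length]``.
    """

    id_a: str
    id_b: str
    pos_a: int
    pos_b: int
    length: int
    strand: Literal["sense", "revcomp"] = "sense"

    def slice_a(self, a: str) -> str:
        return a[self.pos_a : self.pos_a + self.length]

    def slice_b(self, b: str) -> str:
        seg = b[self.pos_b : self.pos_b + self.length]
        return reverse_complement(seg) if self.strand == "revcomp" else seg


@dataclass(frozen=True)
class IdentityReport:
    """Percent identity of one aligned pair at one level."""

    id_a: str
    id_b: str
    level: Literal["nucleotide", "protein"]
    identity_pct: float
    alignment_length: int


def _kmer_index(s: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for j in range(len(s) - k + 1):
        kmer = s[j : j + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(j)
    return index


def _eq(x: str, y: str) -> bool:
    return x == y and x != "N"


def _sense_matches(a: str, b: str, k: int) -> list[tuple[int, int, int]]:
    """Maximal shared substrings >= k between a and b, sense orientation,
    as (pos_a, pos_b, length) triples."""
    if len(a) < k or len(b) < k:
        return []
    index = _kmer_index(b, k)
    out: list[tuple[int, int, int]] = []
    for i in range(len(a) - k + 1):
        kmer = a[i : i + k]
        if "N" in kmer:
            continue
        for j in index.get(kmer, ()):
            # left-maximality: anchors extendable to the left are duplicates
            # of a match already reported from an earlier anchor
            if i > 0 and j > 0 and _eq(a[i - 1], b[j - 1]):
                continue
            end_a, end_b = i + k, j + k
            while end_a < len(a) and end_b < len(b) and _eq(a[end_a], b[end_b]):
                end_a += 1
                end_b += 1
            out.append((i, j, end_a - i))
    out.sort()
    return out


def shared_matches(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    k: int = 21,
    strands: Strands = "sense_only",
) -> list[SharedMatch]:
    """All maximal shared contiguous matches of length >= k between a and b.

    With ``strands="both"``, matches between a and the reverse complement of
    b are also reported (strand ``"revcomp"``), with ``pos_b`` mapped back to
    b's forward strand. Each maximal position pair is reported once, ordered
    by (strand, pos_a, pos_b).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    id_a, seq_a = (a.id, a.residues) if isinstance(a, SequenceRecord) else ("a", a)
    id_b, seq_b = (b.id, b.residues) if isinstance(b, SequenceRecord) else ("b", b)
    out = [
        SharedMatch(id_a, id_b, i, j, ln, "sense")
        for i, j, ln in _sense_matches(seq_a, seq_b, k)
    ]
    if strands == "both":
        rc_b = reverse_complement(seq_b)
        for i, j, ln in _sense_matches(seq_a, rc_b, k):
            out.append(
                SharedMatch(id_a, id_b, i, len(seq_b) - (j + ln), ln, "revcomp")
            )
    out.sort(key=lambda m: (m.strand, m.pos_a, m.pos_b))
    return out


def longest_shared_match(
    a: SequenceRecord | str, b: SequenceRecord | str, strands: Strands = "sense_only"
) -> int:
    """Length of the longest shared contiguous match (0 if none).

    Uses a doubling-then-bisect search over k so short sequences stay cheap.
    """
    seq_a = a.residues if isinstance(a, SequenceRecord) else a
    seq_b = b.residues if isinstance(b, SequenceRecord) else b
    lo_cap = min(len(seq_a), len(seq_b))
    if lo_cap == 0:
        return 0
    k = 8 if lo_cap >= 8 else 1
    matches = shared_matches(seq_a, seq_b, k=k, strands=strands)
    if not matches:
        if k == 1:
            return 0
        matches = shared_matches(seq_a, seq_b, k=1, strands=strands)
        return max((m.length for m in matches), default=0)
    return max(m.length for m in matches)


@dataclass
class MatchCatalogue:
    """Per-species-pair catalogue of maximal shared matches for one gene."""

    gene: str
    k: int
    strands: Strands
    pairs: dict[tuple[str, str], list[SharedMatch]]
    skipped: list[tuple[str, str]]

    def counts(self) -> dict[tuple[str, str], int]:
        return {pair: len(ms) for pair, ms in self.pairs.items()}

    def lengths(self) -> dict[tuple[str, str], list[int]]:
        return {pair: sorted(m.length for m in ms) for pair, ms in self.pairs.items()}

    def total_matches(self) -> int:
        return sum(len(ms) for ms in self.pairs.values())

    def report_lines(self) -> list[str]:
        lines = [f"gene {self.gene}: maximal shared matches >= {self.k} nt ({self.strands})"]
        for (sa, sb), ms in sorted(self.pairs.items()):
            if ms:
                lens = ", ".join(f"{m.length}-mer" for m in sorted(ms, key=lambda m: m.length))
                lines.append(f"  {sa} vs {sb}: {len(ms)} match(es): {lens}")
            else:
                lines.append(f"  {sa} vs {sb}: no matches of {self.k} nt or longer")
        for sa, sb in self.skipped:
            lines.append(f"  {sa} vs {sb}: skipped (missing sequence)")
        return lines


def match_catalogue(
    sequences_by_species: Mapping[str, SequenceRecord | None],
    gene: str = "",
    k: int = 21,
    strands: Strands = "sense_only",
) -> MatchCatalogue:
    """Catalogue maximal shared matches >= k for every unordered species pair.

    ``sequences_by_species`` maps species label to that species' sequence of
    the gene (None if the species lacks one; the pair is then skipped with a
    notice rather than an error).
    """
    pairs: dict[tuple[str, str], list[SharedMatch]] = {}
    skipped: list[tuple[str, str]] = []
    for sa, sb in combinations(sorted(sequences_by_species), 2):
        ra, rb = sequences_by_species[sa], sequences_by_species[sb]
        if ra is None or rb is None:
            skipped.append((sa, sb))
            continue
        pairs[(sa, sb)] = shared_matches(ra, rb, k=k, strands=strands)
    return MatchCatalogue(gene, k, strands, pairs, skipped)


# --- global identity --------------------------------------------------------

def _global_aligner(level: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if level == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    else:
        # EDNAFULL-style match/mismatch
        aligner.match_score = 5
        aligner.mismatch_score = -4
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(
    a: SequenceRecord, b: SequenceRecord, level: Literal["nucleotide", "protein"]
) -> IdentityReport:
    """Global-alignment percent identity: identical columns over aligned
    columns, gap columns included in the denominator."""
    aligner = _global_aligner(level)
    aln = next(iter(aligner.align(a.residues.replace("*", "") if level == "protein" else a.residues,
                                  b.residues.replace("*", "") if level == "protein" else b.residues)))
    sa, sb = str(aln[0]), str(aln[1])
    ncols = len(sa)
    ident = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    return IdentityReport(a.id, b.id, level, 100.0 * ident / ncols, ncols)


def identity_matrix(
    records: Sequence[SequenceRecord], level: Literal["nucleotide", "protein"]
) -> list[IdentityReport]:
    """All pairwise global identities of a record set (symmetric, each
    unordered pair reported once)."""
    if len(records) < 2:
        raise ValueError("identity_matrix needs at least 2 records")
    alphabets = {r.alphabet for r in records}
    if len(alphabets) != 1:
        raise ValueError("mixed alphabets in identity_matrix input")
    return [pairwise_identity(a, b, level) for a, b in combinations(records, 2)]
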
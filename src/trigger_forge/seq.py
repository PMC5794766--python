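"""Sequence data model and basic operations.

Everything downstream (ortholog calling, trigger-window design, shared-match
screening) works on :class:`SequenceRecord` objects with 0-based, half-open
coordinates. FASTA I/O goes through Biopython; U is mapped to T and residues
are uppercased at read time so RNA- and DNA-derived inputs mix freely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

NUCLEOTIDE_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Alphabet = Literal["nucleotide", "protein"]


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide or protein sequence.

    Parameters
    ----------
    id:
        Unique token within a record set.
    residues:
        Uppercase residue string; ACGTN for nucleotide, 20 amino acids plus
        X and * for protein.
    alphabet:
        ``"nucleotide"`` or ``"protein"``.
    description:
        Free-text description (FASTA header remainder).
    """

    id: str
    residues: str
    alphabet: Alphabet = "nucleotide"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        allowed = NUCLEOTIDE_ALPHABET if self.alphabet == "nucleotide" else PROTEIN_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: residues {sorted(bad)} not in "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class OrfAnnotation:
    """An open reading frame on a transcript, 0-based half-open.

    ``start``/``end`` are always given on the forward strand of the
    transcript; for ``strand == "-"`` the ORF reads ATG..stop on the reverse
    complement.
    """

    seq_id: str
    start: int
    end: int
    strand: Literal["+", "-"] = "+"
    frame: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad ORF span [{self.start}, {self.end})")
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if self.frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")

    def __len__(self) -> int:
        return self.end - self.start

    def validate_against(self, record: SequenceRecord) -> None:
        """Check the ORF begins with ATG and ends with a stop on its strand."""
        if self.end > len(record):
            raise ValueError(f"ORF [{self.start},{self.end}) exceeds {record.id}")
        sub = record.residues[self.start : self.end]
        if self.strand == "-":
            sub = reverse_complement(sub)
        if not sub.startswith("ATG"):
            raise ValueError(f"ORF on {record.id} does not start with ATG")
        if sub[-3:] not in ("TAA", "TAG", "TGA"):
            raise ValueError(f"ORF on {record.id} does not end with a stop codon")


def _normalize_nucleotide(raw: str) -> str:
    return raw.upper().replace("U", "T")


def read_fasta(path: str | Path, alphabet: Alphabet = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into an ordered list of records.

    Residues are uppercased; U is mapped to T in nucleotide mode. Duplicate
    ids are a hard error; an empty file yields an empty list with a warning.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        if bio.id in seen:
            raise ValueError(f"duplicate sequence id {bio.id!r} in {path}")
        seen.add(bio.id)
        raw = str(bio.seq)
        residues = _normalize_nucleotide(raw) if alphabet == "nucleotide" else raw.upper()
        desc = bio.description[len(bio.id) :].strip() if bio.description else ""
        records.append(SequenceRecord(bio.id, residues, alphabet, desc))
    if not records:
        warnings.warn(f"no sequences found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records to FASTA, preserving order and descriptions."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def gc_content(residues: str) -> float:
    """Percent G+C of a nucleotide string, N counted in the denominator.

    With ``exclude_n`` semantics deliberately off: a window full of Ns reads
    as low-GC and is flagged separately rather than silently inflated.
    """
    if not residues:
        raise ValueError("gc_content of empty sequence is undefined")
    gc = residues.count("G") + residues.count("C")
    return 100.0 * gc / len(residues)


def reverse_complement(residues: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    bad = set(residues) - NUCLEOTIDE_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)}")
    return residues.translate(_COMPLEMENT)[::-1]


def translate(residues: str) -> str:
    """Translate a nucleotide string in frame 0; stops are '*', trailing
    partial codons are dropped."""
    usable = len(residues) - len(residues) % 3
    if usable == 0:
        return ""
    return str(Seq(residues[:usable]).translate())


def translate_six_frames(record: SequenceRecord) -> dict[str, str]:
    """Translate a nucleotide record in all six frames.

    Returns a mapping from frame label (``+0 +1 +2 -0 -1 -2``) to protein
    string. Frame ``-0`` starts at the first base of the reverse complement.
    """
    if record.alphabet != "nucleotide":
        raise ValueError("six-frame translation needs a nucleotide record")
    if len(record) < 3:
        raise ValueError(f"{record.id}: too short to translate (<3 nt)")
    fwd = record.residues
    rev = reverse_complement(fwd)
    out: dict[str, str] = {}
    for offset in range(3):
        out[f"+{offset}"] = translate(fwd[offset:])
        out[f"-{offset}"] = translate(rev[offset:])
    return out


_STOPS = ("TAA", "TAG", "TGA")


def _scan_strand(seq: str, min_len_nt: int) -> list[tuple[int, int, int]]:
    """All ATG->stop spans >= min_len_nt on one strand, as (start, end, frame)."""
    n = len(seq)
    found: list[tuple[int, int, int]] = []
    for frame in range(3):
        pos = frame
        starts: list[int] = []
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if codon == "ATG":
                starts.append(pos)
            elif codon in _STOPS:
                for s in starts:
                    if pos + 3 - s >= min_len_nt:
                        found.append((s, pos + 3, frame))
                starts = []
            pos += 3
    return found


def find_orfs(record: SequenceRecord, min_len_nt: int = 150) -> list[OrfAnnotation]:
    """All complete ORFs (ATG..stop, inclusive of the stop) of at least
    ``min_len_nt`` on both strands, sorted by length descending.

    Ties break toward the + strand, then the smaller forward-strand start.
    The first element is the principal ORF.
    """
    if record.alphabet != "nucleotide":
        raise ValueError("ORF finding needs a nucleotide record")
    n = len(record)
    orfs: list[OrfAnnotation] = []
    for s, e, frame in _scan_strand(record.residues, min_len_nt):
        orfs.append(OrfAnnotation(record.id, s, e, "+", frame))
    rc = reverse_complement(record.residues)
    for s, e, frame in _scan_strand(rc, min_len_nt):
        # map back to forward coordinates
        orfs.append(OrfAnnotation(record.id, n - e, n - s, "-", frame))
    orfs.sort(key=lambda o: (-(o.end - o.start), o.strand != "+", o.start))
    return orfs


def principal_orf(record: SequenceRecord, min_len_nt: int = 150) -> OrfAnnotation | None:
    """Longest ORF of the record, or None if there is none."""
    orfs = find_orfs(record, min_len_nt)
    return orfs[0] if orfs else None


# --- BED6 export/import -----------------------------------------------------

@dataclass
class BedInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "+"


def write_bed(intervals: Iterable[BedInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


def read_bed(path: str | Path) -> list[BedInterval]:
    out: list[BedInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(
                BedInterval(
                    f[0],
                    int(f[1]),
                    int(f[2]),
                    f[3] if len(f) > 3 else ".",
                    float(f[4]) if len(f) > 4 else 0.0,
                    f[5] if len(f) > 5 else "+",
                )
            )
    return out


def orfs_to_bed(orfs: Iterable[OrfAnnotation]) -> list[BedInterval]:
    return [
        BedInterval(o.seq_id, o.start, o.end, f"orf_{o.seq_id}_{o.start}", 0.0, o.strand)
        for o in orfs
    ]
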
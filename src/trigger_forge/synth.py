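"""Seeded generators for every input the pipeline consumes.

These generators exist so the whole artifact is testable without any
sequencing data: synthetic transcriptomes with planted principal ORFs,
ortholog triplets with controlled nucleotide/protein identity and exactly
placed maximal shared substrings, binomial mortality wells following a
log-logistic dose curve, node-injury-scored root events, and qPCR Ct values
with set amplification efficiencies.

All generators are pure functions of (spec, seed): one explicit
`numpy.random.default_rng` stream per call, no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bioassay import BioassayWell, QpcrMeasurement, RootEvent
from .seq import (
    OrfAnnotation,
    SequenceRecord,
    find_orfs,
    translate,
)

_NTS = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

_CODON_AA: dict[str, str] = {}
for _a in _NTS:
    for _b in _NTS:
        for _c in _NTS:
            _CODON_AA[_a + _b + _c] = translate(_a + _b + _c)
_SENSE_CODONS = sorted(c for c in _CODON_AA if c not in _STOPS)
# synonymous single-nt neighbours of each codon
_SYN_NEIGHBOURS: dict[str, list[str]] = {}
for _codon in _SENSE_CODONS:
    alts = []
    for _i in range(3):
        for _n in _NTS:
            if _n == _codon[_i]:
                continue
            alt = _codon[:_i] + _n + _codon[_i + 1 :]
            if alt not in _STOPS and _CODON_AA[alt] == _CODON_AA[_codon]:
                alts.append(alt)
    _SYN_NEIGHBOURS[_codon] = alts


# --------------------------------------------------------------------------
# transcriptomes
# --------------------------------------------------------------------------

@dataclass
class SynthSpec:
    """Transcriptome generator settings.

    ORF-bearing transcripts receive a planted principal ORF of at least
    450 nt, long enough that a 200-nt trigger window survives the strict
    70-nt margins from start and stop codons.
    """

    seed: int = 0
    n_transcripts: int = 20
    length_range: tuple[int, int] = (900, 2000)
    gc_target: float = 50.0
    orf_fraction: float = 1.0
    min_orf_nt: int = 450

    def __post_init__(self) -> None:
        if self.length_range[0] < 150:
            raise ValueError("length_range minimum must be >= 150 nt")
        if not (0.0 <= self.orf_fraction <= 1.0):
            raise ValueError("orf_fraction must lie in [0, 1]")
        if self.orf_fraction > 0 and self.length_range[0] < self.min_orf_nt + 20:
            raise ValueError(
                f"transcripts of {self.length_range[0]} nt are too short to hold "
                f"a {self.min_orf_nt} nt ORF with UTRs"
            )


def _nt_probs(gc_target: float) -> np.ndarray:
    g = gc_target / 100.0
    return np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])


def _random_nt(rng: np.random.Generator, n: int, p: np.ndarray) -> str:
    return "".join(np.array(list(_NTS))[rng.choice(4, size=n, p=p)])


def _random_orf(rng: np.random.Generator, orf_nt: int, p: np.ndarray) -> str:
    codons = ["ATG"]
    for _ in range(orf_nt // 3 - 2):
        while True:
            codon = _random_nt(rng, 3, p)
            if codon not in _STOPS:
                break
        codons.append(codon)
    codons.append(["TAA", "TAG", "TGA"][rng.integers(0, 3)])
    return "".join(codons)


def generate_transcriptome(
    spec: SynthSpec,
) -> tuple[list[SequenceRecord], list[OrfAnnotation]]:
    """Generate single-ORF transcripts with controlled GC.

    The first round(orf_fraction * n) transcripts carry a planted principal
    ORF; the generator rejects and redraws any transcript whose random
    flanks happen to harbour a competing ORF at least as long as the plant.
    """
    rng = np.random.default_rng(spec.seed)
    p = _nt_probs(spec.gc_target)
    n_orf = int(round(spec.orf_fraction * spec.n_transcripts))
    records: list[SequenceRecord] = []
    orfs: list[OrfAnnotation] = []
    for i in range(spec.n_transcripts):
        name = f"synth_t{i + 1:04d}"
        carries_orf = i < n_orf
        for _attempt in range(50):
            length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            if carries_orf:
                max_orf = (length - 20) // 3 * 3
                orf_nt = int(rng.integers(spec.min_orf_nt // 3, max_orf // 3 + 1)) * 3
                utr5 = int(rng.integers(0, length - orf_nt + 1))
                seq = (
                    _random_nt(rng, utr5, p)
                    + _random_orf(rng, orf_nt, p)
                    + _random_nt(rng, length - utr5 - orf_nt, p)
                )
                rec = SequenceRecord(name, seq, "nucleotide", "synthetic transcript")
                found = find_orfs(rec, min_len_nt=150)
                if found and found[0].start == utr5 and found[0].end == utr5 + orf_nt \
                        and found[0].strand == "+":
                    records.append(rec)
                    orfs.append(found[0])
                    break
            else:
                seq = _random_nt(rng, length, p)
                rec = SequenceRecord(name, seq, "nucleotide", "synthetic transcript")
                if not find_orfs(rec, min_len_nt=spec.min_orf_nt):
                    records.append(rec)
                    break
        else:
            raise RuntimeError(f"could not realize transcript {name} after 50 draws")
    return records, orfs


# --------------------------------------------------------------------------
# ortholog triplets with planted maximal shared substrings
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedMatch:
    """A maximal shared substring to embed between one sequence pair.

    ``pair`` indexes the triplet (0, 1, 2); ``length`` is the exact maximal
    match length to realize, flanks broken by forced mismatches."""

    pair: tuple[int, int]
    length: int
    count: int = 1


@dataclass
class OrthologPlantSpec:
    protein_identity_target: float = 85.0
    nucleotide_identity_target: float = 72.0
    planted_matches: tuple[PlantedMatch, ...] = ()
    species_labels: tuple[str, str, str] = ("sp1", "sp2", "sp3")
    guard_k: int = 21  # no accidental shared run of this length may survive

    def __post_init__(self) -> None:
        for t in (self.protein_identity_target, self.nucleotide_identity_target):
            if not (0 < t <= 100):
                raise ValueError("identity targets must lie in (0, 100]")
        for m in self.planted_matches:
            if m.length < self.guard_k:
                raise ValueError("planted match shorter than the screen k")
            if tuple(sorted(m.pair)) != m.pair or m.pair[0] == m.pair[1]:
                raise ValueError("pair must be an ordered distinct index pair")


def positionwise_identity(a: str, b: str) -> float:
    """Percent identical positions of two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("positionwise identity needs equal lengths")
    same = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * same / len(a)


def _diag_runs(a: Sequence[str], b: Sequence[str], kmin: int):
    """Maximal runs of positionwise equality of length >= kmin, as
    (start, length)."""
    run = 0
    for i in range(len(a)):
        if a[i] == b[i]:
            run += 1
        else:
            if run >= kmin:
                yield i - run, run
            run = 0
    if run >= kmin:
        yield len(a) - run, run


class _TripletBuilder:
    """Stateful construction of one ortholog triplet (see module docstring).

    Sequence 0 stays the base ORF; sequences 1 and 2 are mutated codon-aware:
    nonsynonymous codon swaps set the protein divergence, synonymous
    single-nt swaps top up the nucleotide divergence, split across
    "only-1" / "only-2" / "both-same" classes so all three pairwise
    identities land near the same target.
    """

    def __init__(self, base: str, spec: OrthologPlantSpec, rng: np.random.Generator):
        if len(base) % 3 or len(base) < 60:
            raise ValueError("base ORF must be a codon-complete sequence >= 60 nt")
        if not base.startswith("ATG") or base[-3:] not in _STOPS:
            raise ValueError("base ORF must run ATG..stop")
        if set(base) - set(_NTS):
            raise ValueError("base ORF must be plain ACGT")
        self.base = base
        self.L = len(base)
        self.n_codons = self.L // 3
        self.spec = spec
        self.rng = rng
        self.seqs = [list(base), list(base), list(base)]
        self.frozen: list[set[int]] = [set(), set(), set()]
        protected = set(range(3)) | set(range(self.L - 3, self.L))
        for fr in self.frozen:
            fr |= protected
        # (pair, start, length) of every planted window
        self.windows: list[tuple[tuple[int, int], int, int]] = []

    # -- raw single-nt edits -------------------------------------------------

    def _codon_of(self, i: int, q: int) -> str:
        c = q // 3 * 3
        return "".join(self.seqs[i][c : c + 3])

    def _raw_edit(self, i: int, q: int, avoid: set[str], force: bool = False) -> bool:
        """Set seqs[i][q] to a nt outside ``avoid``, not creating a stop
        codon; returns False if impossible (unless force)."""
        if q in self.frozen[i]:
            return False
        c = q // 3 * 3
        off = q - c
        codon = self._codon_of(i, q)
        syn, ok, risky = [], [], []
        for n in _NTS:
            if n == self.seqs[i][q] or n in avoid:
                continue
            alt = codon[:off] + n + codon[off + 1 :]
            if alt in _STOPS:
                risky.append(n)
            elif _CODON_AA[alt] == _CODON_AA[codon] and codon not in _STOPS:
                syn.append(n)
            else:
                ok.append(n)
        # synonymous preferred: raw edits should perturb the protein as
        # little as possible so the nonsynonymous budget stays in charge
        pool = syn or ok or (risky if force else [])
        if not pool:
            return False
        self.seqs[i][q] = pool[int(self.rng.integers(0, len(pool)))]
        return True

    @staticmethod
    def _third_positions(p: int, m: int, spacing: int = 12) -> list[int]:
        """Positions inside [p+4, p+m-4) at third-codon offsets, no more
        than ~spacing+2 apart, so decoy edits are usually synonymous."""
        out = []
        q = p + 4
        while q < p + m - 4:
            snapped = q - q % 3 + 2
            if snapped < p + m - 4 and (not out or snapped > out[-1]):
                out.append(snapped)
            q += spacing
        if not out:  # very short window: fall back to its centre
            out = [p + m // 2]
        return out

    # -- planted windows -----------------------------------------------------

    def place_windows(self) -> None:
        occ: list[tuple[tuple[int, int], int]] = []
        for m in self.spec.planted_matches:
            occ.extend([(m.pair, m.length)] * m.count)
        if not occ:
            return
        total = sum(length for _, length in occ)
        free = (self.L - 8) - total
        gap = free // (len(occ) + 1)
        if gap < self.spec.guard_k + 4:
            raise ValueError("planted matches do not fit in the base ORF")
        cursor = 4 + gap
        for pair, length in occ:
            self._plant(pair, cursor, length)
            cursor += length + gap
        self.windows.sort(key=lambda w: w[1])

    def _plant(self, pair: tuple[int, int], p: int, m: int) -> None:
        x, y = pair
        self.windows.append((pair, p, m))
        # keep pair members identical over [p, p+m): freeze them as-is
        # (both are still base here), after optional joint decoys below
        if x != 0:
            # window must not be shared with the base sequence: put the same
            # decoy edits in both members every <21 nt (third codon
            # positions, so they are usually synonymous)
            for q in self._third_positions(p, m):
                codon = self._codon_of(x, q)
                off = q % 3
                chosen = None
                for n in _NTS:
                    if n == self.base[q]:
                        continue
                    alt = codon[:off] + n + codon[off + 1 :]
                    if alt in _STOPS:
                        continue
                    if _CODON_AA[alt] == _CODON_AA[codon]:
                        chosen = n
                        break
                    if chosen is None:
                        chosen = n
                if chosen is not None:
                    self.seqs[x][q] = chosen
                    self.seqs[y][q] = chosen
        else:
            # window shared with base: the third sequence must break it
            z = ({0, 1, 2} - {x, y}).pop()
            for q in self._third_positions(p, m):
                self._raw_edit(z, q, {self.base[q]}, force=True)
        # forced flank mismatches bound the match to exactly m
        for q in (p - 1, p + m):
            editable = y if y != 0 else x
            if not self._raw_edit(editable, q, {self.seqs[x][q] if editable == y else self.seqs[y][q]}):
                self._raw_edit(editable, q,
                               {self.seqs[x][q] if editable == y else self.seqs[y][q]},
                               force=True)
        for i in pair:
            self.frozen[i] |= set(range(p - 1, p + m + 1))

    # -- divergence ----------------------------------------------------------

    def _eligible_codons(self) -> list[int]:
        out = []
        for ci in range(1, self.n_codons - 1):
            span = set(range(ci * 3, ci * 3 + 3))
            if span & self.frozen[1] or span & self.frozen[2]:
                continue
            out.append(ci)
        return out

    def diverge(self) -> None:
        paa = self.spec.protein_identity_target
        pnt = self.spec.nucleotide_identity_target
        pool = self._eligible_codons()
        self.rng.shuffle(pool)

        def aa_diffs() -> tuple[int, int, int]:
            prots = [translate("".join(s)) for s in self.seqs]
            d = []
            for i, j in ((0, 1), (0, 2), (1, 2)):
                d.append(sum(1 for a, b in zip(prots[i], prots[j]) if a != b))
            return tuple(d)  # type: ignore[return-value]

        d_aa = (1 - paa / 100.0) * (self.n_codons - 1)
        e01, e02, e12 = aa_diffs()  # divergence already caused by window edits
        n01, n02, n12 = (max(0.0, d_aa - e) for e in (e01, e02, e12))
        nA = int(round(max(0.0, (n01 + n12 - n02) / 2)))
        nB = int(round(max(0.0, (n02 + n12 - n01) / 2)))
        nE = int(round(max(0.0, (n01 + n02 - n12) / 2)))
        if nA + nB + nE > len(pool):
            raise ValueError("protein identity target too low for this ORF length")
        classes = {"A": pool[:nA], "B": pool[nA : nA + nB],
                   "E": pool[nA + nB : nA + nB + nE]}
        used = set(pool[: nA + nB + nE])
        for cls, codons in classes.items():
            for ci in codons:
                cur = self._codon_of(1, ci * 3)
                choices = [c for c in _SENSE_CODONS if _CODON_AA[c] != _CODON_AA[cur]]
                new = choices[int(self.rng.integers(0, len(choices)))]
                if cls in ("A", "E"):
                    self.seqs[1][ci * 3 : ci * 3 + 3] = list(new)
                if cls in ("B", "E"):
                    self.seqs[2][ci * 3 : ci * 3 + 3] = list(new)
        # synonymous top-up to the nucleotide target
        target_d = (1 - pnt / 100.0) * self.L
        d01 = self.L - sum(a == b for a, b in zip(self.seqs[0], self.seqs[1]))
        d02 = self.L - sum(a == b for a, b in zip(self.seqs[0], self.seqs[2]))
        d12 = self.L - sum(a == b for a, b in zip(self.seqs[1], self.seqs[2]))
        n01 = max(0.0, target_d - d01)
        n02 = max(0.0, target_d - d02)
        n12 = max(0.0, target_d - d12)
        alpha = int(round(max(0.0, (n01 + n12 - n02) / 2)))
        beta = int(round(max(0.0, (n02 + n12 - n01) / 2)))
        gamma = int(round(max(0.0, (n01 + n02 - n12) / 2)))
        remaining = [ci for ci in pool if ci not in used]
        jobs = ["a"] * alpha + ["b"] * beta + ["g"] * gamma
        self.rng.shuffle(jobs)
        for job in jobs:
            while remaining:
                ci = remaining.pop()
                cur = self._codon_of(0, ci * 3)  # untouched codons equal base
                if self._codon_of(1, ci * 3) != cur or self._codon_of(2, ci * 3) != cur:
                    continue
                syns = _SYN_NEIGHBOURS[cur]
                if not syns:
                    continue
                new = syns[int(self.rng.integers(0, len(syns)))]
                if job in ("a", "g"):
                    self.seqs[1][ci * 3 : ci * 3 + 3] = list(new)
                if job in ("b", "g"):
                    self.seqs[2][ci * 3 : ci * 3 + 3] = list(new)
                break

    # -- spurious-run repair -------------------------------------------------

    def _windows_for(self, pair: tuple[int, int]) -> set[tuple[int, int]]:
        return {(p, m) for pr, p, m in self.windows if pr == pair}

    def repair(self) -> None:
        k = self.spec.guard_k
        for _round in range(50):
            dirty = False
            for pair in ((0, 1), (0, 2), (1, 2)):
                x, y = pair
                expected = self._windows_for(pair)
                for start, length in list(_diag_runs(self.seqs[x], self.seqs[y], k)):
                    if (start, length) in expected:
                        continue
                    dirty = True
                    self._break_run(pair, start, length)
            if not dirty:
                return
        raise RuntimeError("could not repair accidental shared runs")

    def _break_run(self, pair: tuple[int, int], start: int, length: int) -> None:
        x, y = pair
        mid = start + length // 2
        order = sorted(range(start, start + length), key=lambda q: abs(q - mid))
        for q in order:
            others = {self.seqs[i][q] for i in range(3)}
            for editor in ([y, x] if x != 0 else [y]):
                if self._raw_edit(editor, q, avoid=others - {self.seqs[editor][q]} | {self.seqs[x if editor == y else y][q]}):
                    return
        # last resort: force an edit anywhere in the run
        for q in order:
            for editor in ([y, x] if x != 0 else [y]):
                partner = x if editor == y else y
                if self._raw_edit(editor, q, {self.seqs[partner][q]}, force=True):
                    return
        raise RuntimeError(f"cannot break shared run at {start}+{length} for pair {pair}")

    def build(self) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
        self.place_windows()
        self.diverge()
        if self.spec.nucleotide_identity_target < 100.0:
            self.repair()
        labels = self.spec.species_labels
        nts = [
            SequenceRecord(labels[i], "".join(self.seqs[i]), "nucleotide",
                           "synthetic ortholog")
            for i in range(3)
        ]
        aas = [
            SequenceRecord(labels[i], translate("".join(self.seqs[i]))[:-1],
                           "protein", "synthetic ortholog translation")
            for i in range(3)
        ]
        return nts, aas


def plant_ortholog_triplet(
    base_orf: str, spec: OrthologPlantSpec, seed: int = 0
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Derive three ortholog sequences from a base ORF.

    Returns (nucleotide records, protein records), one per species label.
    Pairwise nucleotide and protein identities land within a few points of
    their targets; every planted (pair, length) appears as a maximal shared
    substring of exactly that length, and no accidental shared run of
    ``guard_k`` nt or longer survives between any pair.
    """
    rng = np.random.default_rng(seed)
    builder = _TripletBuilder(base_orf, spec, rng)
    return builder.build()


def planted_window_coords(
    base_orf: str, spec: OrthologPlantSpec, seed: int = 0
) -> list[tuple[tuple[int, int], int, int]]:
    """The (pair, start, length) layout the builder will use for a given
    spec — placement is deterministic given (spec, base length)."""
    rng = np.random.default_rng(seed)
    builder = _TripletBuilder(base_orf, spec, rng)
    builder.place_windows()
    return sorted(builder.windows, key=lambda w: w[1])


# Conservation structure of the three root-protective RNAi target genes
# across the beetle triplet (indices: 0=dvv, 1=ma, 2=tc after sorting the
# species labels): pairwise identity midpoints at protein and nucleotide
# level, and the catalogue of maximal shared nucleotide matches >= 21 nt.
CONSERVED_GENE_PROFILES: dict[str, dict] = {
    "rop": {"aa": 85.5, "nt": 71.8, "plants": ()},
    "dre4": {"aa": 80.6, "nt": 69.5, "plants": (PlantedMatch((1, 2), 22),)},
    "rpii140": {
        "aa": 95.8,
        "nt": 78.0,
        "plants": (
            PlantedMatch((0, 1), 23),
            PlantedMatch((0, 1), 26),
            PlantedMatch((0, 1), 29),
            PlantedMatch((0, 2), 26),
            PlantedMatch((1, 2), 23, count=2),
            PlantedMatch((1, 2), 26),
            PlantedMatch((1, 2), 32),
        ),
    },
}


def conservation_triplets(
    seed: int = 0,
) -> dict[str, tuple[list[SequenceRecord], list[SequenceRecord]]]:
    """Synthetic stand-ins for the three conserved gene triplets.

    Real ortholog sequences are not bundled; these synthetic triplets carry
    the same reported structure — pairwise identity levels and the exact
    maximal shared-match catalogue — so the conservation screen can be
    exercised end to end. Returns gene -> (nucleotide records, protein
    records) with species labels dvv/ma/tc.
    """
    out: dict[str, tuple[list[SequenceRecord], list[SequenceRecord]]] = {}
    for i, (gene, prof) in enumerate(sorted(CONSERVED_GENE_PROFILES.items())):
        recs, orfs = generate_transcriptome(
            SynthSpec(seed=seed * 101 + i, n_transcripts=1,
                      length_range=(1800, 1900), min_orf_nt=1650)
        )
        base = recs[0].residues[orfs[0].start : orfs[0].end]
        spec = OrthologPlantSpec(
            protein_identity_target=prof["aa"],
            nucleotide_identity_target=prof["nt"],
            planted_matches=prof["plants"],
            species_labels=("dvv", "ma", "tc"),
        )
        out[gene] = plant_ortholog_triplet(base, spec, seed=seed * 31 + i)
    return out


# --------------------------------------------------------------------------
# diet bioassay
# --------------------------------------------------------------------------

def fourfold_series(top: float = 500.0, n: int = 8) -> tuple[float, ...]:
    """A four-fold serial dilution series from the top dose down."""
    return tuple(top / 4**i for i in range(n))


@dataclass
class WeightModel:
    """Per-insect live-weight distribution and its dose suppression."""

    control_mean_mg: float = 1.2
    control_sd_mg: float = 0.25
    gi50: float = 10.0
    slope: float = 2.0
    max_suppression: float = 0.95

    def mean_at(self, dose: float) -> float:
        if dose <= 0:
            return self.control_mean_mg
        frac = self.max_suppression / (1.0 + (dose / self.gi50) ** (-self.slope))
        return self.control_mean_mg * (1.0 - frac)


@dataclass
class BioassaySimSpec:
    doses: tuple[float, ...] = field(default_factory=fourfold_series)
    true_lc50: float = 20.0
    slope: float = 2.0
    control_mortality: float = 0.02
    n_per_dose: int = 16
    insects_per_well: int = 8
    n_control_wells: int = 4
    weight_model: WeightModel = field(default_factory=WeightModel)
    treatment: str = "dsRNA"

    def __post_init__(self) -> None:
        if len(set(self.doses)) != len(self.doses) or min(self.doses) <= 0:
            raise ValueError("doses must be positive and distinct")
        if self.n_per_dose < 1:
            raise ValueError("n_per_dose must be >= 1")
        if not (0.0 <= self.control_mortality < 1.0):
            raise ValueError("control mortality must lie in [0, 1)")


def mortality_at(dose: float, lc50: float, slope: float, c: float) -> float:
    """Log-logistic mortality with control floor c."""
    if dose <= 0:
        return c
    return c + (1 - c) / (1.0 + (dose / lc50) ** (-slope))


def simulate_diet_bioassay(spec: BioassaySimSpec, seed: int = 0) -> list[BioassayWell]:
    """Binomial deaths along a log-logistic dose curve, with per-survivor
    live weights from the weight model; dose-0 negative-control wells
    included."""
    rng = np.random.default_rng(seed)
    wells: list[BioassayWell] = []

    def make_wells(dose: float, n_total: int, label: str) -> None:
        per = spec.insects_per_well
        counts = [per] * (n_total // per)
        if n_total % per:
            counts.append(n_total % per)
        p = mortality_at(dose, spec.true_lc50, spec.slope, spec.control_mortality)
        mean_w = spec.weight_model.mean_at(dose)
        for ri, n in enumerate(counts, start=1):
            dead = int(rng.binomial(n, p))
            alive = n - dead
            weights = rng.normal(mean_w, spec.weight_model.control_sd_mg, size=alive)
            total_w = float(np.clip(weights, 0.01, None).sum()) if alive else 0.0
            wells.append(BioassayWell(label, dose, n, dead, total_w, f"r{ri}"))

    for dose in spec.doses:
        make_wells(dose, spec.n_per_dose, spec.treatment)
    make_wells(0.0, spec.n_control_wells * spec.insects_per_well, "control")
    return wells


# --------------------------------------------------------------------------
# root trials
# --------------------------------------------------------------------------

@dataclass
class RootTrialSimSpec:
    constructs: tuple[tuple[str, float], ...] = (("hpA", 0.9), ("hpB", 0.5))
    events_per_construct: int = 20
    test_dates: tuple[tuple[str, float], ...] = (("d1", 0.0),)

    def __post_init__(self) -> None:
        for label, p in self.constructs:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{label}: pass probability outside [0, 1]")


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def simulate_root_trial(spec: RootTrialSimSpec, seed: int = 0) -> list[RootEvent]:
    """NIS scores per event such that P(NIS <= 0.5) equals the construct's
    pass probability shifted by its test date's logit offset."""
    rng = np.random.default_rng(seed)
    events: list[RootEvent] = []
    dates = spec.test_dates
    for label, p0 in spec.constructs:
        for j in range(spec.events_per_construct):
            date, offset = dates[j % len(dates)]
            if p0 in (0.0, 1.0):
                p = p0
            else:
                p = float(1.0 / (1.0 + np.exp(-(_logit(p0) + offset))))
            passed = rng.random() < p
            if passed:
                nis = float(rng.uniform(0.0, 0.5))
            else:
                nis = float(rng.uniform(0.5, 1.0))
                nis = max(nis, np.nextafter(0.5, 1.0))
            events.append(RootEvent(label, f"{label}_e{j + 1:03d}", date, nis))
    return events


# --------------------------------------------------------------------------
# qPCR
# --------------------------------------------------------------------------

@dataclass
class QpcrSimSpec:
    """Target genes with (efficiency, true knockdown proportion), one
    reference gene with its own efficiency."""

    targets: tuple[tuple[str, float, float], ...] = (("rop", 2.0, 0.6),)
    reference: tuple[str, float] = ("rps3", 2.0)
    n_replicates: int = 6  # 3 biological x 2 technical
    noise_sd: float = 0.15
    base_ct: float = 21.0

    def __post_init__(self) -> None:
        effs = [e for _, e, _ in self.targets] + [self.reference[1]]
        for e in effs:
            if not (1.6 <= e <= 2.1):
                raise ValueError("amplification efficiencies must lie in [1.6, 2.1]")
        for name, _, k in self.targets:
            if not (0.0 <= k < 1.0):
                raise ValueError(f"{name}: knockdown must lie in [0, 1)")


def simulate_qpcr(
    spec: QpcrSimSpec, seed: int = 0
) -> tuple[dict[str, QpcrMeasurement], QpcrMeasurement]:
    """Ct values whose Pfaffl ratio recovers 1 - knockdown in expectation.

    A knockdown of fraction k delays the target's treated Ct by
    log_E(1/(1-k)) cycles; the reference gene is unaffected.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_replicates

    def cts(mean: float) -> tuple[float, ...]:
        return tuple(float(v) for v in rng.normal(mean, spec.noise_sd, size=n))

    ref_name, ref_eff = spec.reference
    reference = QpcrMeasurement(ref_name, ref_eff, cts(spec.base_ct), cts(spec.base_ct))
    out: dict[str, QpcrMeasurement] = {}
    for name, eff, k in spec.targets:
        shift = float(np.log(1.0 / (1.0 - k)) / np.log(eff)) if k > 0 else 0.0
        out[name] = QpcrMeasurement(name, eff, cts(spec.base_ct + shift), cts(spec.base_ct))
    return out, reference
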
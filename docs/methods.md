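# Methods

`trigger-forge` implements the computational side of transferring lethal
RNAi targets from a model beetle (*Tribolium castaneum*) to coleopteran crop
pests (*Diabrotica virgifera virgifera*, western corn rootworm; *Meligethes
aeneus*, pollen beetle): ortholog identification in a pest transcriptome,
dsRNA trigger-window design inside the ortholog's open reading frame,
alignment-free off-target and cross-species conservation screening, and the
downstream bioassay statistics. This note records the models, the defaults
and why, the numerical choices, and what the synthetic data generators do
and do not emulate.

## Ortholog identification

Queries (model-species proteins) are aligned locally against all six
translated frames of every transcript (Smith–Waterman semantics: BLOSUM62,
gap open 11, gap extend 1, via Biopython's `PairwiseAligner`). A hit
survives if

- E-value ≤ 0.01 (protein–protein mode; 10⁻²⁰ for assembled contigs,
  10⁻¹⁰ for unassembled reads, selectable via `db_kind`),
- percent identity over aligned columns ≥ 50, and
- query coverage ≥ 75 % and strictly < 125 %.

Coverage uses the query protein length as the denominator (the
translated-search convention); the asymmetric band rejects both fragments
and implausibly inflated alignments, and the upper bound is exclusive.
E-values use ungapped Karlin–Altschul constants for BLOSUM62
(λ = 0.3176, K = 0.134) with a database-size search-space correction; they
calibrate the familiar thresholds rather than reproduce any particular
search tool's internals. Survivors are ranked by score; a hit whose subject
span overlaps a kept hit's span on the same transcript by more than 50 % is
considered redundant and dropped. Every call records the rejected hits and
the reason each one failed, so filter behaviour is auditable.

Domain-profile hits (scores consumed from an external profile scan, never
computed here) are classified by score: ≥ 10.0 is a domain occurrence;
< 8.5 is excluded; the published thresholds leave [8.5, 10.0) undefined, and
this band is represented explicitly as "questionable" — retained in reports
but never counted as an occurrence.

## Trigger-window design

A trigger window is a candidate dsRNA region inside the principal ORF. The
constraints, all configurable: length 200–500 nt, GC content 40–60 %
(bounds inclusive — "between 40 and 60" with no exclusivity stated), and a
strictly greater than 70 nt distance from both the ATG and the stop codon
(`window.start − orf.start > 70` and `orf.end − window.end > 70`; the
70-vs-71 boundary is unit-tested). Windows containing N or intersecting a
user-supplied exclusion motif/interval are emitted flagged, never silently
dropped. Enumeration defaults to a 10-nt step for tractability; `step=1` is
available and is checked against exhaustive (start, length) enumeration.

Off-target screening flags a window if it shares a contiguous identical
stretch of ≥ 21 nt — the length scale of a siRNA — with any sequence in any
non-target transcriptome set. Both strands of the window are screened
(dsRNA contains both; whether the original screens considered reverse
complements is not stated, so the conservative choice is the default).
Internally this reduces to k-mer set membership: a shared match of length
≥ k exists iff a shared k-mer exists, so one k-mer set over the off-target
collection decides every window; the boundary (20-mer passes, 21-mer flags)
is tested. Splice-site avoidance is a generic exclusion-motif list, not a
splice model.

Ranking is a deliberate, documented convention (no published rule exists):
|GC − 50| ascending, then length descending, then start ascending — a
total, permutation-stable order. T7 synthesis templates prepend the phage
promoter `TAATACGACTCACTATAGGGAGA` (23 nt) to the first/last
`primer_body_len` nt of the insert (reverse primer body is the reverse
complement of the 3′ end).

## Conservation screening

`shared_matches` enumerates *maximal* shared substrings of length ≥ k
between two sequences: maximal means one-position extension in both
sequences, in either direction, breaks equality or hits a boundary. The
engine indexes all k-mers of one sequence and extends anchor hits
bidirectionally; an anchor that can be extended left is a duplicate of an
earlier anchor's match and is skipped, so each maximal position pair is
reported exactly once. N matches nothing, including another N. Each
reported match is verifiable by direct slicing. A quadratic diagonal-scan
oracle ships in the test suite (not the library) and must agree exactly on
hundreds of random pairs. Duplicate substrings at multiple positions yield
one match per position pair; report "counts" are counts of maximal position
pairs.

Pairwise identity uses global alignment (Needleman–Wunsch semantics;
match 5 / mismatch −4 for nucleotide, BLOSUM62 for protein; gap open 10,
extend 0.5), with identity defined as identical columns over all aligned
columns, gaps included in the denominator. Because no published method is
named for the identity figures, every identity report carries its alignment
length, and the aligner settings are fixed and stated here.

## Bioassay statistics

**Growth inhibition.** GI = 1 − (TWIT/TNIT)/(TWIBC/TNIBC), where TWIT/TWIBC
are total live weights and TNIT/TNIBC total insect counts in treatment and
negative control. GI ≤ 1; negative values (treatment outgrew control) are
legal; a zero-weight or zero-count control is a hard error. GI is invariant
to splitting a treatment across wells.

**LC50.** Mortality is modelled as a binomial log-logistic curve on
log10(dose), `p(d) = c + (1−c)·expit(b₀ + b₁·log10 d)`, where the floor `c`
is an Abbott-style control-mortality correction estimated from pooled
dose-0 wells — applied automatically when control mortality reaches 5 %,
forceable either way. The likelihood is maximized directly
(Nelder–Mead with a moment-based start); with the floor off the estimate
matches a standard binomial GLM to high precision (cross-checked in tests).
LC50 = 10^(−b₀/b₁), the dose where corrected mortality is 50 %. The 95 %
confidence interval is a profile likelihood over log10(LC50) (deviance
cutoff 3.84), searched by bracketing and bisection. All-dead or all-alive
designs return a non-converged fit with no point estimate; non-monotone
dose patterns are noted but fitted.

**GI50.** A two-parameter log-logistic curve is least-squares fitted to
per-dose pooled GI; GI50 is the dose where the fitted curve crosses 0.5.
The CI is a seeded within-dose bootstrap of wells (default 1000 resamples;
the seed is a required input).

**Root protection.** Node-injury scores (NIS, 0–1 scale) convert to binary
pass/fail at NIS ≤ 0.5 (the boundary passes). Raw per-construct pass
proportions with binomial SEM are always reported. When two or more test
dates are present, a fixed-effects logit model
η = intercept + construct + test date supplements them — a deliberate
simplification of a mixed model with random date effects, flagged in the
output; complete separation (a construct uniformly passing or failing)
skips the model with a warning rather than reporting unstable effects.

**qPCR.** Relative expression is the efficiency-corrected ratio
E_target^ΔCt_target / E_ref^ΔCt_ref with ΔCt = mean Ct(control) − mean
Ct(treated); knockdown % = 100·(1 − ratio). With both efficiencies exactly
2 this reduces to the textbook 2^−ΔΔCt (pinned by test). Replicate-level
ratios are exposed when replicate counts align. Efficiencies ≤ 1 are
rejected.

## Synthetic data

All generators are pure functions of (spec, seed) with one explicit RNG
stream; same seed, byte-identical output.

**Transcriptomes.** Single-ORF transcripts with i.i.d. nucleotides at a GC
target (default 50 %), lengths uniform in a range (default 0.9–2 kb, a
typical mRNA scale). ORF-bearing transcripts carry a planted principal ORF
of ≥ 450 nt — long enough that a 200-nt window survives the 70-nt margins —
realized as ATG + non-stop codons + stop; a transcript whose random flanks
happen to harbour a competing ORF at least as long is redrawn. Not
emulated: codon-usage bias, splice isoforms, UTR composition, sequencing
error. Tests passing on this generator show the algorithms are correct on
clean single-ORF transcripts, not that they are robust to assembly
artifacts.

**Ortholog triplets.** Three sequences are derived from one base ORF with
codon-aware mutation: nonsynonymous codon swaps set protein divergence,
synonymous single-nt swaps top up nucleotide divergence — decoupling the
two levels, as real orthologs show (high amino-acid identity over lower
nucleotide identity). Mutations are split into "only sequence 1",
"only sequence 2", and "both, identically" classes sized so all three
pairwise identities land near the same target (tolerance ±3 points).
Planted maximal shared matches are realized by keeping the designated pair
identical over a window, breaking the window's similarity to the third
sequence (and to the base, when neither member is the base) every < 21 nt,
and forcing flank mismatches so the match length is exact. A repair pass
then breaks any accidental shared run of ≥ 21 nt between any pair,
preferring synonymous edits; consequently realized identity saturates
around 95–96 % — a sequence with no 21-nt identical run cannot exceed ~95 %
positionwise identity — which matches the most conserved real case used
here (95.8 %). The planted structure is verified by the brute-force oracle
in tests before the main engine is trusted with it. The bundled
`conservation_triplets` fixtures are synthetic stand-ins for the real
ortholog sets (which are not redistributable here); they reproduce the
reported identity levels and the exact shared-match catalogue: rop — no
matches ≥ 21 nt; dre4 — a single 22-mer; rpii140 — 23/26/29-mers
(dvv–ma), a 26-mer (dvv–tc), and two 23-mers, a 26-mer and a 32-mer
(ma–tc).

**Diet bioassays.** Deaths are binomial along
`p(d) = c + (1−c)/(1+(d/LC50)^−slope)` with defaults: an 8-point four-fold
dilution series from 500 ng/cm² (the high-dose screen concentration),
true LC50 20 ng/cm² (mid-range of the reported 2.7–103.7 ng/cm² span),
slope 2, control mortality 2 % (clean but not sterile controls), 16 insects
per dose in 8-insect wells. Per-survivor live weights are normal with a
dose-suppressed mean (its own log-logistic, GI50 10 ng/cm²). The LC50
recovery experiment under these conditions sits near the information limit:
with ~128 insects per assay the median relative error of the ML estimate is
~15 % and varies by a few points across seed blocks (an oracle fit given
the true control floor cannot do better than ~16 % when the 2 % floor is
active), while profile-CI coverage is a stable 93–95 %.

**Root trials and qPCR.** NIS scores are drawn so that P(NIS ≤ 0.5) equals
the construct's pass probability, shifted on the logit scale by a per-date
offset (degenerate probabilities 0/1 bypass the offset). Ct values place
the target's treated mean log_E(1/(1−knockdown)) cycles above control with
the reference gene unshifted, so the Pfaffl ratio recovers 1 − knockdown in
expectation; replicate noise is normal (default SD 0.15 cycles).

## Pipeline and configuration

The end-to-end runner executes orthologs → ORF placement → enumeration →
screening → ranking → T7 templates → conservation report, writing only
plain-text artifacts (FASTA/BED/TSV/JSON) plus a run report with per-stage
attrition counts and a full config echo. Output is a pure function of
(inputs, config, seed); no timestamps enter artifacts, and reruns are
byte-identical. Config is JSON validated up front with all errors —
constraint violations and missing paths — collected into one message.
Coordinates are 0-based half-open everywhere internally, matching BED.

## Known limitations

- No mismatch-tolerant (seed-and-extend inexact) off-target model; the
  screen is exact-match at the siRNA length scale only.
- The identity figures depend on the stated aligner settings; other
  gap penalties would shift values by fractions of a percent.
- The root-protection model uses fixed date effects, not the random effects
  of a full mixed model; with few dates the two agree closely, and raw
  proportions are always reported alongside.
- The synthetic triplet builder cannot realize identity targets above
  ~96 % while also guaranteeing no accidental 21-nt shared run.
- The E-value calibration is intentionally simple (ungapped constants);
  thresholds, not tool-exact E-values, are the contract.
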
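# Methods

`mulmir` reimplements, as a tested library, the analysis chain of a
three-tissue plant small-RNA sequencing study: read cleaning, annotation,
conserved-miRNA cataloguing, hairpin-based novel miRNA prediction,
tissue-bias calling, target prediction, and qRT-PCR quantification. This
note records the models, the tunable parameters, the numerical choices,
and what the synthetic test bed does and does not demonstrate.

## Read cleaning and collapsing

Raw reads are filtered (mean Phred < 20 discarded — the threshold is a
package choice, configurable; reads containing N discarded), the 3'
adapter is located by the longest adapter-prefix match against the read
(minimum overlap 6 nt, at most one mismatch) and removed, and inserts
outside the 18–30 nt retention window are dropped. Survivors are
collapsed to unique sequences with counts. Reads in which no adapter is
found are kept untrimmed when their full length already lies in the
window, so pre-collapsed public data pass through unchanged. Cleaning is
idempotent and collapse conserves read mass; both are property-tested.

## Annotation cascade

Unique reads are classified by a priority cascade, first hit wins:
rRNA → tRNA → snRNA → snoRNA → miRNA → repeat → exon (sense/antisense) →
intron (sense/antisense) → unannotated. Structural ncRNA matching is
exact-substring in either orientation against user-supplied reference
sets; "miRNA" requires full-length identity with a mature reference
entry. Putting miRNA ahead of repeat/exon/intron means miRNAs residing in
annotated introns are not lost to the degradation classes. The cascade is
deterministic: reference insertion order never changes a label. The
per-category totals plus unannotated always partition the clean total.

## Conserved catalog and conservation profiles

A unique read identical (full length, exact — no isomiR shifts) to a
reference mature becomes a conserved miRNA; per-tissue counts are summed
per sequence. Family labels are "miR" plus the leading integer of the miR
token (arm suffixes and letter variants stripped). Within a family,
members receive letter suffixes a, b, c… in descending total abundance
(the original catalog's assignment order is unknowable, so no statistic
depends on the letters). Presence in a tissue means count > 0.

The cross-species profile compares each mature against per-species
reference sets by unit-cost edit distance (edlib; an O(nm) DP oracle
cross-checks it in the tests). Distance 0 → "++", 1–3 → "+", otherwise
"−". Edit distance rather than Hamming keeps matures of unequal length
comparable. A family counts as found in a species when any member is "+"
or "++" there; the "less conserved" set is families found in at most two
of the seven species.

The published 85-entry catalog (counts and symbols) and the three
libraries' clean-read totals ship as package data; every catalog
statistic in the tests and the acceptance script is recomputed from those
tables at run time.

## Folding engine

Secondary structure comes from a self-contained Zuker-style dynamic
program: stacking energies from a nearest-neighbor table (Turner-like
ΔG37 values, kcal/mol, shipped as package data and checked for
strand-exchange symmetry at import), plus logarithmic hairpin and bulge
penalties, a linear internal-loop penalty with an asymmetry term, and an
affine multiloop cost (a = 3.4, b = 0.4 per branch, unpaired free).
Minimum hairpin loop 3 nt; interior loops capped at 30 unpaired;
no dangles, no terminal-AU penalty, no tetraloop bonuses, 37 °C only.
The DP is numba-compiled; traceback re-derives the optimum from the
filled matrices.

An oracle mode scores −1 per pair with all penalties zero and the
interior-loop cap lifted, which reduces the recursion exactly to Nussinov
maximum pairing; the tests compare it against brute-force enumeration of
all nested pairings on short sequences. The energy-mode engine is also
cross-checked loosely against an independent thermodynamic folder on a
planted stem (both must call it stable). An external folder can be
plugged in via `fold(seq, engine=...)`, but every shipped result and test
uses the built-in engine, so the −18 kcal/mol and MFEI 0.85 thresholds
are engine-relative by construction.

MFEI = (|MFE|/length × 100) / GC%; AMFE = |MFE|/length × 100. Duplexes
(miRNA:target and miRNA:miRNA*) are scored ungapped and antiparallel:
position i of the miRNA faces position L−1−i of the site; the energy sums
stack terms over consecutive paired positions, so removing a pair can
only weaken binding (monotonicity is property-tested).

## Novel miRNA discovery

Unannotated reads are mapped to the genome (exact, full length, both
strands). Each locus seeds two candidate windows — mature on the 5' arm
(20 nt upstream flank, 300 + 20 nt downstream) or on the 3' arm
(mirrored) — clipped at contig ends; minus-strand loci are evaluated in
read orientation. Windows carry a 40 nt margin beyond the star-space
bound so that boundary violations are measured rather than silently
truncated. The window is folded, the precursor excised as the
mature–star extent plus 20 nt flanks, and refolded; reads whose partners
fall inside the mature itself are rejected as loop-spanning.

The miRNA* is predicted from the fold with the Dicer convention of 2-nt
3' overhangs on both strands: star = [partner(m₁−3), partner(m₀) + 3)
with partners extrapolated from the nearest paired position. Duplex
statistics are read off the fold over all paired mature positions:
symmetric unpaired positions count as mismatches (5' terminal gaps
included, up to 2 nt of 3' overhang excluded); an event with unequal
unpaired counts on the two sides is an asymmetric bulge of size
|gₘ−gₛ|; duplex asymmetry is the net difference of total unpaired
between the two sides (so opposed bulges cancel, matching the Mireap
convention).

Twelve pass/fail filters fill the candidate's criteria ledger — nine
structural: supporting-read lengths 18–25 nt; representative read 20–23
nt; ≤ 20 genomic copies (finalized at catalog level); precursor MFE
< −18 kcal/mol (strict); mature–star space ≤ 300 nt; ≥ 16 paired mature
positions; largest bulge ≤ 4; asymmetry ≤ 4; ≥ 20 nt flanks — and three
manual: MFEI ≥ 0.85 (inclusive), < 3 asymmetric bulges, < 4 mismatches.
A candidate is accepted when all structural filters pass AND (all manual
filters pass OR the predicted miRNA* is itself observed in a library,
within a ±2 nt end-shift tolerance). The star rescue never overrides a
structural failure — the stricter reading of an ambiguous rule.
`star_observed` is recorded on every candidate as a fact rather than a
thirteenth filter, because the rescue is a disjunct, not a conjunct: a
candidate whose only anomaly is an unobserved star is simply accepted on
the manual branch, and a manual-filter decoy necessarily lacks an
observed star (it would otherwise be rescued). The knockout suite
therefore proves twelve single-failure rejections plus a
rescue-acceptance, which together exercise all thirteen published
criteria.

Accepted candidates group by mature sequence into catalog entries;
matures at more than 20 loci are dropped entirely (counted after the
cap). When the duplex partner of an accepted mature seeded its own
accepted candidate (the star arm read both ways), the more abundant
strand keeps the entry and the other is recorded as its star. Entries
are named miRn1, miRn2, … in descending total count.

## Expression and qRT-PCR

Counts are normalized to reads per million using each library's
clean-read total as denominator (the published analysis says only
"normalized reads"; the clean-read choice reproduces the printed leaf and
bark family lists exactly). Family counts are summed from members before
normalization. A unit is tissue-biased when its RPM in one tissue is at
least (inclusive) twice the RPM in each other tissue and nonzero; it is
tissue-specific when its raw count is zero everywhere else. All-zero
units are unbiased. Under this denominator the miR167 family misses the
2× male-flower bound by about 1% while miR5523 (reads 0/1/2) clears it,
so the male-flower family composition — though not the count of 8 — is
sensitive to the unknown original denominator; the leaf and bark lists
are not.

2^−ΔΔCt: replicate Cts are averaged per assay and sample; the reference
Ct is the arithmetic mean of the reference assays' mean Cts (equivalent
to a geometric mean of their linear quantities — the combination rule for
the two reference genes is a package choice); ΔCt = Ct_target − Ct_ref,
ΔΔCt = ΔCt_sample − ΔCt_calibrator, RQ = 2^−ΔΔCt. The calibrator's RQ is
identically 1. No amplification-efficiency correction is applied.

## Target prediction

Every length-L window of a transcript (sense strand, ungapped) is scored:
(1) weighted mismatches ≤ 4, G:U = 0.5; (2) no run of > 2 consecutive
mismatch positions; (3) no adjacent mismatch positions within 2–12;
(4) positions 10 and 11 Watson–Crick; (5) weighted mismatches over 1–12
≤ 2.5; (6) duplex energy ≥ 75% of the miRNA's perfect-complement energy.
G:U wobbles count as mismatch *positions* for rules 2–4 (strict reading
of "no mismatches at 10 and 11"); `gu_blocks_positions=False` switches to
the lenient reading. The scanner is verified equivalent to a brute-force
window evaluator written from the rule definitions.

## Synthetic data: what it shows and what it does not

The generator emulates the study's structure with machine-readable truth:
a toy genome with planted hairpins (each verified at generation time to
satisfy every discovery criterion under the shipped engine, with two G:U
wobbles per stem so hairpins are not exact palindromes), knockout decoys
each violating exactly one criterion (constructed compositionally — e.g.
A-only bulge stretches inside A-free stems so the fold cannot re-pair
around the designed lesion — and re-drawn up to 100 times until the
evaluator confirms the single-failure signature), three 50,000-read
tissue libraries (21/24-nt-dominated length profiles; planted conserved
miRNAs at 3× effects for biased families, comfortably clearing the 2×
call under multinomial noise; ncRNA/degradation fragments; ~50% random
background; adapters appended; a sprinkle of low-quality and N reads),
a multi-species mature reference at controlled edit distances 0/2/5,
transcripts with compliant and single-rule-knockout target sites, and
noise-free-derivable Ct tables. A single integer seed drives one child
RNG stream per artifact; outputs are byte-identical across runs.

Passing recovery tests therefore shows the pipeline implements its own
rules faithfully and recovers structure planted under those rules. It
does not show performance on real data: the generator has no sequencing
errors, no isomiR heterogeneity, no multimapping ambiguity beyond the
planted copies, exact (not heuristic) reference matching, and planted
conserved miRNAs that deliberately do not reside in the toy genome.
Problem sizes (50,000 reads per library, ~30 kb genome, ~10 true
hairpins) were chosen so the statistical margins are meaningful while a
full run stays in the minutes range.

## Known limitations

* The folding engine is simplified; absolute MFEs differ from full
  thermodynamic folders by up to tens of percent on long sequences, so
  the energy thresholds are meaningful relative to this engine.
* Target scanning is ungapped and sense-strand only; bulged target sites
  are not modeled.
* No isomiR handling: a read one shift away from a reference mature is
  not conserved, by design.
* Differential expression is a deterministic threshold rule; no
  replicate-based statistics are provided because the emulated design has
  one library per tissue.
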
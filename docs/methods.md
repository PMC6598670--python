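# Methods

This note records the models, conventions and numerical choices behind
`promkit`, and what the synthetic data do and do not establish.

## Coordinate and sequence conventions

Promoters are stored 5′→3′ as given; offset 0 is the distal end of the
2-kb upstream region and the TSS sits immediately 3′ of the last base,
so distance to the TSS is `length − position`. All intervals are 0-based
half-open, matching BED; human-readable reports derive from the same
values. Input residues are uppercased and any symbol outside
{A, C, G, T, N} becomes N (with a logged count) rather than raising:
genome-browser dumps routinely contain soft-masked and ambiguous bases,
and rejecting them would make real inputs unusable. An N never counts
toward GC content (excluded from numerator and denominator), breaks STR
units and G-runs, and matches a motif position only when that position
allows all four bases — a masked base cannot confirm a specific match.

## Expression classification

The HK definition is four-fold: detected in every tissue of the panel
(detection threshold 1.0 FPKM by default — a common convention, exposed
as a parameter because results depend on it and no single threshold is
canonical); across-tissue uniformity by a one-sample two-sided
Kolmogorov–Smirnov test against U(0,1) on the min–max-normalized profile
with cutoff *P* > 0.1; every value within [mean/4, 4·mean]; and all
transcripts of the gene passing. The KS construction is the only
uniformity test that is scale-free (rescaling all FPKM leaves the
normalized profile unchanged); a constant profile has *P* = 1 by
convention. The fourfold band is read two-sided: an abnormally *low*
tissue violates uniform housekeeping expression just as a spike does.
TS labels exist at both levels: a transcript is TS-like when expressed
in 1–3 tissues; a gene is TS when it is not HK, has at least one
expressed transcript, and every expressed transcript is TS-like
(gene-level consistency mirroring HK criterion iv).

## Element scanners

**CpG islands.** The windowed rule set (100-bp window, GC > 0.5,
O/E > 0.6, length ≥ 200) leaves the merge procedure underdetermined, so
it is fixed here completely: slide the window by 1 bp, mark island-like
windows, merge overlapping marked windows into maximal regions, trim each
region to its outermost CpG dinucleotide, and keep regions that still
satisfy all three thresholds when recomputed over the whole region. Every
reported island therefore verifies its own invariants from the raw
sequence. O/E of a region of length L with c C's, g G's and n CpG
dinucleotides is n·L/(c·g), defined as 0 when c·g = 0.

**STRs.** A locus is a maximal period-k run (every base equals the base
k earlier) reported at its primitive unit only — a unit that is itself a
power of a shorter unit (including mononucleotides) is reported at the
shorter period, which prevents AC/ACAC double counting. Copies are the
whole number of unit repetitions from the run's first base; ≥ 7 copies
("more than six") by default. Overlapping arrays of *different* primitive
units are each reported, and no cross-family deduplication is attempted:
a planted CG-dinucleotide island legitimately also scores as a CG-unit
STR, the same double counting real scans exhibit.

**PQS.** A candidate is four G-tracts of one common length g ≥ 2
separated by loops ≥ 0 within a 30-bp span, enumerated exhaustively on
both strands. The score rewards long tracts and even loops:
Σ over loops of (10 − |loop − median loop|) + 10·(g − 2). Overlaps are
resolved greedily — descending score, then ascending start, then end,
strand and tract length as deterministic tie-breaks — into a mutually
non-overlapping hit set; the pre-resolution candidate set is exposed
separately (`pqs_candidates`) because it is the natural object to verify
against independent enumeration. The four-tract reading of "minimum
number of units = 4" is the structural requirement of a quadruplex; the
alternative (minimum run length 4) would make a bare G₁₆ run the minimal
hit, contradicting how quadruplex mappers with loop size 0 behave.

**Motifs.** IUPAC patterns are matched position-by-position; reverse
strand hits come from matching the reverse-complement pattern on the
forward sequence and are reported in forward coordinates with strand −.
All overlapping occurrences are reported.

## Substitution rates

Nei–Gojobori counting: per sense codon, each position contributes one
site split by the fraction of its three single-nucleotide changes that
are synonymous under the standard code, so syn + nonsyn sites sum to 3
exactly. Changes creating stop codons count as nonsynonymous by default;
an "excluded" policy (removing them from the per-position denominator)
is available because reference implementations differ and the choice is
rarely stated — both modes are tested. Differences between codons at 2
or 3 positions are averaged over all 2 or 6 mutational pathways,
excluding pathways through stops (if every pathway hits a stop, all are
used with stop steps counted nonsynonymous). Codons containing a gap or
N in either sequence are skipped (pairwise deletion); S and N are means
of the two sequences' site totals. pS = Sd/S and pN = Nd/N are
Jukes–Cantor corrected, d = −¾ ln(1 − 4p/3); p ≥ ¾ is reported as a
saturated (nan) rate with a flag rather than an exception mid-table, and
ω = dN/dS is nan when dS = 0.

The selection Z-test resamples codon columns with replacement (500
replicates by default, seeded); Z = (dN − dS)/√(Var dN + Var dS) against
the standard normal, two-sided. Bootstrap rather than the analytic
variance because the per-codon contribution vectors are already in hand
and the bootstrap is assumption-free; degenerate variance (identical
sequences) returns *P* = 1. The promoter rate dP is the raw p-distance
after pairwise deletion — on the scale such surveys report (a TS-class
value of 0.64 is only interpretable as an uncorrected proportion, since
its JC correction would exceed 1.1); JC correction is an option.

`align_global` is a textbook Needleman–Wunsch with linear gap scoring
(match +1, mismatch −1, gap −2) and deterministic tie-breaking
(diagonal > up > left), provided for unaligned inputs; it aligns
nucleotides, not codons, which is a documented simplification — the
pipeline's simulated pairs are gap-free, and externally aligned pairs
are taken as given. Pearson correlations between dP and coding rates
drop non-finite pairs pairwise and refuse zero-variance inputs.

## Group comparisons

Mann–Whitney U, two-sided: exact null by full enumeration when the
combined sample is ≤ 12 without ties, otherwise the normal approximation
with midrank tie correction and continuity correction (the continuity
correction matters at small n and is stated here because the convention
varies between implementations). Summary tables report mean ± SEM
(sd/√n) per feature with raw p-values; no multiple-testing correction is
applied across feature rows, matching how such tables are conventionally
presented.

## Synthetic data: what it emulates, and what it does not

**Expression.** HK transcripts are drawn around 17.1 FPKM (the level
such panels report for HK genes) with mean-preserving multiplicative
tissue effects of coefficient of variation `noise_cv` (default 0.1).
The effects are *stratified uniform* — each tissue occupies one quantile
stratum of a bounded band, in random order — rather than i.i.d., because
the KS uniformity criterion defines housekeeping-likeness as an evenly
spread profile: i.i.d. noise of any scale concentrates values centrally
and fails the criterion for roughly a third of genuinely stable
transcripts (measured pass rates ≈ 0.69 log-normal, ≈ 0.90 uniform,
≈ 1.0 stratified at n = 21). True-HK profiles must satisfy the
definition by construction or recall would measure generator–classifier
disagreement, not classifier correctness. TS transcripts are expressed
log-normally around 6.43 FPKM in 1–3 uniformly chosen tissues and below
threshold elsewhere. "Other" transcripts each violate exactly one HK
criterion, recorded per transcript: an evenly spaced profile dipping
below the detection threshold (detection only), a two-cluster profile
inside the fourfold band (KS only), and an evenly spaced grid spanning
1.2–12× the threshold whose low end breaks the mean/4 bound while the
even spacing keeps KS happy (fold only). These constructions are
deliberately engineered so violations do not cascade; real "other" genes
fail criteria jointly, so per-criterion error attribution on real data
would be less clean.

**Promoters.** Background is i.i.d. with per-base GC probability
(defaults 0.46 HK / 0.45 TS). Planted elements are written verbatim at
recorded intervals with one guard base per flank chosen to break the
period (for STRs: left guard ≠ last unit base, right guard ≠ first) so
the recorded interval is exactly the maximal array. Around a planted PQS
the background is additionally sanitized within the 30-bp span limit —
G-G and C-C adjacencies outside payloads are broken — so no background
candidate can overlap and outscore the planted hit; without this, exact
interval recovery would fail at a low but nonzero rate by honest chance.
An i.i.d. background has no nucleosome structure, no repeat families and
no TATA/Inr positional grammar; element *densities* in the bundle are
inputs, not predictions.

**Divergence.** Codon mode draws a stop-free ancestor, proposes
Poisson(t·n_codons) single-nucleotide changes and accepts them with
relative ratio ω : 1 for nonsynonymous : synonymous (stop-creating
changes rejected) — an accept/reject scheme, not a full codon
substitution model, adequate for recovering the sign and approximate
magnitude of ω at these scales (measured: ω = 1 recovered within
(0.73, 1.13) over 20 seeds at 2,000 codons). Promoter mode substitutes
each site independently with probability p_site. The study bundle ties a
gene's promoter and CDS divergence through a shared log-normal per-gene
modifier (CV 0.3) applied on the JC-corrected distance scale, which
induces the positive dP-versus-dN/dS correlation across genes that
motivates comparing the two; ω itself is class-constant, so dP~ω
correlations are near zero in the bundle — a known limitation.

## Problem sizes and determinism

The analysis and acceptance runs use 150 genes per class, 21 tissues,
2-kb promoters, CDS lengths of 727/491 codons (HK/TS, the class-mean CDS
lengths such surveys report), 500 bootstrap replicates per Z-test, and
100 neutral pairs of 500 codons for the calibration check — sizes chosen
so the whole study reruns in well under a minute on one core while
keeping binomial error small relative to the effects studied. Every
random draw flows from a single seed through `numpy.random.default_rng`;
rerunning the pipeline with one config reproduces every TSV/BED byte for
byte (only the run log carries a timestamp), and this is asserted, not
assumed.

## Known limitations

De novo motif discovery and motif-to-factor annotation are out of scope
(the motif scanner consumes given consensus patterns); STRs must be
perfect (no approximate repeats) and mononucleotide runs are never
reported; the aligner is nucleotide-level; the Mann–Whitney exact path
requires tie-free small samples; and none of the synthetic results
transfer quantitatively to real genomes — the tests establish that the
scanners, classifier and estimators implement their stated rules
exactly and recover planted truth, not that any particular density or
rate holds in a real promoter set.
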
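# Methods

This note describes the models and procedures implemented in `splicemap`,
the choices made where the design was genuinely open, and what the
synthetic data do and do not establish.

## Coordinates, events and sequences

Coordinates are 0-based half-open internally; GTF is read as 1-based
closed (via gffutils) and BED exports are 0-based half-open. "Upstream"
and "downstream" always refer to transcript orientation: on the minus
strand the upstream intron is genomically right of the exon, and all
extracted sequences are reverse-complemented to the sense strand.

A cassette-exon event carries the exon interval, both flanking introns,
the regulation label (`up`/`down` under regulator depletion, or one of the
two reference classes) and ΔPSI for regulated events. Reference sets are
built from expressed genes that host no regulated event: an internal exon
present in every transcript is *reference constitutive*; one present in
some but not all transcripts is *reference cassette*, restricted to single
cassette exons (some transcript lacking the exon must equal a containing
transcript minus that exon; multi-exon alternatives are excluded). When
transcripts disagree on the flanking introns, the shortest flank is used —
deterministic and conservative for sequence extraction. Flanks are clipped
at the intron boundary (never crossing into a neighbouring exon) and at
contig ends, with a `truncated` flag. `N` bases match no motif letter and
are excluded from both numerator and denominator of GC content.

## Splice-site strength

Site strength is a first-order position weight matrix log-odds in bits.
Windows follow the de facto standard: donor = last 3 exonic + first 6
intronic nt; acceptor = last 20 intronic + first 3 exonic nt. Matrices are
trained on constitutive junctions (≥ 20 usable sites; windows containing N
are skipped) with pseudocount 0.5 per cell, against a background estimated
from the pooled window composition. A window containing N scores absent
rather than imputed. A PWM was chosen over more elaborate dependency
models because training data are fully controlled here and only relative
group comparisons are consumed downstream.

## Branchpoint and polypyrimidine tract

A deliberately transparent heuristic replaces trained branchpoint
predictors. Within a 15–250 nt window upstream of the acceptor, each
adenine is scored against the yUnAy consensus (+1 for each of: pyrimidine
at −3, U at −2, pyrimidine at +1 relative to the A); the best-scoring
adenine wins, ties resolving to the adenine closest to the acceptor. The
PPT is the maximum-weight contiguous segment (Kadane's algorithm; empty
segment allowed with weight 0) between the branchpoint and acceptor−3
under weights T=+2, C=+1, A=G=N=−2; ties prefer the segment closest to the
acceptor, then the shorter one. The implementation is verified against an
exhaustive scan over all adenines and all segments on randomized fixtures;
the weights and window are configuration-exposed.

## Motif discovery

Discovery is discriminative, DREME-style, on sequence-level presence:

1. enumerate every exact word of widths 4–8 occurring in the positive set
   (regulated exon + flanks, concatenated);
2. rank by the one-sided Fisher exact test of presence in positives versus
   negatives (computed as the hypergeometric upper tail, vectorized);
3. greedily generalize the best core one position at a time to IUPAC
   classes, keeping a step only if it strictly lowers p (ties: lowest p,
   then smallest class, then lexicographic code);
4. report the motif with its E-value = p × number of distinct exact words
   tested (a conservative Bonferroni), erase matched sites (replaced by N)
   from the positives, and repeat up to `max_motifs`.

Matching is sense-strand only — RBP motifs act on the pre-mRNA — and
overlapping occurrences count. Site counts are used only for the
per-sequence count statistics (Welch t-tests) and the χ² presence test
(computed without continuity correction); enrichment itself is driven by
presence, matching the discriminative statistic.

## Positional profiles

Match centers are mapped onto a meta-exon axis: 250 absolute
upstream-intron positions anchored at the 3'ss, the exon scaled to 100
bins, 250 absolute downstream-intron positions anchored at the 5'ss. The
raw profile is matches-per-position divided by the number of sequences, so
`raw.sum() × n` equals the number of mapped matches exactly; the reported
density is a Gaussian smoothing (σ = 10 positions, `mode="constant"`).
Matches spanning an exon/intron junction in the original transcript are
attributed per region and matches farther than 250 nt from a splice site
are dropped. The exon is scaled (rather than kept absolute) because exon
lengths vary several-fold; flanks stay in absolute nt because splice-site
proximity is the biologically meaningful coordinate.

## Compendium matching and regulator nomination

The compendium is read from MEME-minimal files (Bio.motifs), with RNA
alphabet U mapped to T. A query position-probability matrix is slid along
each target requiring ≥ 4 overlapping columns; the alignment score is the
mean per-column Pearson correlation of probability columns (a constant
column correlates 1 with an equal column, else 0). Significance comes from
a seeded permutation null that shuffles the target's columns and retakes
the best alignment; the add-one p-value counts only strictly better
permutations as more extreme, because shuffles of a target identical to
the query recreate the perfect score and counting such ties would penalize
exact matches, which must rank first. Ranking is by p, then similarity.

Concordance encodes the nomination logic: with a positive
regulator-of-the-RBP effect (the default; the polarity is a parameter),
exons *down*-regulated on depletion should correlate *positively* with the
RBP's expression across patients and up-regulated exons negatively.
Spearman ρ uses average ranks; the two-sided p is an exact permutation
enumeration for n ≤ 8 and the large-sample t approximation otherwise (full
enumeration beyond that is computationally disproportionate, and cohort
records require ≥ 10 complete pairs anyway). A record is concordant when
the sign matches and p ≤ α (default 0.05); records with constant PSI or
too few pairs are flagged unusable, not dropped silently. The positional
consistency check asks whether each direction's profile peak falls in the
region the RNA-map rule predicts (down ⇒ downstream intron; up ⇒ upstream
intron or exon) and reports the peak location and peak/background ratio.

## Cohort statistics

Differential PSI uses the two-sided Wilcoxon rank-sum test per event
(exact when both groups are ≤ 25 and tie-free, otherwise the
tie-corrected normal approximation), Δ median PSI with an explicit group
order, Benjamini–Hochberg adjustment across tested events, and the
significance rule |Δ median PSI| ≥ 0.1 and FDR ≤ 0.01 (both thresholds
exposed). Events below three non-missing values per group are reported
untested rather than non-significant. Overlap tests are upper-tail
hypergeometric probabilities and require the universe explicitly — the
choice of universe is the main analytic ambiguity in this kind of
comparison, so there is no silent default. Direction agreement between two
comparisons is a 2×2 Fisher exact test with a configurable polarity map.

Survival stratification fits Kaplan–Meier curves per PSI stratum
(lifelines) and compares them by log-rank test. In optimal mode the cutoff
is the observed PSI value minimizing the log-rank p among splits leaving
≥ 10% of patients per side, ties resolving to the cutoff closest to the
median; the function warns that this p is nominal, since scanning cutoffs
inflates significance.

## Synthetic data

The generator is a deterministic function of its seed and writes a
ground-truth manifest (class labels, planted motif regions and offsets,
planted correlations, the prognostic event and its hazard boundary) so
every recovery test has an oracle.

*Gene structure.* One contig per gene; each gene has five exons with an
inclusion transcript and a skipping transcript lacking the middle exon, so
the middle exon is a single cassette exon and the two other internal exons
are constitutive. Exons are 80–200 nt, introns 300–500 nt; strands are
random. Defaults mirror the study conditions: 48 up- and 91 down-regulated
events (139 regulated genes) and 400 reference genes (400 reference
cassette + 800 constitutive exons) — the reference:regulated imbalance of
the real annotation at desk scale.

*Splice sites and composition.* Donor/acceptor sites are drawn from
vertebrate-like consensus frequency matrices by Boltzmann sampling at a
class temperature (probability ∝ f^(1/T)): regulated exons at T = 2.0,
reference cassette at 1.3, constitutive at 1.0, which reproduces the
weak-exon ordering by construction. Introns flanking regulated exons use
GC 0.35 versus 0.45 for reference introns; exons use GC 0.50.

*Motif planting.* A degenerate word (default CATGCAD) is planted in 65% of
regulated events versus 10% of reference events, downstream of the exon
for down-regulated events and in the upstream flank or exon for
up-regulated ones; reference plants are unbiased. Chance occurrences are
scrubbed from the background (outside splice-site windows and planted
spans), so planted presence is observed presence. Splice-site windows are
never overwritten; residual chance matches overlapping those windows
(~1% of events) are left in place.

*Cohort.* Event PSI is a logistic transform of a latent Gaussian tied to
the RBP's expression through a Gaussian copula; because Spearman
correlation is invariant under the monotone link, the planted ρ (sign +
for down-regulated events, − for up-regulated; Pearson parameter
2·sin(πρ/6)) is the true Spearman value. TNBC samples receive a ±0.3 PSI
shift on designated events, signed by regulation direction (the regulator
promotes the TNBC-specific variant). The designated prognostic event uses
a steeper link giving a near-uniform PSI spread; survival times are
exponential with the hazard multiplied by 3 above PSI 0.5, under
independent exponential censoring calibrated to a 10% censored fraction
(mild censoring keeps the planted boundary identifiable; heavier censoring
only degrades cutoff recovery, not the estimator).

*What passing tests do and do not show.* The generator plants exactly the
structure the analysis assumes: a single motif with clean positional bias,
monotone PSI–expression dependence, a sharp hazard threshold, no batch
effects, no annotation errors, no correlated events, and independent
samples. Passing therefore demonstrates correctness of the machinery and
calibration of the statistics, not performance on real RNA-seq-derived
data, where motif redundancy, co-regulation, confounded subtypes and
heavy censoring will all reduce power.

## Problem sizes and numerical choices

Default analyses run at desk scale (hundreds of genes, 100-patient
cohorts, 10–20 seeded replicates for stochastic checks), which keeps the
full test suite and the acceptance script to a few minutes. Fisher/
hypergeometric tests are exact; BH uses statsmodels; Welch t-tests are
used wherever the variance structure is unknown (group sizes differ by an
order of magnitude between regulated and reference sets). Degenerate
inputs are explicit: empty sequence sets are errors, all-N sequences give
absent GC, events with unusable windows give absent scores, and absent
values propagate as missing rather than zero.

## Known limitations

- The PWM splice-site score ignores positional dependencies; absolute
  scores are not comparable to maximum-entropy implementations, only group
  contrasts are meaningful.
- The branchpoint heuristic targets the canonical yUnAy context only.
- Motif discovery's E-value correction is a conservative Bonferroni over
  exact words; generalized words are not separately corrected.
- The compendium match is a similarity ranking, not a calibrated motif
  alignment statistic; only the ranking is consumed.
- Optimal-cutoff survival p-values are nominal by construction.
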
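# splicemap

Cassette-exon characterization, discriminative RNA-motif maps and
splicing-regulator nomination.

When knocking down a regulator (for instance a nuclear kinase in
triple-negative breast cancer cells) changes the inclusion of a set of
cassette exons, the natural follow-up questions are: *what kind of exons are
these*, *which sequence element marks them*, *which RNA-binding protein
(RBP) reads that element*, and *does the program matter in patients*?
`splicemap` is a library for answering those questions from standard inputs
— a genome FASTA, GTF gene models, a regulated-event table with ΔPSI
(percent-spliced-in change), cohort PSI/expression matrices and an RBP
motif compendium — plus a seeded synthetic-data generator that produces all
of these with known ground truth, so every stage is testable offline.

## What it computes

**Reference sets and sequence features.** Internal exons of expressed,
non-regulated genes are split into *reference cassette* exons (present in
some but not all transcripts, single-exon alternatives only) and *reference
constitutive* exons (present in 100% of transcripts). Splice-site strength
is a first-order PWM log-odds score in bits over the standard windows
(donor: 3 exonic + 6 intronic nt; acceptor: 20 intronic + 3 exonic nt),
trained on constitutive junctions with pseudocount 0.5:

    score(w) = Σ_i log2( p_i(w_i) / q(w_i) )

The branchpoint is the adenine in a 15–250 nt window upstream of the 3'ss
maximizing a yUnAy consensus match; the polypyrimidine tract is the
maximum-weight contiguous segment between branchpoint and acceptor−3 under
weights T=+2, C=+1, A=G=−2. Group differences use Welch's t-test.

**Motif discovery and RNA maps.** A DREME-style discriminative search:
enumerate exact words (widths 4–8) in the regulated sequences
(exon ± 250 nt intronic flanks), rank by one-sided Fisher exact test on
sequence-level presence against the reference sets, greedily generalize the
best core to IUPAC classes while p improves, report, erase matches, repeat.
Occurrence centers are mapped to a meta-exon axis (absolute flank
positions, exon scaled to 100 bins) to give positional profiles per
regulation direction.

**Regulator nomination.** The discovered motif is compared to a
MEME-format RBP compendium by best-offset mean column Pearson correlation
with a seeded column-shuffle permutation null. The nominated RBP is then
tested for concordance in a cohort: Spearman correlation of each event's
PSI with the RBP's expression should be positive for exons down-regulated
on regulator depletion and negative for up-regulated ones; a
position-dependent rule (activator from the downstream intron, repressor
from the upstream intron/exon) is checked against the profiles.

**Cohort statistics.** Differential PSI between sample groups (Wilcoxon
rank-sum, Benjamini–Hochberg FDR, significant when |Δ median PSI| ≥ 0.1
and FDR ≤ 0.01), hypergeometric set-overlap tests with an explicit
universe, Fisher direction-agreement tests, and Kaplan–Meier survival
stratified by a PSI cutoff (fixed, or the observed value minimizing the
log-rank p — reported as nominal).

## Worked example

`examples/` contains one narrative script per capability. The end-to-end
run (`python examples/06_full_pipeline.py`) generates the default synthetic
study — 139 regulated cassette exons (48 up / 91 down), 400 reference
cassette and 800 constitutive exons, a 100-patient cohort — and prints:

```
{
 "direction_agreement": {"fisher_p": 1.75e-38, "fraction_agreeing": 1.0, "n": 139},
 "fraction_concordant": 1.0,
 "n_prognostic_events": 14,
 "n_significant_differential": 139,
 "positional_consistency": {"down": "consistent", "up": "consistent"},
 "presence_chi2_p": 3.26e-75,
 "profile_peaks": {"down": "downstream_intron", "up": "exon"},
 "top_motif": "CATGCA",
 "top_rbp": "RBFOX2",
 "top_rbp_similarity": 1.0
}
```

Reading this: discovery recovered the planted motif word; its occurrences
peak downstream of the 5'ss for down-regulated exons and within the exon
for up-regulated ones, consistent with the activator-downstream /
repressor-upstream RNA map; the compendium match names the planted RBP;
every significant PSI–expression correlation has the expected sign
(`fraction_concordant` 1.0); all 139 events are differentially spliced
between the simulated subtypes with full direction agreement; and 14 of the
20 events screened for survival stratify patients at nominal log-rank
p ≤ 0.05.

The same run is available as a CLI for file-based use:

```
splicemap simulate --outdir inputs --seed 42
splicemap run-all --config run.yaml     # paths + thresholds in YAML
```

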
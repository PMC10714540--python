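# Methods

## Overview

`metadomain` evaluates two families of evidence for classifying rare missense
variants, both built on the idea of aggregating sparse data across paralogous
protein domains:

1. **Variant co-localisation (PM5 and its benign mirror).** A *different*
   pathogenic missense change previously reported at the same amino-acid
   position supports pathogenicity (ACMG/AMP criterion PM5). The analysis is
   extended to *meta-positions*: structurally equivalent residues across all
   instances of a domain family, so that a pathogenic variant in one paralog
   can inform an equivalent position in another.
2. **Missense constraint (PP2 and its benign mirror).** Depletion of missense
   variation in population data signals purifying selection. A *meta-domain*
   constraint score pools population variation over every instance of a
   domain family; externally computed per-gene (missense Z, missense o/e) and
   per-region (CCR) scores are evaluated by the same machinery.

Both evidence types are scored against clinically labelled variants in a
contingency framework, summarised by the positive likelihood ratio
`LR+ = sensitivity / (1 − specificity)` and mapped onto evidence-strength
categories with the Tavtigian-framework thresholds: supporting (LR+ ≥ 2.08),
moderate (≥ 4.33), strong (≥ 18.71), all boundaries inclusive. A table with
zero false positives yields an infinite LR+, which is propagated as a flagged
value with category "strong", never numerically capped.

## Coordinate backbone

Transcripts are modelled as stranded, rank-ordered exon intervals (1-based,
inclusive, VCF/Ensembl convention) plus a coding sequence. Residue *i*
occupies CDS positions 3i−2..3i projected through the exons in transcription
order; codons freely span exon junctions, and on the minus strand the three
genomic coordinates of a codon descend. Each codon carries exactly nine
possible SNVs (three per base), annotated as missense, synonymous or nonsense
from the standard genetic code. Changes at the reference stop codon (stop
retention or stop loss) fall outside that trichotomy; they are labelled
`other` and excluded downstream. Transcripts failing structural validation
(exon/CDS length mismatch, internal stops, translation not matching a
supplied protein sequence exactly) are skipped with a logged warning rather
than aborting a run.

## Meta-position numbering

Domain alignments are read from Stockholm files in the PFam dialect:
uppercase letters and `-` are match states, lowercase letters and `.` are
insert states. Match columns are numbered 1..L with deletions consuming a
label without emitting a residue; inserted residues take an incremental
suffix from the preceding match column (`12+1` is the first insertion after
column 12; insertions before the first match column attach to pseudo-column
0). Two residues anywhere in the proteome sharing a (family, column) label
form a meta-position. Members whose aligned letters disagree with the
supplied protein sequence are excluded (alignment and transcript set then
describe different isoforms); multiple instances of a family in one protein
are independent members and all contribute.

The Stockholm reader is implemented in-package because general-purpose
alignment readers normalise `.`/lowercase insert states into plain gaps and
uppercase, destroying exactly the state distinction the numbering is defined
on.

## Co-localisation evidence

Clinical assertions are pooled per variant: a variant is labelled pathogenic
if all its classifications are P/LP, benign if all are B/LB, and dropped
otherwise (no review-status weighting, no rescue of majority opinions among
conflicting submissions). Only missense SNVs are analysed. "Same position"
means the same (protein, residue); a co-localised record only counts as a
*different* variant when its amino-acid substitution differs from the
query's, so two genomic changes producing the identical substitution are not
mutual evidence.

* **Standard PM5** — positive for a query iff at least one different
  co-localised variant exists and all of them carry the evidence direction's
  label. Positives at queries of that label are TP, at opposite-label queries
  FP; all non-positive queries (opposite, mixed, or no co-localised set)
  count FN/TN.
* **Meta-position PM5** — each meta-position is assigned from the multiset of
  labels of all clinical variants mapped to it: two or more concordant
  variants assign the position; a single variant is *unique*; mixed labels
  are resolved by one of two rules — *no-conflict* (any disagreement voids
  the assignment) or *majority* (plurality wins, exact ties conflict). A
  query is positive iff its meta-position is assigned to the evidence
  direction. By default the query's own record is included in the counts,
  which matches position-level counting but biases the null LR+ above 1
  (the query's label feeds its own position's assignment); a leave-one-out
  mode recomputes each assignment without the query for sensitivity
  analysis, and the permutation test in the acceptance suite demonstrates
  the difference. A residue under two overlapping domain annotations is
  scored against each family and the most evidential outcome is used.
  Insertion-labelled meta-positions participate in co-localisation
  (configurable) though they are excluded from constraint.
* **Cascade** — standard PM5 first (strong evidence when positive), else
  meta-position evidence for in-domain variants (moderate), else none. The
  benign mirror runs as a parallel cascade. Cascade sensitivity dominates
  standard sensitivity by construction.

Meta-position analyses are restricted to the in-domain stratum, and the
standard-PM5 comparison in that stratum uses the same restricted variant set
so the two are commensurable.

An optional REVEL pre-filter keeps pathogenic variants with score ≥ 0.7 and
benign variants with score ≤ 0.2 (inclusive); unscored variants are dropped
in that mode, never imputed.

## Meta-domain constraint

For each domain family the background-adjusted missense/synonymous ratio is

    adjusted m/s = Σ_p (missense_obs / missense_poss)
                 / Σ_p (synonymous_obs / synonymous_poss)

where `poss` counts the possible SNVs of each class at position *p* given the
codon (the 9-way enumeration above, nonsense excluded from both classes) and
`obs` counts distinct PASS-filtered population sites (presence/absence;
allele counts are carried but deliberately unused, since the statistic counts
variants, not alleles). The sums run over all non-insertion positions of all
family members. Positions are deduplicated within a family by their codon's
genomic coordinates, so a locus shared by several transcripts counts once
per family while still contributing to every family that covers it.

Two numerical decisions matter:

* **Complete-case positions.** The per-position sums include only positions
  where both classes are possible. Codons with no possible synonymous change
  (Met, Trp) cannot contrast the two classes; including their missense terms
  would shift the neutral expectation from 1 to the composition ratio
  N_mis/N_syn (≈ 1.08 for typical sequence), defeating the purpose of the
  adjustment. With complete-case sums the score's expectation under neutral
  sampling is exactly the missense/synonymous observation-rate ratio, and the
  calibration tests verify convergence to 1 (neutral) and to the simulated
  selection multiplier otherwise.
* **Per-position vs pooled sums.** The default aggregates per-position
  obs/poss ratios; a pooled alternative, `(Σobs_m/Σposs_m)/(Σobs_s/Σposs_s)`,
  is available behind a flag for sensitivity analysis. A raw `Σobs_m/Σobs_s`
  ratio is always reported alongside.

A family whose synonymous denominator is zero gets a missing score — never 0.

### Thresholds

The pathogenic threshold for the adjusted m/s score is chosen from a
1000-step sweep of equally spaced thresholds between the minimum and maximum
observed score: the least stringent (highest, for low-is-constrained metrics)
threshold whose LR+ still meets the moderate-evidence bound of 4.33. Sweep
points with an empty contingency cell are emitted with an explicit
`defined = False` flag rather than dropped. The benign threshold mirrors the
pathogenic one to the opposite side of the score distribution at the same
number of standard deviations from the mean; CCR scores are centile ranks of
a bimodal distribution, so their benign threshold is simply 100 minus the
pathogenic threshold. External metrics require explicit thresholds in
configuration — the package invents no defaults for published tools.
Variants without a score never meet a threshold; their number is reported.

## Synthetic data generator

The generator (`metadomain.synthetic`) produces every input class the
pipeline consumes, from a single seed, byte-identically reproducible:

* **Genome and transcripts** — protein-coding genes on both strands with 1–4
  exons; the first gene always contains a junction-spanning codon and strands
  alternate, so both code paths are always exercised.
* **Domain families** — a consensus sequence per family; members diverge by
  substitutions (rate 0.3 per column), deletions and insertions (rate 0.02
  per column each), and are emitted as Stockholm alignments with correct
  match/insert column structure.
* **Population variation** — each possible SNV is an independent Bernoulli
  site observation with probability `mutation_rate` (default 0.3), scaled for
  missense SNVs inside a family's domains by that family's *selection
  multiplier* `s ∈ (0, 1]` (defaults 1.0…0.05 across six families). Under
  this model the closed-form expectation of the per-position adjusted m/s is
  `s` itself, which the calibration tests exploit. A small fraction (3%) of
  observed sites carries a non-PASS filter flag to exercise filtering; the
  thinning is class-uniform so it leaves the expectation at `s`.
* **Clinical assertions** — `n_pathogenic`/`n_benign` (60/60) labels on
  missense SNVs. With probability `meta_cluster_weight` (0.6) a new label is
  placed at an already-labelled meta-position (within which, with probability
  0.3, at the same protein residue — creating same-protein co-localisation);
  otherwise placement is family-weighted: pathogenic labels favour
  constrained families (weight ∝ 1.02 − s) and benign labels are strongly
  depleted from them (weight ∝ s² + 0.02), emulating the clustering of
  pathogenic variation in constrained domains that makes domain-level
  constraint informative. Half the benign labels fall outside domains.
  Setting a single multiplier of 1.0 and zero cluster weights yields the
  label-independence null used in the permutation test.
* **Scores** — REVEL-like values drawn from Beta(8,2) for pathogenic and
  Beta(2,8) for benign variants, for 90% of labelled variants.

The generator does **not** attempt human trinucleotide mutation spectra,
sequencing-coverage models, ClinVar review-status structure, or realistic
PFam family-size distributions; passing tests therefore demonstrate the
correctness and calibration of the machinery under the stated model, not
performance on real cohorts. Default problem sizes (six families of three
members, 40-residue domains, 120 clinical labels, ≈10,000 simulated SNVs; 5000
positions for constraint calibration) were chosen so every property is
measurable at tight sampling error while a full run stays in the low seconds.

## Reported quantities and degenerate cases

Reports carry one row per (criterion, rule, direction, filter) with the full
contingency table, unique/conflicting tallies, sensitivity, specificity, PPV,
LR+ and strength. Strata with an empty truth class are emitted with an
explicit `not_evaluable` marker rather than dropped. On small synthetic
datasets zero false positives are common; the acceptance script reports such
likelihood ratios with a Haldane (0.5) continuity correction so that its JSON
output is finite, and says so.

## Limitations

* Recomputing the published contingency tables for the real ClinVar/gnomAD/
  PFam corpus requires the study's deposited per-variant classification list,
  which is too large to redistribute here; the acceptance suite documents
  this as an explicit failure rather than silently skipping the check.
* Evidence types are evaluated in isolation; no posterior combination of
  criteria is attempted, and the circularity between constraint metrics and
  population-frequency criteria is out of scope.
* Gene-level and regional external metrics are consumed as score tables;
  the package does not recompute missense Z, o/e or CCR from raw data.
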
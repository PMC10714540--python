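# metadomain

Aggregating missense-variant evidence across paralogous protein domains.

Rare missense variants are hard to classify because direct evidence at any
one residue is sparse. This package implements a pipeline for two evidence
classes used in ACMG/AMP-style classification, extended by pooling data
across *meta-positions* — structurally equivalent residues in all paralogous
instances of a protein-domain family:

* **PM5 / PM5(benign)** — a different pathogenic (benign) missense variant at
  the same residue of the same protein, extended to variants at the same
  meta-position in other proteins, with a cascading strong → moderate logic;
* **PP2 / PP2(benign)** — a meta-domain missense-constraint score, the
  background-adjusted missense/synonymous ratio

  ```
  adjusted m/s = Σ_p (missense_obs / missense_poss) / Σ_p (synonymous_obs / synonymous_poss)
  ```

  summed over non-insertion domain positions, where `poss` is the exhaustive
  9-SNVs-per-codon enumeration and `obs` counts distinct PASS population
  sites. Low values indicate missense depletion (purifying selection).

Evidence performance is evaluated in a Bayesian framework: contingency tables
over pathogenic/benign labelled variants give the positive likelihood ratio
`LR+ = sens / (1 − spec)`, mapped onto evidence strengths supporting
(LR+ ≥ 2.08), moderate (≥ 4.33) and strong (≥ 18.71).

It is aimed at clinical-genomics methods developers who want to calibrate
domain-aggregated evidence on their own variant sets, entirely from flat
text inputs (exon tables + FASTA, Stockholm alignments, ClinVar-like and
gnomAD-like TSV/VCF-style tables), with a seeded synthetic-data generator so
every stage is testable without downloads.

## Worked example

Generate a synthetic bundle (14 genes on both strands, six domain families
with selection multipliers 1.0 → 0.05, 120 clinical labels) and run the full
pipeline:

```
metadomain synth --seed 1 --out bundle
cat > run.yaml <<EOF
genome: bundle/genome.fa
exons: bundle/exons.tsv
stockholm: bundle/domains.sto
clinical: bundle/clinical.tsv
population: bundle/population.tsv
revel: bundle/revel.tsv
EOF
metadomain run --config run.yaml --out out
```

The report (`out/report.tsv`) holds one row per analysis; the unfiltered
pathogenic-direction rows print as:

```
              criterion        rule  direction filter  tp  fp  fn  tn  unique  conflicting     sens      spec  lr_plus strength
           PM5_standard             pathogenic    all  38   0  22  60      63            0 0.633333  1.000000      inf   strong
 PM5_standard_pfam_only             pathogenic    all  38   0  22  25      38            0 0.633333  1.000000      inf   strong
               PM5_meta no_conflict pathogenic    all  50   0  10  25      18            0 0.833333  1.000000      inf   strong
            PM5_cascade no_conflict pathogenic    all  50   0  10  60      43            0 0.833333  1.000000      inf   strong
        PP2_adjusted_ms             pathogenic    all  52   2   8  58       0            0 0.866667  0.966667     26.0   strong
 PP2_benign_adjusted_ms                 benign    all  24  23  36  37       0            0 0.400000  0.616667    1.043    below
```

Reading the numbers: 63 of 120 labelled variants are *unique* (no
co-localised variant), so standard PM5 recovers 38/60 pathogenic variants;
pooling meta-positions lifts the cascade's sensitivity from 0.63 to 0.83. At
this sample size no benign variant co-localises with a pathogenic assignment,
so those LR+ values are flagged infinite rather than capped. The constraint
threshold selected from the 1000-step sweep (0.451, `out/manifest.json`)
separates constrained from tolerant families — `out/constraint.tsv` shows the
six family scores tracking their simulated selection multipliers
(1.03, 0.88, 0.45, 0.33, 0.14, 0.06 for s = 1.0, 0.7, 0.5, 0.3, 0.15, 0.05)
— while the mirrored benign threshold yields LR+ ≈ 1: absence of constraint
is no evidence of benignity.

Every stage is also exposed as its own subcommand (`simulate-snvs`,
`map-domains`, `annotate`, `pm5`, `constraint score|evaluate|sweep`) and as a
plain library (`metadomain.transcripts`, `.alignments`, `.annotation`,
`.pm5`, `.constraint`, `.evaluation`, `.synthetic`, `.pipeline`).

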
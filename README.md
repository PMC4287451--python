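# te-stress

Transposable elements (TEs) make up the bulk of the maize genome, and some
TE families carry stress-responsive regulatory sequence: genes with an
insertion of such a family within 1 kb upstream of their transcription
start site (TSS) are disproportionately up-regulated under abiotic stress
(cold, heat, salt, UV). `te_stress` implements that analysis as a tested,
reusable pipeline for anyone working on TE-proximal regulation in plant
genomes: it classifies per-gene stress responses from RNA-seq counts, tests
every TE family for enrichment of responsive neighbours, quantifies TE
family expression under strict read filters, attributes the transcriptome
response to enriched families, and runs the mechanistic follow-ups (strand
bias, distance decay, DREB/CBF motif scanning, exemplar positional
enrichment, transcript start-site comparison). A synthetic-data module
generates maize-like genomes with planted effects and truth tables, so the
whole pipeline is exercised end to end with known answers.

## The statistics at the core

Per contrast (genotype × stress), each gene is classified from RPKM
(reads per kilobase of merged exon space per million mapped reads):

* `not_expressed` if RPKM ≤ 1 in both conditions;
* `up` / `down` if |log2((RPKM_s + 0.5)/(RPKM_c + 0.5))| ≥ 1 and, with
  replicates, adjusted p < 0.1 (a gene is *activated* when up-regulated
  with control RPKM ≤ 1);
* `nonDE` otherwise.

For a TE family whose TSS-proximal expressed genes split into counts
(n_up, n_down, n_nde) with n = n_up + n_down + n_nde, against background
proportions (p_up, p_down, p_nde) over all expressed genes:

* fold enrichment FE_up = (n_up / n) / p_up, and
* a multinomial goodness-of-fit p-value
  P[ G(X) ≥ G(obs) ], X ~ Multinomial(n, p), with the log-likelihood-ratio
  statistic G = 2 Σ_i o_i log(o_i / n p_i) — computed by exact enumeration
  of all compositions for n ≤ 60 and seeded Monte Carlo above.

A family is *enriched* when n > 10, FE > 2 and p < 0.001 (all strict).
TE families themselves are quantified as RPM from reads fully contained in
an insertion that map to ≤ 5 genomic locations.

## Worked example

```
python analysis/01_simulate.py --seed 1     # synthetic genome + counts + truth
python analysis/02_enrichment.py --seed 1   # assignment, classification, enrichment
```

prints, for the default conditions (5,000 genes, 40 families, 4 planted
enhancer-like families at effect 2.5 log2 and penetrance 0.6):

```
TE families enriched for up-regulated neighbours:
family type  genes  %up      F.E.  log2 stress/control
 fam11  RLX     13 54.0  9.193246             2.442917
 fam19  TIR     18 61.0 10.433604             2.283815
 fam21  TIR     18 50.0  8.536585             2.456229
 fam32  RLG     26 69.0 11.819887             2.353258

up-regulated genes: 287 (activated: 3)
attributed to enriched families: 15.7% (activated subset: 33.3%;
baseline over expressed genes: 1.5%)
```

The four called families are exactly the four planted ones: each has more
than 10 expressed neighbours, 50–69% of them up-regulated (%up), an 8–12×
fold enrichment over the ~6% background up-rate, and a TE-expression log2
ratio near the planted 2.5. About 16% of all up-regulated genes — versus a
1.5% baseline over expressed genes — lie next to an enriched-family
insertion; that is the attributable share of the transcriptome response.
`analysis/03_recovery_null.py` scores recovery across seeds and
`analysis/04_mechanism.py` summarises the mechanistic follow-ups.

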
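# Methods

## Coordinates, TSSs and signed distances

All intervals are 0-based half-open internally (BED convention); GFF3 input
(1-based closed) is converted on ingest and written back 1-based. A gene's
TSS is the strand-aware 5' end of the gene-level feature: `start` on `+`,
`end − 1` on `−`. Genes with several transcripts use the gene feature's 5'
end; there is no per-isoform TSS.

The signed TE–TSS distance follows closestBed-style gap counting: 0 when
the insertion interval contains the TSS base, otherwise the count of bases
from the TSS to the nearest TE edge, so an element ending on the base
immediately before the TSS is at distance 1. Distances are positive on the
gene's 5' (upstream) side and negative on the 3' side. TE–gene assignment
defaults to `upstream_only` (0 ≤ d ≤ 1000 bp), matching how the
attribution analysis counts "1 kb 5' of the TSS"; a `symmetric` mode
(|d| ≤ window) is available and every report table records the mode used.
The TSS window used by the start-site analysis extends upstream from the
TSS (100 bp by default) and is truncated at the chromosome start.

Unmapped TE superfamilies default to RLX — the unknown-retrotransposon
class — with a warning.

## Expression and response classes

RPKM = count / (merged exon kb) / (library size / 10^6); replicate RPKMs
are averaged per condition before forming ratios. All log2 ratios add a
0.5 pseudocount to both numerator and denominator, which bounds ratios for
silent genes; "expressed" means RPKM > 1 (strict) in at least one
condition, and the 2-fold rule is |log2 ratio| ≥ 1 (inclusive). With
replicates a gene must additionally reach adjusted p < 0.1; the
single-replicate mode applies the expression and fold-change rules alone.
A gene is *activated* when classified up with control RPKM ≤ 1 and stress
RPKM > 1.

### Stand-in differential-expression test

Adjusted p-values are accepted from any external DE tool as a per-gene
table. When none is supplied, the package applies its own stand-in: a
two-group negative-binomial Wald test. Group means are compared on the log
scale with a delta-method standard error under Var = μ + αμ², where the
dispersion α is pooled across all genes by the moment estimator
α̂ = Σ(v − m) / Σ(m² − v/n) (the denominator corrects the squared sample
mean for its own sampling variance; a per-gene moment ratio at n = 3 is
hopelessly noisy and median-biased). Pooling buys a normal reference
distribution instead of a 4-df t, which is what makes 2–2.5 log2 effects
detectable at n = 3 after Benjamini–Hochberg correction across 5,000
genes. This is deliberately *not* a per-gene shrinkage model à la DESeq:
it assumes a common dispersion and will be conservative for genes whose
dispersion is far above the pool. Identical groups return p = 1; BH across
genes is applied by the caller.

## TE-family expression

A read counts toward an insertion iff its aligned span lies fully inside
the insertion interval and the read maps to ≤ 5 genomic locations (taken
from the NH tag for SAM input, or the `locations` column of the TSV
alignment dialect: chrom, start, end, locations, sample_id — both inputs
share one code path after ingest). Counts are summed per insertion, then
per family; RPM uses the pooled library size of each condition. A read
inside two overlapping insertions of *different* families counts once per
family — containment is tested independently per element — while nested
insertions of one family count it once. The family log2(stress/control)
ratio (0.5 RPM pseudocount) is reported only when both raw counts reach 10
reads; otherwise it is flagged unavailable, mirroring the "NA" entries of
family-level report tables whose exact criterion is not standardised.

## Enrichment testing

Per family, distinct expressed TSS-proximal genes are partitioned into
up / down / nonDE (a gene counts once per family however many insertions it
has; `not_expressed` genes are excluded everywhere). The default
background is all expressed genes in the contrast; `all_genes` and
`te_associated_genes` backgrounds are exposed as a robustness check rather
than assumed equivalent.

The goodness-of-fit test uses the log-likelihood-ratio statistic
G = 2 Σ o_i log(o_i / n p_i) with 0·log 0 = 0, chosen over Pearson's X²
because it enumerates exactly and retains the χ²₂ asymptote. For
n ≤ 60 the p-value is the exact tail sum over all (n+1)(n+2)/2
compositions (clipped to 1 against float accumulation); above that, a
seeded Monte-Carlo tail with the add-one estimator
p = (1 + #{G_sim ≥ G_obs}) / (n_mc + 1), default 10⁵ draws. A tolerance
of 10⁻⁹ on the statistic comparison keeps ties (e.g. the observed table
itself) inside the tail. Enrichment calls use strict thresholds — more
than 10 expressed genes, FE > 2, p < 0.001 — with no multiple-testing
correction for the headline calls; a BH-adjusted column is emitted
alongside for transparency. Attribution counts a gene once even when it
neighbours two enriched families.

## Mechanistic follow-ups

* **Strand bias** — per family, a 2×2 table of up vs nonDE genes ×
  same vs opposite strand (gene-level, nearest insertion), two-sided
  Fisher exact test, BH across families. Chosen for exact small-sample
  behaviour; the underlying convention in the field is often unnamed.
* **Distance decay** — genes binned by the distance of their nearest
  family insertion (upstream only), default edges 0/250/500/1000/2000/5000
  bp (bin boundaries are this package's choice), responsive proportion per
  bin.
* **Motif scan** — the DREB/CBF consensus A/GCCGACNT as IUPAC `RCCGACNT`,
  scanned with per-position base-class lookup tables; overlapping hits all
  count, both strands by default (a plus-strand-only flag reproduces
  single-strand counting conventions), and an N in the sequence matches
  only an N in the pattern.
* **Positional enrichment** — per exemplar position, the coverage
  proportions of insertions near responsive vs non-responsive genes; the
  enrichment ratio adds a +1 pseudocount to counts (and +1 to group
  sizes); enriched regions are maximal runs ≥ 50 bp with ratio ≥ 4, each
  scored by a Fisher exact test on full-region containment. Pseudocount,
  run length and ratio threshold are configurable.
* **Start sites** — only genes with an insertion ≥ 100 bp 5' of the TSS
  are compared. `novel_te_start_stress_only`: control transcript starts
  within the gene model or the 100-bp TSS window while the stress
  transcript starts within the TE ± 50 bp (the slack operationalises
  "near the TE" and is configurable); `upstream_both`: both starts beyond
  the TSS window (incomplete annotation); otherwise `concordant`, or
  `no_data` when either condition lacks a transcript.

## Synthetic data

The generator emulates the data regime the analysis assumes, not raw
sequencing: ~5,000 non-overlapping genes (1–4 exons) on 5 chromosomes; 40
TE families, Poisson(40) insertions each, half placed 1–1000 bp upstream
of random TSSs and half intergenic (kept clear of every TSS window so the
truth table is exact; insertions never overlap one another). Four planted
families exert an up-only cis effect of 2.5 log2 on in-window neighbours
with penetrance 0.6 (optionally attenuated exponentially with distance);
effects are up-only because enriched family–stress combinations in this
regime are overwhelmingly up-associated, while a 10% background fraction
responds with random sign at 2.0 log2. Penetrance sits inside the 26–87%
per-family range such analyses observe. Baseline expression is log-normal
(log2 RPKM ~ N(3, 1.5²)); counts are negative binomial with
Var = μ + 0.1 μ² (the "dispersion" convention is stated because it varies
between packages), scaled to a 5×10⁶-read library over 3 replicates per
condition, single genotype and stress — shared-ancestry multi-genotype
simulation is out of scope.

Alignment records plant Poisson(8) retained reads per insertion and
condition (planted families up-scaled by the cis effect), plus ~10% decoys
with > 5 locations and ~10% decoys straddling a TE edge; a generation
ledger of retained counts is the oracle for the filter-fidelity check.
Consensus sequences are motif-scrubbed random DNA, with Poisson(2)
DREB/CBF sites planted into planted families; the exemplar coverage set
plants one 300-bp region covered by 90% of responsive vs 10% of
non-responsive insertions (backgrounds matched on either side); five
planted TE-promoter genes emit stress transcripts from mid-TE.
Start-site candidate genes are restricted to those with exactly one near
insertion at ≥ 150 bp so "nearest TE" is unambiguous and truth exact. One
global seed fans out through named `SeedSequence` children, so adding a
generator never perturbs earlier streams and all outputs are reproducible
byte for byte.

What the synthetic data does **not** model: sequencing error and raw reads,
isoform structure beyond gene-level TSSs, GC or mappability biases,
genotype sharing, correlated placement of TE families, and realistic
per-gene dispersion variation. Passing recovery tests therefore show the
pipeline's logic and calibration are sound under its stated assumptions,
not that real maize data would yield these effect sizes.

## Problem sizes and numerical choices

The recovery suite runs 20 simulations at the full default conditions and
the null suite 50; per-family tests there use exact enumeration (typical
n ≈ 15–30) or 2×10⁴ Monte-Carlo draws, and the 2,000-family null
calibration uses 4,999 draws per family — sizes chosen so the whole
analysis reruns from scratch in minutes on a single core while leaving
Monte-Carlo error well below the decision thresholds. Degenerate inputs
resolve to flags rather than errors wherever a report can still be
written: empty families and zero background rates yield NaN fold
enrichments, degenerate 2×2 tables yield NaN p-values, and empty distance
bins report n = 0 with an unavailable proportion.

## Known limitations

* The stand-in DE test shares one dispersion across genes; heavy-tailed
  per-gene dispersion would inflate its false-positive rate.
* Exact multinomial enumeration is limited to three response classes.
* Fold enrichment is undefined (NaN) when the background class rate is
  zero; such families are never called enriched.
* The start-site classifier considers a single nearest upstream insertion
  per gene and does not model multi-TE promoters.
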
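# Methods

## The model

CpG islands — CG-dense stretches of mammalian genomes — are normally
unmethylated, and two *cis*-encoded mechanisms are thought to keep them
so: the density of CG dinucleotides itself, and the binding of
transcription factors (TFs). `methylib` implements the computational
machinery for dissecting the two: an insertion-library workflow
(fragmenting CG-rich regions, reading their methylation by bisulfite
sequencing) and the models built on top of it.

The core quantitative object is the **CG-only model**: the methylation a
DNA fragment acquires is a sigmoidal function of its CG density

    y(x) = y_min + (y_max - y_min) / (1 + exp(-b (x - c)))

with both asymptotes fixed before fitting (y_max = 100%, y_min = 0%),
because full and absent methylation are the known saturation states of
methylation data. Only the slope `b` (per CGs/100 bp, negative) and the
inflection density `c` (CGs/100 bp) are free. The package's reference
coefficients are `b = -0.337`, `c = 6.917`; with these, predicted
methylation falls below 20% once density exceeds ~11.0 CGs/100 bp — the
regime where density alone protects a sequence.

CG density is CG dinucleotide starts per 100 bp, computed either over a
whole fragment (fragment length as denominator) or over a 300 bp window
centred on a single CG (window truncated at contig edges and normalised
by its actual length). CpG is its own reverse complement, so
forward-strand counting is strand-complete.

The **combined model** adds TF-binding information through DNase
hypersensitivity: per-CG DNase cut counts collected in a window around
each CG (300 bp by default) are winsorised at the 0.99 quantile,
log2(x+1)-transformed, and binned into five ordered categories with
"zero cuts" as its own category. Observed methylation is regressed by
ordinary least squares on the sigmoid prediction plus category indicator
variables (additive main effects, no interaction — the simplest form
consistent with "a linear model combining the two"). Models are fitted
on exactly two contigs and evaluated on the rest of the genome;
R-squared is 1 - SSE/SST on held-out CGs, not a squared correlation.
Prediction accuracy is also summarised as the proportion of CGs
predicted within ±20 methylation points (inclusive), per segment class.

## The synthetic data generator

No real data ship with the package; every analysis runs on synthetic
genomes whose statistical structure matches what the models assume.

* **Sequence.** CG density is the modelled covariate, so it is
  controlled directly rather than emerging from i.i.d. base sampling:
  CG dinucleotides are planted at evenly spaced positions (jittered
  within their slots) to hit each region's target count, and every other
  base is drawn left-to-right under two constraints — never a G directly
  after a C, never a C directly before a fixed G — so that no CG ever
  arises outside the planted set. Realised island densities land within
  a fraction of one count of their targets. Island-like regions
  (defaults: 800–2000 bp, 3–20 CGs/100 bp, mirroring the CGI spectrum)
  sit in a CG-poor background (1 CG/100 bp, the mammalian genome-wide
  scale) with at least 300 bp between islands.
* **TF sites.** Motif instances (default: the REST consensus, whose one
  CG the density accounting includes) are planted anywhere on the
  contig, pairwise non-overlapping, with factor identities assigned
  round-robin. Background sites emulate CG-poor distal regulatory
  regions (the LMR phenomenology), island sites emulate bound CGIs.
* **Methylome.** Unbound CGs take exactly the sigmoid of their local
  300 bp density. CGs within 150 bp of a bound site are reduced
  multiplicatively by the TF effect (default 90%), which keeps values in
  [0,100] without clipping and makes bound sites near-fully
  hypomethylated, as observed at occupied regulatory regions.
* **DNase cuts.** Cut events are Poisson: 15 expected cuts per bound
  site spread uniformly over a ±150 bp footprint, on a uniform
  background of 15 expected cuts per 300 bp. These rates put the data in
  the moderate-enrichment regime (~2x over background at a site centre
  within a 300 bp window) deliberately: the collection-window experiment
  is only informative when background noise is non-negligible. At very
  high enrichment any nonzero count is a perfect binding detector and
  the smallest candidate window always wins the scan, for any rate
  choice — the matched-filter optimum at the generating footprint exists
  only against noise, as it does in real DNase libraries.
* **Bisulfite reads.** Reads sample both strands uniformly within each
  fragment; at each CpG the cytosine survives conversion with
  probability methylation/100 (symmetric across strands), all other
  cytosines convert at the conversion rate (default 1.0). Reverse-strand
  reads are emitted as the reverse-strand sequence, i.e. G→A on the
  forward frame. Read names carry fragment, strand and start for oracle
  tests. Sequencing error and PCR duplication are not modelled.
* **Condition pairs.** Differentiation-like: CGs bound only by lost
  factors revert to the sigmoid prediction (always a gain) and their
  cuts reset to the background rate; everything else is untouched.
  Cancer-like: every island CG gains a flat ε (default 30 points,
  clipped at 100) regardless of density. For analyses that need two
  *independently measured* conditions (the DNase-change association),
  the second condition is generated afresh from the reduced site set on
  the same genome, so both methylome and DNase track carry independent
  noise.

What passing tests on these data do **not** show: that real methylomes
follow the sigmoid at these exact coefficients, that real TF effects are
multiplicative with a sharp 150 bp boundary, or that real DNase
backgrounds are uniform Poisson. The generator establishes that the
pipeline recovers whatever structure of this family is present — a
correctness statement about the machinery, not a biological claim.

## Study conditions (problem sizes)

Three frozen configurations (`methylib.studies`) drive the analyses,
tests and the reproduction script:

* *Prokaryotic-library analogue* — 3×60 kb, 12 islands/contig spanning
  3–20 CGs/100 bp, no TF sites: density is the only determinant, as in
  the bacterial-DNA libraries. Digested with MspI (CCGG), size-selected
  100–600 bp, sequenced at 50x, fragments ≥250 bp fitted.
* *Window scan* — 4×50 kb, no islands (uniform density 2 CGs/100 bp),
  40 TF sites/contig: binding is the only source of methylation
  variance, the clean design for locating the optimal DNase collection
  window among {100, 200, 300, 600, 1000} bp.
* *Dynamics* — 3×60 kb, 10 islands and 60 TF sites per contig: binding
  dense enough that factor loss changes a few percent of CGs in every
  prediction bin, which a per-bin 99th-percentile profile can resolve.

These sizes were chosen so each experiment has the statistical power its
claim needs while a full run of every analysis stays in the minutes
range on one core.

## Library design and calling rules

Digestion scans every (possibly overlapping) occurrence of each
palindromic recognition site on the forward strand; with a methylome
given, a site of a methylation-sensitive enzyme is not cut if any CG
inside it exceeds the masking threshold (default 50% — "methylated
regions" without a stated cutoff). Cut offsets are the canonical ones
(NarI GG^CGCC, BstUI CG^CG, BssHII G^CGCGC, MspI C^CGG). Size selection
is inclusive at both bounds. The reference set drops *every* member of
any overlapping cluster, leaving pairwise-disjoint fragments so read
assignment cannot be ambiguous by construction.

Read assignment replaces a full bisulfite aligner with a pigeonhole
seed-and-verify matcher on converted references (read C→T against
fragment C→T and against revcomp-fragment C→T), justified because the
reference set is small and disjoint; reads matching more than one
fragment are discarded. Calling filters follow the study design
literally: a CG needs ≥10 reads and must not be SNP-masked; a fragment
average (unweighted over called CGs, both strands pooled under the
symmetric-methylation assumption) requires strictly more than 50% of
the fragment's CGs and at least four CGs covered; a fragment is called
inserted when strictly more than 50% of its bases are read-covered.

## Dynamics analyses

Segmentation is a deliberate simplification of HMM-based callers:
maximal runs of ≥3 consecutive CGs at ≤30% methylation are
hypomethylated segments, UMR when they hold ≥30 CGs, LMR otherwise;
everything else becomes FMR blocks. Change profiles bin per-CG change
(second minus first condition) by the CG-density-predicted methylation
(10-point bins) and report the 99th percentile (linear interpolation
between order statistics) as a proxy for the maximal amplitude of
change, plus the median. Gains, not absolute changes, are profiled: the
directional claim is about methylation *gain* approaching the
prediction. Motif enrichment around changing CGs uses density-matched
controls (10 equal-width density bins, per-bin subsampling without
replacement, seeded), counts hits on both strands at a normalised-score
threshold ((score-min)/(max-min) ≥ 0.8 — raw log scores are negative,
so a fraction-of-maximum threshold is applied on the normalised scale),
and attaches a label-permutation p-value. Constitutive patches are runs
of ≥2 consecutive island CGs predicted below 20%.

## Numerical choices

* Sigmoid fitting: `scipy.optimize.curve_fit`, initialised at
  (b, c) = (-0.3, 7), parameter tolerance 1e-8; degenerate inputs
  (constant methylation, <3 points, density span ≤1) are rejected with
  specific errors. Noiseless model output is recovered to 1e-6.
* The noisy-recovery estimate of `b` is attenuated slightly toward zero
  (≈ -0.32 at sd-10 noise) because clipping noisy values into [0,100]
  compresses the extremes; this is inherent to the stated noise model,
  not a fitting artefact.
* PWM scoring: log(frequency + 0.01), columns normalised from counts;
  only score order matters for the best/lowest pair. Consensus ties
  break alphabetically. The bundled REST matrix is a synthetic stand-in
  pinned so that its consensus equals the published best-score motif.
* The lowest-score motif search samples seeded shuffles of the
  consensus (equal mononucleotide composition by construction) and
  keeps only candidates with the consensus's CG dinucleotide count; the
  permutation space is far too large for exhaustion.
* Quantile category edges are deduplicated before digitising, so
  heavily tied DNase counts cannot produce empty categories.

## Known limitations

* The matcher handles substitutions only (no indels) and is not a
  general aligner; it is sound only against disjoint references.
* The segmenter is rule-based; it will not reproduce HMM segment
  boundaries on real data and has no PMD class.
* Winsorisation/categorisation is fitted on all contigs jointly, not
  training contigs only; with genome-scale data the difference is
  negligible, but it is a (documented) leak of feature scaling.
* The linear alternative to the sigmoid, mentioned as performing
  equally well on the linear mid-range, is documented but not
  implemented.
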
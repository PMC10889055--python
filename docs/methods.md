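# Methods

## Problem and approach

Genome-wide association studies report lead SNPs, but the allele that drives
a regulatory mechanism is often not the lead: variants in near-perfect
linkage disequilibrium can have entirely different effects on chromatin, and
the effect of one allele can depend on which alleles its neighbors carry.
`caism` implements context-aware in-silico mutagenesis to dissect this: for a
candidate biallelic SNV it builds fixed-length sequence windows carrying
controlled allele substitutions, scores each window with a
sequence-to-chromatin-feature annotator, and quantifies how the predicted
probability of each feature changes between the major-allele and
minor-allele window — across every combination of neighboring alleles.

## Windows and coordinates

Variant positions are 1-based (VCF convention); window arithmetic is 0-based
half-open.  The window for a center at position *p* with length *L* = 2000
covers 1-based positions [*p* − 999, *p* + 1000] (999 bp upstream, 1000 bp
downstream), center at 0-based offset 999.  The reference window sets every
known variant inside it to its major allele; alternate windows substitute
minor alleles at the center and/or neighbors.  Declared alleles always win
over the assembly base: if the assembly matches neither allele, substitution
proceeds and the window is flagged `ref_mismatch:<id>`, because the
procedure is defined by alleles and silent divergence would corrupt the
ref/alt contrast.  Indels and multiallelic records are rejected at load
time; windows containing N are allowed but flagged.  All windows are built
on the forward strand; a reverse-complement pass is an optional, separately
reported analysis (see below).

## Genetic contexts

A context fixes the allele of every neighboring variant inside the window;
the center allele is always the contrast.  For *k* neighbors all 2^*k*
major/minor combinations are enumerated, in a deterministic order
(neighbors sorted by position, lexicographic with major < minor).  A
configurable cap (default 12 neighbors, 4096 sequences) fails loudly rather
than truncating silently.  When phased haplotypes are supplied, enumeration
can optionally be restricted to neighbor-allele patterns observed in the
data, since exhaustive combinations include haplotypes that may not exist;
this is off by default.

## Effect statistics and empirical calibration

For feature probabilities *P*ref and *P*alt (major- vs minor-allele window,
same context in both):

- log-odds change: Δ = logit(*P*ref) − logit(*P*alt), natural log;
- E statistic: *E* = Δ · (*P*ref − *P*alt).

Because logit is strictly increasing the two factors share a sign, so
*E* ≥ 0 with equality iff the probabilities are equal; it folds relative and
absolute change into a single magnitude.  Positive Δ means the minor allele
lowers the predicted probability; the `direction` column reports this as
"loss" (and negative Δ as "gain") for the minor allele.

Significance is empirical.  The same statistic is computed for *n* random
background variants (default here *n* = 999; the procedure scales to
millions when compute allows), giving one null distribution per feature —
not pooled, since different features have very different score dynamics.
The e-value of an observation is its add-one tail rank (*r* + 1)/(*n* + 1),
with ties counted in *r* (conservative); the smallest achievable e-value is
1/(*n* + 1), 0.001 at the default size.  Background variants are sampled
uniformly over eligible positions at least half a window from contig edges,
with the alternate allele uniform over the three non-reference bases, all
from a recorded seed.  No multiple-testing correction is applied in the core
report; a Benjamini–Hochberg column is available as a clearly labeled
extension.

Reporting thresholds default to |Δ| ≥ 1 and e ≤ 0.05.  A flagged
variant/feature pair is labeled *context-stable* when the spread of Δ across
contexts is below 25% of its median magnitude, *context-dependent*
otherwise; the fraction is configurable, and the label is this package's
explicit operationalization of "similar effect regardless of context".

## The synthetic annotator

A pretrained deep chromatin model is deliberately out of scope; the package
instead ships a deterministic motif-occupancy annotator whose ground truth
is known by construction, so every pipeline property can be verified against
closed-form expectations.  Each feature scores a raw occupancy
*s* and squashes it through a logistic p = σ(k·(s − c)) with steepness
*k* = 4 and offset *c* = 0.5 by default, clamped to [10⁻⁶, 1 − 10⁻⁶] so
logits stay finite.  Since logit(σ(x)) = x away from the clamp, a substitution
changing the raw score from *s*ref to *s*alt yields Δ = k·(*s*ref − *s*alt)
exactly — planted effect sizes are analytic.  With the defaults, one motif
match sits at p ≈ 0.88 and none at p ≈ 0.12, far from the clamp.

Feature modes:

- **single** — *s* = number of motif occurrences (both strands when the
  strand-symmetric option is on, which makes annotate(seq) =
  annotate(revcomp(seq)) exactly);
- **cooperative** — two motifs, *s* = count(M1) · (1 + count(M2)): M2
  occupancy doubles M1's contribution, so an allele toggling M1 has
  |Δ| = 2k when M2 is present versus k when absent — a planted context
  effect with a closed-form margin of exactly k;
- **dense** — a seeded per-position, per-base affinity landscape summed over
  the window; every substitution moves the score by a continuous amount,
  which makes this mode the natural null model for calibration studies of
  the e-value machinery (the motif modes give exactly-zero background
  statistics, which is ideal for planted-effect recovery but degenerate for
  uniformity checks).

N bases carry zero affinity everywhere.  An external deep-model annotator
can plug in through the same `annotate_batch` contract plus a declared
feature list; nothing in the pipeline assumes the synthetic scorer.

## Synthetic data generation

The generator materializes every input from a single seed.  The genome is
uniform-random background with motif instances written at declared variant
positions: "present with major" plants a complete instance that the minor
allele destroys (loss of function); "present with minor" plants a one-base
broken instance the minor allele completes (gain).  The background is then
sanitized so every position outside planted footprints is at Hamming
distance ≥ 2 from every motif and its reverse complement.  A single
substitution can close at most one mismatch, so no background variant — and
no unintended allele — can create or destroy a match anywhere outside the
planted sites; planted raw scores are exact integers and the background
null for motif features is exactly zero.  Background sampling for the null
additionally excludes a window-sized zone around each candidate variant, so
the null measures genuinely unplanted sequence and the planted variant's
rank is deterministic.

Phased haplotypes realize pairwise r² targets by a two-component mixture:
the partner column copies the anchor with probability √r² and is drawn
independently otherwise.  At the default 2000 haplotypes the realized r² for
a 0.98 target fluctuates by well under 0.05.  This gives exact control of
pairwise LD with no coalescent machinery; there is deliberately no
recombination map or demography.

The cohort generator draws Hardy–Weinberg genotypes at given minor-allele
frequencies and case status from a logistic model
logit P(case) = logit(baseline) + Σ ln(ORᵢ)·gᵢ + ln(OR_int)·g_a·g_b.

The default study (one 120-kb contig, seven variants) plants the three
qualitative phenomena the method exists to exhibit: a dominant
loss-of-function variant whose effect is identical in every context; a
cooperative pair whose center effect doubles when the neighbor carries the
minor allele (target pair r² 0.5); a pair in near-perfect LD (target r²
0.98) where only the anchor touches a motif; and a protective epistatic
pair in the cohort (main ORs 0.6/0.7, interaction OR 0.5, baseline case
rate 0.35, n = 2000 — a dementia-cohort-like prevalence).  A
machine-readable answer key (expected log-odds changes, the cooperative
margin, designated null variants, truly interacting pairs) is emitted
alongside, so tests compare pipeline output against construction rather
than against the pipeline itself.

What the generator does **not** emulate: real sequence composition (repeats,
GC structure), overlapping regulatory grammar, more-than-pairwise LD
structure, population stratification, genotyping error.  Passing tests
demonstrate that the statistical machinery is correct and calibrated under
known ground truth; they do not certify any particular deep annotator's
biological accuracy.

## LD analysis

r² between two loci is D²/(p_a(1−p_a)p_b(1−p_b)) with
D = f(minor,minor) − p_a·p_b over phased haplotype rows.  "Correlated
group" means the anchor-centered set of variants with r² ≥ threshold
(default 0.8); no haplotype-block-calling algorithm is used or needed.
Monomorphic variants have undefined LD and are excluded from groups with a
warning rather than silently scored 0.  The group contrast reports, per
feature, each member's no-context log-odds change, the group divergence
(max pairwise absolute difference), and flags members in near-perfect LD
(r² ≥ 0.9) with the anchor whose effect falls below the threshold the
anchor exceeds — the concrete form of "high LD does not imply similar
regulatory effect".

## Epistasis validation

Carrier-group proportions dichotomize each locus into carrier (≥ 1 minor
allele) vs non-carrier and report the case fraction in each of the four
groups, with missing genotypes excluded per pair and counted.

The epistasis test compares allelic association between cases and controls:
within each phenotype group the joint 2×2 minor/major allele-pair table for
the two loci is formed from the expected within-individual pairing
(n_mm = Σ g_a·g_b/2, etc. — the standard allelic approximation for unphased
data), and Z = (lnOR_case − lnOR_control)/√(V_case + V_control) is referred
to the standard normal, two-sided.  The textbook sum-of-inverse-cell
variance treats the 2n alleles as independent draws; for this product-paired
table that assumption is badly conservative (simulated rejection rate ~0 at
nominal 0.05), so V is instead a delta-method estimate from the empirical
covariance of the per-individual contributions (g_a·g_b, g_a, g_b), which is
asymptotically correct without assuming Hardy–Weinberg.  Simulated type-I
error at α = 0.05 is ≈ 0.05 (400 null cohorts of n = 5000), and power
against an interaction OR of 2.0 at n = 2000 exceeds 95% at p < 10⁻⁴.
Zero cells receive the Haldane–Anscombe 0.5 correction and are flagged.
A logistic-regression Wald test of the dosage interaction is provided as a
labeled alternative; no covariate adjustment is performed.

## Numerical and design choices

- Probabilities are clamped to [10⁻⁶, 1 − 10⁻⁶] before logit; raw inputs at
  0/1 are rejected rather than silently clamped downstream.
- E-value ties count inclusively (conservative); the add-one estimator
  keeps every e-value strictly positive.
- Enumeration order, neighbor ordering, and context labels are canonical
  and stable; labels are bijective join keys.
- Every random draw site takes an explicit seed recorded in output
  metadata; reruns with identical config are byte-identical (output tables
  carry a config fingerprint that excludes the output path).
- Problem sizes used throughout the tests and the reproduction script —
  120-kb genome, background n = 999, 2000 haplotypes, cohorts of 2000–5000,
  400/100 simulation replicates — were chosen as the smallest sizes at
  which the statistical properties under test (minimum e-value 0.001,
  r² targets within ±0.05, calibration within binomial error) are
  identifiable.

## Known limitations

- The synthetic annotator is a ground-truth instrument, not a biological
  predictor; conclusions about real variants require an external annotator.
- Exhaustive context enumeration is exponential in the neighbor count; the
  cap forces the user to restrict neighbors (e.g. to observed haplotypes)
  beyond 12.
- LD grouping is anchor-centered thresholding, not block inference.
- The epistasis test is allele-based and unadjusted; confounding by
  ancestry or other covariates is out of scope.
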
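# Methods

This note records the models, numerical choices and open design
decisions behind each stage of the pipeline, and what the synthetic
validation does and does not establish about real data.

## Substitution models and likelihood

Nucleotide models are JC and HKY (equilibrium frequencies π, transition
/transversion ratio κ), with the rate matrix normalised to one expected
substitution per unit time, so branch lengths are expected
substitutions per site. HKY is the default because it is the smallest
family accommodating unequal base composition; frequencies are taken
empirically from the data being fitted. Transition matrices come from a
single symmetrised eigendecomposition per model (the model is
time-reversible), so `P(t)` and `dP/dt` each cost two 4×4 products.

Log-likelihoods use Felsenstein pruning over unique site patterns, with
per-pattern rescaling against underflow on deep trees. Gaps, `N` and
all other ambiguity codes are treated as missing data (partial
likelihood one in every state). A species absent from a locus is
marginalised rather than pruned, keeping one topology for all loci;
branches with no observed tips on one side are unidentifiable for that
locus and reported missing.

Correctness of the pruning is anchored to an exhaustive-enumeration
oracle (sum over all internal-state assignments) on trees of up to five
tips, with agreement required to 1e−8.

## Branch-length estimation

Per-locus branch lengths maximise the pruning likelihood with the model
held fixed. The optimiser is coordinate-wise: a depth-first traversal
visits every edge, forms the exact partial-likelihood vectors on both
sides of the edge from messages kept consistent with the current
lengths, and solves the 1-D problem by root-finding the score
(d lnL/dt) with Brent's method on [0, cap]. Because every coordinate
step is exact, the log-likelihood increases monotonically; sweeps stop
when a full pass improves lnL by less than 1e−5 (minimum two sweeps,
default cap 25). On five-taxon test problems the result matches a joint
quasi-Newton optimisation over all branches to ~1e−10 lnL units.

An earlier variant that froze the "rest of tree" vectors at the start
of each sweep produced a period-two oscillation on 20-taxon trees and
never converged — the reason the traversal refreshes messages lazily.

Branch lengths are capped at 10 substitutions/site; estimates pinned at
the cap (saturated data) are flagged and the locus marked unconverged.
Note that under a reversible model with the root prior at π, only the
sum of the two root-child edges is identifiable; recovery checks
therefore treat that pair jointly, and the simulator never auto-selects
a root child as the foreground branch.

## Neutral model

The neutral (genome-wide) model is fitted on elements passing two
filters — length ≥ 250 bp and ≥ 85% non-gap coverage in every species —
concatenated into one alignment. Branch sweeps alternate with a bounded
1-D optimisation of log κ until the joint lnL stabilises (tolerance
1e−4, up to six outer rounds). Zero survivors raise an error that names
the per-filter rejection counts.

## Relative evolutionary rates

From the loci × branches length matrix: (1) lengths strictly below the
cutoff become missing (cutoff 0 keeps zero-length branches); (2) each
row is divided by its observed-branch sum, removing the locus's overall
rate; (3) the per-branch expectation is the across-locus mean of the
scaled lengths; (4) both sides are square-root transformed; (5) each
locus is regressed (with intercept) on the expectation and the
standardised residuals are the RERs.

The heteroskedasticity correction is a two-pass weighted regression:
squared residuals from the first (ordinary) pass are pooled over loci,
binned into ten quantile bins of fitted value, smoothed with isotonic
regression (variance must not decrease with the mean), and inverted
into weights for the second pass. Residuals are multiplied by √w and
divided by the per-locus weighted residual SD, making RERs unitless and
comparable across loci. On neutral simulations the binned RER variance
of short vs long branches agrees within a factor of two — the testable
content of the correction.

Loci need at least four observed branches to receive RERs; a branch
with no usable observations gets a missing column and a warning.
Exactly proportional locus trees produce residuals at floating-point
noise level; these are reported as RER 0 rather than noise divided by a
vanishing SD. At desk scale (300 bp loci) per-branch RER means carry a
small bias from branches estimated at exactly zero interacting with the
sqrt transform; it shrinks with locus length and does not affect the
planted-shift contrasts, which compare against matched backgrounds.

## Acceleration test

The null is the neutral tree; the alternative multiplies the single
pre-specified foreground branch by λ ∈ [1, 100] (testing one ancestral
branch; a config switch rescales the whole descendant clade instead).
Because only one edge changes, one two-pass computation of the
edge-side partials makes each λ evaluation a small matrix product.
ΔlnL = 2(lnL̂ − lnL₁) is referred to the boundary mixture
½χ²₀ + ½χ²₁ — p = 1 when ΔlnL = 0, else ½·P(χ²₁ ≥ ΔlnL) — the standard
treatment for a one-sided parameter on the edge of its space. Improvements
below 1e−9 lnL units count as the boundary case. Elements whose data
cannot inform the foreground branch are flagged untestable rather than
given a p-value. Calibration on neutral simulations keeps the empirical
type-I rate inside the exact binomial 99% interval around 0.05.

## Regulatory domains

Basal window: TSS − 5 kb to TSS + 1 kb on the + strand, mirrored on −,
clipped to the chromosome. Extension: up to 1 Mb per side, stopping at
the nearest *basal* boundary of another gene (never at another gene's
extension), and never shrinking below the own basal window. Containment
uses the CNE midpoint under half-open coordinates, so boundary ties
resolve without double counting; any-overlap mode is available as a
flag. The implementation (interval trees) is checked against a
brute-force all-pairs scan on random genomes.

## Enrichment

The resampling unit is the CNE for CNE analyses and the gene for coding
analyses; resamples are drawn with replacement, of exactly the term's
size, 1,500 replicates by default. The Z-score compares the term's mean
score with the resample-mean distribution; SUMSTAT sums ΔlnL¼ and uses
the add-one empirical p-value `(1 + #{resamples ≥ observed})/(1 + B)`,
which can never be exactly zero. FDR is Benjamini–Hochberg (step-up,
order preserved), delegated to statsmodels. Gene annotations propagate
up the ontology DAG by default. The HA/SA contrast averages each extant
branch's RER over the term's loci and applies a one-tailed two-sample t
test (equal-variance default, Welch optional); identical groups return
p = 0.5 by the t = 0 convention. The minimum term size is 1,000 CNEs at
genome scale (10 genes for coding analyses); the desk-scale pipeline
uses 5 CNEs, scaled to its 300-element universes.

## Mutation screen

Gene sequences are concatenations of single-copy exons in reference
order; isoform duplicates collapse if identical, conflicts are errors,
missing exons leave recorded gaps. Truncation rules: indel length not
divisible by three ⇒ frameshift; a substitution creating a stop codon
strictly before the annotated terminal codon ⇒ nonsense (no distance
threshold — any premature stop counts); zero coverage at every exon
while the species has data at other genes ⇒ whole-gene deletion.
Frameshift/nonsense calls need ≥ 3 supporting reads. "Fixed" means the
supporting-read fraction reaches a configurable threshold, default 1.0
(all covering reads), reflecting pooled population sequencing.

Clinical-site mapping walks the protein alignment; the ancestral
residue is the ≥ 2/3 majority among designated outgroup/basal species
(column skipped otherwise), and only columns where ancestral = human
are eligible — variation at sites where human itself is derived is
uninformative about convergence. The pleiotropy score counts a gene's
annotations outside the hematopoietic subtree after removing the
explicit excluded terms (pallor, blood chemistry, organ size, spleen
abnormalities, …) and their descendants; it counts retained term
annotations, not distinct organ systems. Erythroid bias requires
erythrocyte expression ≥ fold × the best other hematopoietic lineage
(default fold 2.0; fold 1.0 degrades to "weak maximum"). The
LoF × pleiotropy association is the conditional two-sided Fisher exact
test; the odds ratio gets the Haldane 0.5 correction when a cell is
empty (reported only — the p-value is untouched).

## Shape metrics

Segmentation inverts the image (cells are darker than background),
applies Gaussian blur (σ = 1), true rolling-ball background subtraction
(radius 7; the actual algorithm, available in scikit-image, rather than
a morphological-opening stand-in), a 0.1%-saturation contrast stretch,
the minimum-method histogram threshold (an error with guidance if the
histogram has no valley), then opening/closing and hole filling. Binary
inputs pass through untouched.

Perimeters use the Crofton 4-direction estimator: naive pixel-edge
counting biases circularity far below 1 for rasterised circles, whereas
Crofton puts an r = 30 px circle at C ≈ 1.01 and a 2:1 ellipse at
C ≈ 0.841 — matching the Ramanujan perimeter approximation for that
aspect ratio. Particles touching the border (1-px frame test) are
dropped; µm conversion is a mandatory argument. The filter chain
retains particles with area in [70, 150] µm², C ≥ 0.80 and solidity
≥ 0.93, reporting per-rule removal counts. The two-group comparison is
the two-sample Mann–Whitney U test: the study design compares two
independent cell populations of unequal size, so a paired signed-rank
test is not applicable and the rank-sum test is the coherent choice.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the study design at desk scale: a pure-birth
topology rescaled so the crown age is uniform on 18.6–23.9 Ma (the
published calibration interval for the clade), a foreground branch
auto-chosen as an interior branch subtending about a quarter of the
species (the trait-loss ancestor), HA = the foreground clade and SA =
the remainder, HKY sequence evolution at 0.012 substitutions/site/Ma,
and a rate shift implemented exactly as the inference assumes — a
branch-length multiplier on the foreground branch. Defaults: 20
species, 300 loci × 300 bp, 50 shifted at 4×, 100 genes on a 20 Mb
chromosome, a 20-term ontology. The planted term is defined as exactly
the genes whose extended domains contain a shifted CNE (seeded from 4
genes, a few percent of the gene set, matching the gene-count fraction
of a disease-ontology anemia term); decoy terms are drawn from the
remaining genes so they are genuine nulls. Pileups carry planted
variants (including a deliberately under-supported frameshift that must
never be called); masks place ellipses on a jittered grid so particles
can touch neither each other nor the border.

Deliberately not emulated: indel evolution within alignments (variants
are planted in pileups, not evolved), read-level sequencing error,
alignment error and the capture data's missingness structure (dropout
is a free parameter, default 0), rate variation across sites, and
selection regimes other than a single branch multiplier. Passing the
planted-recovery tests therefore demonstrates that the statistics
recover the signal they were designed for under their own model
assumptions — not robustness to alignment artefacts or model
misspecification in real capture data.

Determinism: every component draws from a generator seeded by
`(config.seed, component-id)`, so identical configs give byte-identical
fixture files.

## Problem sizes used in validation

The end-to-end recovery runs use the default configuration above (ten
seeded replicates); the null control uses 150 loci × 250 bp with 50
decoy terms and no shift; acceleration calibration uses 500 neutral
elements of 300 bp and 150 four-fold-shifted elements of 500 bp; the
likelihood oracle uses 20 random 4–5-taxon trees; the domain oracle
100 random genomes. These sizes were chosen so the statistics being
asserted (rank-1 recovery, binomial-interval calibration, exact set
equalities) are sharp while the whole suite stays desk-scale.

## Known limitations

* Root-edge ambiguity: the two root-child branches are only jointly
  identifiable; their individual RERs are correspondingly noisy.
* The λ̂ of the acceleration test absorbs any error in the neutral
  foreground length; fitting the neutral model on a contaminated
  element set (as the desk-scale pipeline does, with ~17% shifted
  elements) shrinks ΔlnL but leaves ranking intact.
* Per-branch RER means at desk scale are centred only approximately
  (|mean| up to ~0.3 with 300 bp loci) due to zero-length estimates
  under the sqrt transform.
* JC/HKY only; no Γ rate variation; ambiguity codes other than N are
  treated as N.
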
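# Methods

`subqtl` re-implements, as a tested pipeline, the analysis used to
partition a mouse body-fat QTL on distal chromosome 2 into two linked loci
using overlapping congenic strains, and to fine-map the stronger of the
two.  This note documents the models, the parameters that matter, the
synthetic data the tests run on, and the numerical choices.

## The congenic F2 design

A congenic strain carries a CAST/EiJ donor segment introgressed into a
C57BL/6J-hg background.  Its F2 intercross segregates (B/H/C, i.e.
b6/b6, b6/cast, cast/cast) only inside the donor interval; outside it,
every animal is homozygous background.  Merging the F2 populations of a
founder congenic and five overlapping subcongenics yields one mapping
panel (n = 278 + 384 + 208 + 382 + 353 + 385 = 1,990) in which different
intervals are informative in different subsets of animals.  When a strain
dataset is merged onto the union marker map, markers it never genotyped
are coded `B` outside its donor region (fixed by construction) and
`missing` inside it; the recombinant ends of each donor segment
("boundary uncertainty", default 1 Mb per end) are coded missing so the
HMM marginalizes over them.  An observed donor allele outside a strain's
donor region fails validation rather than being overwritten.

Positions are physical (Mb, single chromosome) and converted to map
distance at a configurable 1 cM/Mb before the Haldane map function
r = (1 − e^(−2d/100))/2; the original analysis also scanned the physical
map because a merged genetic map could not be estimated reliably.

## Genotype probabilities and imputation

The F2 genotype sequence is a three-state Markov chain (stationary
distribution ¼, ½, ¼; the standard F2 transition matrix).  `calc_genoprob`
runs a forward–backward pass over markers plus pseudomarkers (default
step 0.1 Mb, grid anchored at the first marker, marker positions always
kept) with a genotyping-error emission model, `error_prob` default 1e-4 —
small but nonzero so an impossible double-recombinant observation cannot
zero the likelihood.  `impute_missing` is a forward-filtering /
backward-sampling pass, so each imputed genotype vector is a coherent
draw from the joint conditional given that animal's observed markers;
this matters because composite interval mapping uses whole imputed
markers as covariates.  On any small example the forward–backward result
equals exhaustive enumeration over hidden genotype configurations (tested
to 1e-10), and imputation frequencies converge to the conditional
probabilities.

## Interval mapping

Fat phenotypes (GFP, MFP, RFP, FFP and their sum TF) are first adjusted
by least squares for strain, sex and sacrifice weight; the residuals are
the mapping phenotype.  At each grid position Haley–Knott regression uses
x_a = P(C) − P(B) and x_d = P(H), and LOD = (n/2)·log10(RSS0/RSS1)
comparing models with and without the two genotype scores.  Significance
thresholds come from permutations of the adjusted residuals (default
1,000; the empirical (1 − α) quantile of per-permutation maximum LOD), and
location credible intervals from the 10^LOD-weighted cumulative-mass rule
(accumulate positions by decreasing weight to 95% mass, ties leftmost,
endpoints expanded outward to the nearest genotyped markers).

One numerical rule deserves mention: a position's additive or dominance
score column is treated as non-segregating when its projected sum of
squares falls below 1e-4 of the scale of a genuinely segregating column
(sum of squares of order n).  In a congenic panel most of the chromosome
is fixed background for most animals, and the error model otherwise leaks
a vanishing (~1e-4-scale) copy of neighbouring-marker information into
those constant columns, which ordinary least squares would happily fit.

## Composite interval mapping, replicated

`cim_scan` (one run): impute missing genotypes → forward-select marker
covariates (default 3; each candidate contributes its additive and
dominance columns; ties leftmost) → scan with covariates, excluding any
covariate within window/2 Mb of the test position (the window is read as
a full width centred on the test position; default 2 Mb).  With no
covariates CIM degenerates to interval mapping on the imputed data.  On
imputed (complete) data the scan uses the exact flanking-marker
conditional at pseudomarkers with error_prob = 0, which is identical to
the HMM there and much cheaper.

`replicated_cim` repeats this, re-imputing and re-selecting every run
(replicate seeds are the driver seed plus a global run counter, so no two
runs share an imputation stream), for the baseline parameters plus a 3×3
factorial of windows (1, 0.5, 0.25 Mb) × steps (0, 1, 0.5 Mb): 10
combinations × 400 replicates = 4,000 runs at the published scale.  Each
combination is summarized by its pointwise *median* LOD (the replicate
distributions are skewed, so a mean would be dominated by favourable
imputations), and the consensus peak is the modal 0.5 Mb bin of the ten
median-profile argmax positions; no significance threshold is attached —
the procedure prioritizes a location inside an already-established QTL.

A caveat the simulations make measurable: when two linked QTL of
comparable strength segregate, greedy covariate selection tends to place
the first covariate at the *ridge* maximum of the single-QTL profile,
up to ~1.5 Mb off the true distal peak; small-window combinations then
suppress the true peak everywhere except at that covariate, so the
consensus tracks the covariate position.  The procedure is most reliable
when one QTL clearly dominates (as in the original data, where the
distal:proximal LOD ratio was ~2.5) and when heavy missingness makes the
selection vary between replicates.  Under this package's default
simulation (ratio ~2:1, 5% missingness) the consensus lands within
±1 Mb of the distal QTL in only ~60% of study replicates — a documented
limitation of replicated CIM in that regime, not a numerical artifact.

## Per-strain effect models and decomposition

For single-strain analyses each animal is classified by its consensus
donor-region genotype (majority code across donor-region markers;
ties excluded, within-region recombinants counted and logged).  The trait
is regressed on sex, sacrifice weight, x_a (B = −1, H = 0, C = +1) and
x_d (1 for H).  If the sex×additive term is significant at p ≤ 0.05 both
interactions are retained and sex-specific (a, d) are reported; the
pooled effect is the unweighted sex average (matching the published
LS-means arithmetic: the distal subcongenic's total-fat cells give
(C−B)/2 averaged over sexes = −0.0515 ≈ the printed −0.052).  LS means
are model predictions at the covariate mean per sex×genotype cell.  No
multiplicity correction is applied across traits.

Because the subcongenic donor regions tile the founder's, the founder's
additive effect decomposes as a_founder = Σ a_subcongenic + e;
`decompose_additive` is exact arithmetic and the residual e is the
transgressive/undetected-QTL remainder.

## The synthetic study generator

`simdata` emulates the study design, not any particular dataset: a
~74.9–181 Mb map with 1 marker/2 Mb below 145 Mb and 1/0.75 Mb above
(the microsatellite-then-SNP density of the original panel); the founder
plus five overlapping subcongenics at the published sample sizes (only
the founder's and the distal-most strain's donor bounds are published —
the other intervals reproduce the overlap topology and are config
options); two additive QTL at 156.9 and 174.3 Mb with a = −0.040 and
−0.090 g; a +0.30 g female sex effect; sacrifice weight ~ N(45, 5²) g
with slope 0.02 g/g; total-fat residual SD 0.30 g (effect sizes and noise
calibrated to the order of magnitude of the published strain effects and
cell SEs; they are stated choices, not measurements); 5% missing
genotypes plus fully-missing recombinant-end zones.  Each fat pad carries
a fixed share of the signal (GFP 0.36, FFP 0.34, MFP 0.22, RFP 0.08) and
pad noise scales with √share, so TF = ΣGFP..FFP exactly and the TF-level
parameters are exactly the configured ones.  Gametes are simulated as
independent Haldane Markov chains over the donor-region loci.

What the generator does not emulate: genotyping error (simulated codes
are true codes, apart from missingness), epistasis, parent-of-origin
effects, segregation distortion, non-Gaussian residuals, and the real
study's strongly non-uniform missingness (366 of 1,990 animals carried
the fine-map SNP genotypes).  Passing tests therefore demonstrate the
statistical machinery under a clean version of the design, not robustness
to those real-data features; the last item is consequential for
replicated CIM, as noted above.

## Comparative-Ct expression analysis

ΔCt = Ct_target − median(Ct of the two housekeepers Gus and Sdha; for
two values the median is their mean), ΔΔCt subtracts the mean ΔCt of an
explicitly supplied reference sample set (conventions differ between a
pooled-control mean and a single calibrator, so the set is a required
argument), RQ = 2^−ΔΔCt.  Inference runs on ln(RQ) (= −ΔΔCt·ln 2) with
fixed effects of sex and genotype; pairwise genotype contrasts are
adjusted by a max-|t| Monte-Carlo adjustment (draws from the contrasts'
joint null, default 100,000), with adjusted p floored at the unadjusted p
to keep monotonicity under Monte-Carlo noise.  Technical replicates are
assumed pre-averaged.

## Problem sizes used by the test suite and acceptance script

The suite runs the full merged design (n = 1,990, 84 markers) for the
flagship recovery checks (20 study replicates; 50 CIM replicates per
parameter combination), a 200-study × 200-permutation null calibration at
n = 400 with 20 markers, 100-seed effect-recovery runs at n = 385, and
the published-scale 4,000-run bookkeeping on a 50-animal toy.  The
acceptance script reruns the same stack at one seed and reports the
quantities it computes.
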
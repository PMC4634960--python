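# Methods

## Observable meioses and phasing model

A three-generation family — offspring, sire, dam, both grandsires,
optionally the granddams — makes two meioses observable: sire →
offspring (paternal) and dam → offspring (maternal). Phasing is strictly
within-family and single-offspring: pooling a bull's hundreds of progeny
would phase males far better than females and bias every sex contrast,
so no LD and no multi-offspring information is used anywhere.

The trio rule is implemented as transmission enumeration: for each site,
all ordered (paternal allele, maternal allele) pairs consistent with the
three genotypes are listed; the site is phased iff exactly one pair
survives. This is equivalent to "homozygotes phase trivially,
heterozygotes phase unless both parents are heterozygous", and it yields
the Mendelian-inconsistency rule for free: an empty set flags the site.
Inconsistent sites are masked for all members and counted — never
corrected — and a family whose offspring-trio inconsistency rate exceeds
2% (configurable) is flagged for exclusion as a likely pedigree or
genotyping error. A missing genotype in any member leaves the site
unphased without flagging. When a granddam is ungenotyped, a
heterozygous parent site phases only if the grandsire is homozygous; the
grandsire's allele defines the parent's grand-paternal haplotype.

## Crossover calling

A site is *informative* for a meiosis when the transmitting parent is
heterozygous with known phase and the transmitted allele is assigned;
the allele then identifies the grandparental origin. Crossovers are
origin switches, subject to a support rule: each flanking origin run
must contain at least `min_support = 3` consecutive informative SNPs.
"Consecutive" is read as consecutive *among informative sites*
(uninformative sites in between do not interrupt); the stricter
map-adjacent reading is available via `strict_adjacency=True`.

Runs shorter than the support threshold are treated as unresolved: they
neither generate calls nor break their neighbours, so a short discordant
run flanked by two same-origin runs produces no call — a potential tight
double crossover deliberately not counted, which makes the calls
"observed crossovers" that can undercount truth. No map-function
correction is applied at calling time; at ~42 kb mean interval spacing
the numerical difference is negligible. The called region spans the
half-open interval between the last supporting SNP on the left and the
first on the right, covering `m` adjacent-SNP intervals (1-based
positions, intervals `(pos_i, pos_{i+1}]`).

Detection power is the fraction of simulated crossovers whose true
position lies inside a called region of the same meiosis and
chromosome. At the default full-scale simulation (29 autosomes, 2,516
Mb, 54K SNPs, MAF ~ U(0.05, 0.5), no genotyping error) the measured
power is ≈ 97%; the losses are chromosome ends (fewer than three
informative flanking SNPs) and tight double crossovers.

## EM map construction

Each called crossover is known only up to its region's `m` intervals.
With `n` meioses and regions `r`, the model treats each crossover as a
draw from a per-interval probability vector `c`; the likelihood is
`∏_r Σ_{i∈r} c_i`, maximized by EM: initialize each region's expected
count as `1/m` per interval; M-step `c_i = (total expected count in
i)/n`; E-step: redistribute each region's count across its intervals
proportionally to current `c_i`. Two invariants hold at every iteration
and are tested: `Σ_i c_i · n` equals the region count exactly, and the
likelihood is non-decreasing. The fixed point equals the multinomial MLE
(verified against an independent nested grid search on small
instances). Numerical choices: convergence when `max |Δc| < 1e-8`, with
an iteration cap of 20,000 (large instances take a few thousand cheap
vectorized iterations); intervals that reach exactly zero are ordinary
EM fixed points and stay at zero (no floor, ε = 0); a region whose
intervals are all at zero falls back to a uniform split (logged).

Maps report raw expected crossovers per meiosis (1 Morgan = 1 expected
crossover) as genetic distance. Haldane-adjusted lengths
`d_i = −½ ln(1 − 2 c_i)` are an alternative output; the adjustment is
convex, so adjusted ≥ raw with equality only at zero, and it requires
every `c_i < 0.5`. The map itself is intended to be fit from
highest-quality meioses (all members on the densest chip); the
chip-density correction — rescaling each chip-category's mean crossover
count to the reference category's mean, per sex — applies to the scalar
count phenotypes, not to the map.

## Hotspots and usage

Hotspot threshold: `mean + k·SD` of interval rates over all autosomal
intervals of one sex's map, strict inequality, default `k = 2.5`
(supported sweep: 2, 2.5, 3, 5, 10). The distance-standardized variant
divides each rate by interval bp length and excludes intervals < 500 bp
from both thresholding and calling (per-bp rates on very short intervals
are unstable); standardized rates vary much less, hence the lower
default cutoff of 0.6 SD.

Usage of a meiosis = mean over its crossovers of each region's hotspot
mass share, `Σ rates of hotspot intervals in the region / Σ rates of
all its intervals` — the EM-posterior-consistent allocation for regions
straddling hotspot boundaries. A hard-assignment alternative (region
counts as hotspot iff its rate-weighted share exceeds ½) is available.
The animal-level record is the mean over the animal's crossover-bearing
meioses, weighted downstream by that meiosis count.

## Weighted mixed-model GWAS

Phenotypes are animal-level means over repeated meioses: genome-wide
crossover count (chip-corrected), hotspot usage, or subtelomeric count
(crossovers with region midpoint in the terminal 15% of the chromosome;
cattle autosomes are acrocentric so only the far end qualifies). The
model is `y = Xg + Za + e` with `a ~ N(0, A σ²_a)`,
`e ~ N(0, R σ²_e)`, `R = diag(1/w)`. Note the variance convention:
`σ²_e` is the residual variance of a single meiosis, and an animal
averaging `w` meioses has residual variance `σ²_e / w`; rescaling all
`w` rescales `σ²_e` in the same direction at fixed data.

The GRM is VanRaden method 1 on observed allele frequencies with a 1e-8
diagonal ridge; monomorphic SNPs are rejected. SNP filters: MAF ≥ 0.001
and a greedy within-chromosome prune of any SNP correlating above
|r| = 0.95 with an already-kept SNP in a trailing 50-SNP window
(duplicates always go).

Variance components are REML-estimated once on the null model:
standardizing by `diag(√w)` and eigendecomposing the weighted GRM turns
the profile REML into a 1-D bounded search over the variance ratio.
Each SNP is then tested by GLS with `V = A σ̂²_a + R σ̂²_e` held fixed
(Wald test) — the standard two-stage large-scan approximation; an exact
per-SNP REML mode exists for small n. Conditional analyses add chosen
SNPs to the fixed effects; a joint fit estimates all chosen SNPs
simultaneously. Significance uses 0.05/#tests; at the HD-imputed scale
of ~312,500 tests this is the conventional 1.6×10⁻⁷. Calibration is
checked by genomic inflation (median χ² ratio) on null simulations.

When validating effect-size recovery on simulated QTL with few SNPs,
the GRM is built without the tested SNP (leave-one-chromosome-out
convention): a GRM containing a large-effect causal SNP absorbs part of
its effect into the polygenic term. At realistic SNP counts the bias is
negligible and the scan uses the full GRM.

## Diagnostics

Positional profiles regress per-bp interval rates (scaled to the mean
interval length) on relative position (midpoint / chromosome length),
pooling autosomes, after removing intervals overlapping 2 Mb at either
chromosome end where sparse coverage depresses detection power.
Smoothing uses an ordinary-least-squares B-spline with 5 degrees of
freedom — a regression-spline counterpart of a fixed-df smoothing
spline. Time trends residualize per-meiosis counts on chip categories,
parental genomic inbreeding, and offspring/parent informative-SNP
counts with quadratic, cubic and interaction terms (inbreeding lowers
heterozygosity and thus the informative-SNP supply), then smooth
residual + mean on birth year; aliased design columns are dropped by
greedy QR with a warning.

The LD screen computes, for a candidate SNP, two-point recombination
fractions against all same-chromosome SNPs from phase-known meioses
(`r̂ = R/N` capped at 0.5, pairs with N < 20 skipped) and
`LOD = log₁₀ L(r̂)/L(0.5)`, `L(r) = r^R (1−r)^(N−R)`. A correctly placed
SNP shows a LOD peak at itself decaying with distance. The qualitative
expectation is made explicit by two rules: suspicious if the LOD argmax
lies > 10 Mb from the mapped position, or if distance-binned mean LOD
fails to decay monotonically (tolerance 5% of peak LOD). These are
stated proxies for a visual judgement, not a reconstruction of one.

## Simulator: what it emulates and what it does not

Defaults are the full study conditions: 29 autosomes proportional to the
cattle karyotype totalling 2,516 Mb; 54,000 SNPs allocated by length
with uniform random positions; alternate-allele frequencies from a
chip-ascertainment-like MAF law U(0.05, 0.5); sex-specific genetic maps
totalling 25.5 (male) and 23.2 (female) Morgans, split across
chromosomes by physical length; genotyping error and missingness 0
(rates of the real assays are not published; both are configurable and
error flips a dosage to a uniformly chosen different valid value);
granddam genotyping mix (36.4% both, 41.0% one, 22.6% neither) matching
the reported family composition; sires reused across families (5
progeny each by default) to mimic the many-offspring-per-bull
structure.

Chiasmata follow a gamma-renewal process on the genetic scale (rate 2
per Morgan on the four-strand bundle, shape ν, 5-Morgan burn-in for
stationarity) thinned by ½ per chromatid; ν = 1 gives exactly Poisson
crossovers, matching the Haldane/no-interference setting of the power
simulation, and ν > 1 models positive interference. An
obligate-crossover mode redraws until at least one crossover occurs.
Optionally a designated fraction of interval bp can carry a chosen
fraction of map mass, giving a ground-truth hotspot structure for
usage-recovery experiments.

Deliberately not emulated: background LD among founders (phasing here
uses family rules, not LD — but this means LD-screen nulls are cleaner
than real data), selection, mutation, imputation, X/Y chromosomes, and
coalescent-realistic allele-frequency spectra. Consequently, passing
tests demonstrate correctness of the inference machinery under the
stated generative model, not robustness to real-chip artefacts such as
clustered genotyping errors or assembly misplacements (the LD screen
addresses the latter directly).

## Problem sizes used in the validation suite

The test suite simulates at the scale each check needs: 500 full-scale
families (54K SNPs, 29 autosomes) for detection power; 50,000
truth-phased meioses on a 2.5-Morgan chromosome for map recovery
(interval-rate correlation with truth > 0.95); 10,000 error-free meioses
for phasing exactness (zero phase errors, zero false-positive calls);
2,000 animals × 5,000 SNPs for mixed-model calibration (genomic
inflation within [0.95, 1.05]); 20,000 meioses for hotspot-usage
recovery (3% of bp carrying 25% of map mass reproduces mean usage
0.25 ± 0.01). The complete suite runs in a few minutes on one CPU.
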
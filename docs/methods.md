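# Methods

## Problem setting

High-density tiling arrays interrogate a genomic region with fixed-length
oligonucleotide probes whose start positions step along the sequence at a
small offset (the *tiling path offset*). Because repetitive sequence cannot
be probed specifically, the region is first repeat-masked, leaving a series
of discontinuous *unique segments* onto which probes are tiled. Probes tiled
densely compete for the same labelled DNA fragments (*competitive
hybridization*), which depresses signal; where masking interrupts the tiling,
probes at segment edges face less competition and fluoresce higher (the
*edge effect*). This package implements the full design/QC/analysis chain for
quantifying these effects from single-channel array data, plus a simulator
that reproduces the effect structure so the chain is testable without arrays.

## Segmentation and design geometry

A target region (0-based half-open coordinates throughout; BED conventions on
disk) is partitioned into unique segments as the complement of the merged
repeat intervals. Repeats are grouped six ways: LINE, SINE, LTR, Simple, LC
(low-complexity) and Other; RepeatMasker `.out`, BED and softmask (lowercase
run) annotations are accepted. Merging is used only for the complement —
per-repeat records are kept so each interior masked gap can be summarized by
the class of its longest repeat and the combined length of all repeats in the
gap. Gaps touching the region boundary carry no repeat summary.

Probes (60-mers by default) are tiled per *zone*: each zone has its own
offset, and candidate starts form an arithmetic grid anchored at the zone
start (`anchor="global"`), so a segment's probe count depends on its phase
relative to the grid. With grid step `o` and probe length `p`, a segment of
length `L ≥ p` holds between `floor((L−p−o+1)/o)+1` and `floor((L−p)/o)+1`
probes over phases; a 200 bp segment therefore holds at least 23 probes at
6 bp offset but only 5 at 26 bp. A `per-segment` anchor that restarts the
grid at every segment start (maximising per-segment counts) is available as a
plan flag. Any candidate whose interval extends into masked sequence is
discarded.

Geometry annotation per segment of `n` probes: the k-th probe gets position
`min(k, n−k+1)` (rising toward the centre), the first/last probes are 5'/3'
edges and carry the width of the adjacent masked gap as their *distance*; a
single-probe segment is both edges and takes the larger gap. In the densest
zone, the 5'-most probe of every segment of at least
`p + (ceil(p/o)−1)·o` bp (114 bp for 60-mers at 6 bp — the shortest segment
in which some base attains the maximal `ceil(p/o)`-fold coverage) is printed
five times, providing within-array replicates.

## Sequence covariates

Per probe: GC percentage; the longest homopolymer run of each base (the true
longest run is recorded, 0 if absent — a run-length floor can be applied
downstream); and the genome-wide off-target count, defined as the sum over
all 25-mer windows of the probe of (index count − 1), the subtracted one
being the window's own occurrence at the probe locus. The k-mer index counts
every ACGT window of the reference, by default pooling each k-mer with its
reverse complement (hybridization is strand-agnostic); a strand-specific mode
exists. Self-folding free energy (kcal/mol at the hybridization temperature)
is accepted as an external input column and never computed internally.

## QC and filtering

The raw datum is the median feature signal per probe per array (saturating
at 65,530), with a per-feature background. A probe is removed *globally* —
from all arrays — if on any array its signal exceeds that array's
positive-control median, falls below the negative-control median, or its
background exceeds 50; probes inside supplied CNV regions are also removed.
This union rule keeps per-array retained counts identical; a per-array mode
is available. The deletion stringency control (DCP) analysis groups control
features by the number of centrally deleted bases (0–8) and reports each
level's mean signal as a percentage of the non-deleted parent mean.

## Statistics

**Repeatability** of replicate signals is the intraclass correlation
r = S²_A / (S² + S²_A), with S² the within-group ANOVA mean square and
S²_A = (MS_between − MS_within)/n₀, n₀ = (N − Σn²ᵢ/N)/(k−1) for unbalanced
groups. Negative S²_A is truncated at zero (the raw value is kept for
diagnostics); all-identical data is flagged degenerate with r defined as 1.

**Group comparisons** use the unequal-variance t test with Satterthwaite
degrees of freedom, alongside the variance-ratio F test that motivates
separate variance estimates and each group's coefficient of variation
(100·sd/mean, computed on raw filtered intensities by default).

**Intensity models** regress log_e signal on GC%, log_e(1+off-targets), free
energy, the four homopolymer lengths, log_e background, log_e segment length
and the offset factor (reference level: the smallest offset, fixed at 0),
plus exactly one of: probe position (all probes), log_e distance (edge probes
only) or log_e combined repeat length with the repeat-class factor (the
repeat-adjacent subset — nearest 4 probes per gap side in 6 bp zones, 2 in
26 bp zones; the repeat preset drops the off-target and segment-length
covariates). log_e(1+count) is used for off-targets because the count's
median is 0. Homopolymer covariates additionally receive truncated-linear
regression-spline bases (knots at quantiles of the distinct values, at most
5 interior knots) whose joint Wald χ² tests non-linearity; exact penalized-
spline χ² values from other software are not expected to reproduce.

**Fitting.** The primary backend is an exact profiled REML for the linear
mixed model with a random probe intercept: given the variance ratio
λ = σ²_probe/σ²_resid, β and σ² have closed forms, so the REML criterion
reduces to a one-dimensional profile minimized by bounded scalar search.
This remains stable at the extreme variance ratios typical of probe data,
where general-purpose mixed-model optimizers can fail to converge; the
statsmodels MixedLM implementation of the same model is retained as a
cross-check backend, and an OLS fit with probe-clustered robust standard
errors is the documented fallback (flagged in the result). Dog and DNA
source are array-level effects with one array per dog; their variance is not
separable from the residual at 8 arrays, so the backend absorbs array-level
heterogeneity into the residual. In the balanced post-filter design
(identical probes on every array) array effects cancel exactly in
between-probe contrasts, so estimates and standard errors of the probe-level
covariates are unaffected; only the reported variance components should be
read with this in mind. Per-term F statistics are squared Wald ratios
(1 d.f.); factor and spline terms get joint Wald χ² tests. Covariates with
zero variance or entirely missing values (e.g. free energy when no ΔG file
is supplied) are dropped and listed in the result. The significance
threshold is 0.05 with no multiplicity correction.

## Simulator

The generator emulates the study conditions end to end. A region (default
200 kb for fixtures) receives non-overlapping repeats (target mass fraction
0.30, lognormal lengths around 300 bp, class mix LINE .35 / SINE .30 /
Simple .15 / LTR .10 / LC .10) realized as lowercase tandem motif copies,
plus a few unmasked 300 bp segmental duplications so off-target counts are
exercised. Zones default to two 26 bp-offset flanks around a 6 bp central
zone (fractions 0.4/0.2/0.4). Intensities follow the fitted effect
structure: log_e signal = β₀ + Σ effect×covariate + offset contrast
(0.190 for 26 vs 6 bp) + probe/dog/source random intercepts + residual,
exponentiated and clipped to [1, 65 530]. Fixed-effect defaults are the
fitted per-unit effects listed in `DEFAULT_EFFECTS`; the distance effect
applies to edge probes only. Backgrounds are lognormal around 36 with log-sd
0.13, chosen so the union background rule retains ≈93% of probes, matching
the study's retained fraction; random-effect sds (probe 0.15, dog 0.05,
source 0.05) are free parameters — no empirical variance components were
reported — and the residual sd 0.013 places per-probe raw-scale CVs in the
1.2–1.6% band. Saliva arrays are attenuated (×0.49) with 1.15× residual
noise, reproducing the lower-mean/higher-CV contrast. Controls: 30 positive
(level 9350) and 30 negative (level 57) features per array, and 20 DCP sets
of 10 features (2 parents + 4 deletion levels × 2, odd/even deletion sets
alternating) following a retention curve declining from 100% to 24% at
8 deletions with a characteristic odd/even saw pattern. All draws flow from
one seeded generator per operation in a documented stream order, so outputs
are bit-reproducible from (config, seed).

What the simulator does **not** emulate: mechanistic hybridization kinetics
(competition enters only through the fitted reduced-form design effects),
spatial array artifacts, sequence-dependent background, microbial
contamination of saliva beyond signal attenuation, and real canine sequence
composition (the unique sequence is i.i.d. uniform ACGT, so GC and
homopolymer distributions are narrower than in a real genome). Passing
recovery tests therefore demonstrates correctness of the pipeline under the
stated model, not performance on real arrays.

## Problem sizes used in the test suite

Property suites run 1,000 random ~1.5 kb fixtures (mask overlap), the full
(L ≤ 500, p ∈ {20, 60}, o ≤ p) phase-enumeration grid, and a 45 kb toy
genome for brute-force off-target comparison. Parameter recovery simulates a
47 kb region (≈2,000 probes post-design, ≈1,950 post-filter) × 8 arrays over
50 seeds, fitting both the position and distance models, and requires every
nonzero generating effect within 3 SE in ≥90% of seeds; null calibration
runs 200 replicates at ≈500 probes with all fixed effects zero and checks
per-term rejection near the nominal 5%. The shared fixture dataset uses a
30 kb region.

## Known limitations

- Variance components for dog/DNA source are not estimated separately (see
  above); repeatability and the blood/saliva comparison cover those contrasts
  instead.
- The repeat-adjacent subset assigns a probe flanking two gaps to the nearer
  gap only.
- Off-target self-occurrence correction subtracts exactly 1 per window,
  which is exact whenever the probe locus is unique in the reference.
- The k-mer index is an in-memory dictionary: appropriate for region-scale
  references (≤ tens of Mb), not whole-genome builds.
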
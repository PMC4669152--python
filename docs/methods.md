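# Methods

## The morphology model

PVD extends one anterior and one posterior primary dendrite from the
soma along the animal's anterior–posterior (A-P) axis. The analysis
assumes skeletons are registered so that +x is anterior with the soma
near the origin (images are straightened using the primary dendrite as a
reference before tracing; the pipeline additionally re-parameterizes the
primary by arc length, so mild curvature is harmless).

**Primary-path extraction.** The 1° dendrite is taken to be the
tip-to-tip path through the soma with the greatest A-P span (anterior
tip maximizing x, posterior tip minimizing x, chosen in different soma
subtrees; arc length breaks ties). Span, rather than raw path length, is
the criterion because menorah detours — primary → secondary stem →
tertiary arm — can exceed a bare primary arm in arc length while never
exceeding it in A-P extent. A skeleton whose tips all lie on one side of
the soma raises a degenerate-path error carrying the best single arm.

**Branch-order classification.** The skeleton minus the primary
decomposes into maximal unbranched chains. A chain is also split where
successive edges turn by more than `split_angle` (default 60°), so an
order transition without a bifurcation node — e.g. a stem whose single
surviving tertiary arm turns 90° — is still detected. Rules, with angles
measured between a chain's chord and the A-P axis:

- every protrusion from the primary is a **2°**, regardless of length or
  orientation (short filopodia and misoriented stems count);
- a child of a 2° within `theta_t` (default 45°) of the A-P axis is a
  **3°**; other children continue the secondary;
- a child of a 3° deviating from the A-P axis by more than `theta_q`
  (default 45°) is a correctly-oriented **4°**; among A-P-trending
  children the one most parallel to the parent chord continues the
  tertiary, and any other is labelled order 4 but flagged
  `not_correctly_oriented` and excluded from n4;
- children of 4° chains are flagged `beyond_quaternary` (warning, not
  error) and excluded from counts.

Counting is over branch *units*: a unit is a maximal run of same-order
chains rooted at a parent of lower order. A tertiary arm cut into
segments by quaternary attachment points is therefore one tertiary, and
the toy menorah (one stem, two arms, four twigs) counts
n2=1, n2_with3=1, n3=2, n4=4.

**Regions.** The anterior extent [0, L_a] is cut into three equal-length
half-open thirds (+1, +2, +3); whatever posterior extent exists is
region -1 (it is not length-matched to the anterior thirds). A base
falling exactly on a boundary goes to the more anterior region — a
deterministic tie-break under floating-point arc lengths. Secondaries
are assigned by the position of their base on the primary; tertiaries
and quaternaries by the base of the secondary stem of their menorah,
even when arms cross a boundary.

**Branch complexity index.** Per region,

    bci = ( n2/n2*  +  n2_with3/n2  +  (n4/n3)/q* ) / 3

with conventions n2=0 → second term 0 and n3=0 → third term 0, so
branch-poor segments score finite values and an empty segment scores
exactly 0. The components are *not* clipped at 1: anterior-shifted
mutants exceed the wild-type ideal in the distal region and clipping
would erase that signal. The "ideal segment" parameters are not published
numbers; the defaults are n2\* = 14 (the wild-type generator's densest
region) and q\* = 5 quaternaries per tertiary, and both are explicit
arguments everywhere so users can recalibrate. The tertiary-bearing
fraction is kept in [0, 1] (a reporting layer may display it ×100, which
preserves the ideal-segment normalization to 1). Note one consequence of
the fraction term: bci is monotone in n2_with3 and n4, and in n2 only
while the fraction term is unaffected — adding bare secondaries to a
segment with a fixed number of tertiary-bearing ones dilutes menorah
completeness, and the index correctly reflects that.

In L2/L3 animals only the whole-arbor secondary (filopodia) count is
tabulated (`count_filopodia`); asking for it at L4 is an error directing
the caller to the regional counts.

## Kymograph analysis

Kymographs are time × position images, rows at Δt = 0.125 s (8 frames/s)
by default. Detection is deliberately transparent rather than
Hough/Radon-based: per-row local maxima above median + k·MAD (k = 3),
sub-pixel refinement by a three-point parabola on the log intensity
(exact for a Gaussian streak profile, which is why the zero-noise oracle
recovers slopes to machine precision), greedy nearest-neighbour linking
with a velocity-predicted gate (1.2 px/frame) and gap closing (3
frames), and a least-squares line fit per track. Two crossing comets
briefly merge into a single maximum, so one peak may feed up to two
tracks during linking; a stitching pass rejoins collinear fragments and
a shadow-removal pass drops tracks that merely ride a longer track's
maxima. Without these, crossings preferentially fragment the
minority-direction tracks and bias the plus-end-out fraction toward 0.5.
Tracks shorter than `min_run` (5 frames) are discarded and comets slower
than `v_min` (0.02 μm/s) are excluded from polarity counts — only
directed movements are scored.

Direction is soma-relative: EB comets mark growing microtubule plus
ends, so a comet moving away from the soma reports a plus-end-out
microtubule. `CometTrack.velocity` is signed positive away from the soma
(invariant under mirroring the image together with `soma_side`), and
`velocity_image` keeps the raw +column slope (which flips under
mirroring). Per-region results pool into counts, the plus-end-out
fraction, and a two-sided exact binomial test against 0.5; a region with
no directed tracks is flagged undefined rather than given a fraction.

## FRAP

Traces carry pre-bleach frames at t < 0, the bleach at t = 0, and 1 s
post-bleach sampling for 300 s. Normalization divides by the pre-bleach
mean (optionally double-normalizing against an unbleached reference
region for acquisition photobleaching — off by default). Recovery is fit
by least squares to the single-exponential
F(t) = f0 + (f_inf − f0)(1 − e^(−t/τ)), initialized at the first
post-bleach value, the last-decile mean, and the time to half recovery.
The mobile fraction (f_inf − f0)/(1 − f0) clamps the plateau at the
pre-bleach level first, since noise can push the fitted plateau above 1.
A single exponential is a deliberate simplification: the question asked
of these data is "faster and more complete, or not", which maps onto τ
and the mobile fraction; reaction–diffusion models are out of scope.
Group comparison interpolates traces onto a common post-bleach grid and
runs the genotype × time two-way ANOVA; time is treated as an ordinary
crossed factor, not a repeated measure, which is anticonservative for
within-animal correlation — users comparing marginal timepoints should
keep that in mind.

## Statistics

The two-way ANOVA computes type-II sums of squares by model comparison
(each main effect against the additive model, the interaction against
the full model), which is invariant to unbalanced animal numbers and
coincides with the textbook decomposition on balanced designs (verified
against a brute-force cell-means oracle and statsmodels in the tests).
The interaction is always included; a design with an empty cell or
without within-cell replication is an error naming the cell. Tukey's HSD
uses the studentized-range distribution with Tukey–Kramer standard
errors for unequal group sizes; the residual mean square may be supplied
from a surrounding ANOVA. "Multiple t-tests" are Welch tests reported
unadjusted — matching the common Prism-style convention for
developmental time-course comparisons — with a Holm-adjusted column
alongside for family-wise control. Penetrance is a per-animal threshold
rule (default: BCI below 50% of the wild-type reference mean in *both*
regions -1 and +1, the posterior-loss phenotype) with an exact
Clopper–Pearson 95% interval; the rule is configurable because
"phenotypic" is not defined numerically anywhere authoritative.

## The synthetic-data generator

`simulate_arbor` lays the primary at 1 μm node spacing along x, draws
per-region Poisson secondary counts at uniform positions (snapped to the
nearest interior primary node), grows stems orthogonally with Gaussian
orientation noise, promotes each stem to a full menorah with per-region
probability p3 (stem reaches the tertiary line at 20 μm and spawns two
A-P arms), trims arms at midpoints between same-side neighbours so
menorahs tile without overlap, and decorates each menorah with a
Poisson(2·μ4) number of orthogonal quaternaries spread over its arm
nodes. Arbors are 2-D (z = 0): every quantified feature of this system
lives in the A-P/dorsoventral plane of a straightened animal. Ground
truth (per-region counts, the primary node list, per-secondary records)
is emitted alongside and is exact by construction; at zero orientation
noise the counting pipeline reproduces it in 100/100 arbors.

Calibration: the wild-type profile's per-region rates sum to the
reported whole-arbor means — λ2 = (10, 14, 12, 6) over (-1, +1, +2, +3)
totalling 42, p3 = 0.9, μ4 = 114/(2·0.9·42) so E[n4] = 114. The
wy787-like profile shifts rates anterior — λ2 = (6, 5, 5, 12) totalling
28, p3 = (0.05, 0.05, 0.30, 0.85), μ4 chosen so E[n4] = 17 — and gives
its defective (non-menorah) secondaries short truncated lengths and wide
orientation noise, reproducing the short, misoriented posterior
secondaries and the complexity peak in +3. Per-region splits for all
genotypes are *estimates* shaped to the described phenotypes (the
numeric per-region table is in an external supplement not available
here); only the four whole-arbor totals are treated as reported values.
Profiles are plain frozen dataclasses, exportable/importable as
versioned YAML.

Geometric guardrails keep classification well-posed by construction:
intact stems cap orientation noise at ±15° and defective stems at ±60°
from perpendicular; tilts that would push a tip past the primary's
x-extent are reflected toward the interior; arms are clipped 1.5 μm
inside the primary tips; quaternaries never attach at an arm's tip node
(a 90° bend at a chain tip is indistinguishable from a continuation in
any skeleton format). Consequently the primary tips are always the
unique A-P extremes and path extraction is exact.

Kymograph scenes draw comet births uniformly in time, positions
uniformly across the field, direction from the region's plus-end-out
fraction, speeds from 0.10–0.30 μm/s, and *finite lifetimes of 3–10 s*
(EB comets end by catastrophe; letting streaks persist to the field edge
produces unrealistically dense crossings). Streaks have Gaussian profile
(σ = 1.2 px, amplitude 80) over a Poisson background (mean 8);
`noise=False` renders the exact float streak sum for oracle tests. FRAP
traces follow the single-exponential model with additive Gaussian noise
(σ = 0.02 by default); wild-type recovers faster and more completely
(τ = 20 s, mobile fraction 0.75) than the rab-10-like profile (τ = 60 s,
plateau 0.5) by construction.

Master-seed handling: cohorts derive per-animal seeds via
`numpy.random.SeedSequence(master).spawn(n)` reduced mod 2³¹, so a
(profile, n, seed) triple reproduces a cohort bit-for-bit across
platforms.

**What the generator does not emulate:** image noise and tracing errors
in skeletons (nodes are exact), developmental dynamics (a profile is one
stage snapshot), 3-D geometry, branch-length distributions beyond the
simple truncated normals, spatial correlation between neighbouring
menorahs beyond tiling, comet nucleation bursts or pausing, and FRAP
bleach-spot geometry. Tests passing on synthetic data therefore
demonstrate correctness of the *computations* under the stated
generative assumptions, not robustness to segmentation artifacts in real
micrographs.

## Problem sizes and numerical choices

Calibration checks use 200-animal cohorts (standard error on the mean
total 2° count ≈ 0.46 branches, so a 2-SE check is a ±1-branch test);
null-distribution checks use 2000 Monte-Carlo replicates (binomial SE on
a 5% rate ≈ 0.5%); mixture-recovery checks pool ~50 kymograph scenes
(~500 comets). The Tukey family-wise-error check compares an observed
proportion over 2000 seeded replicates against its nominal 5% level;
being an exact procedure, the observed value hovers at the level and the
check is meaningful only together with its fixed seed. Fit tolerances:
noiseless oracle round trips are asserted at 1e-6 (parameters) and the
kymograph slope oracle at 1e-6 μm/s, both far above float64 error but
far below any biological effect. Degenerate inputs are defined, not
undefined: empty segments score BCI 0, flat FRAP traces fit with zero
mobile fraction, blank kymographs return zero tracks, and zero-track
polarity results are flagged undefined.

## Known limitations

- Branch-order rules are angle-threshold based; arbors with strongly
  curved tertiaries near 45° will classify sensitively to `theta_t`.
- The primary-path span criterion assumes the skeleton is registered
  with A-P along x; unregistered skeletons must be rotated first.
- The FRAP ANOVA ignores repeated measures (see above).
- The comet linker is greedy; extremely dense scenes (many simultaneous
  crossings) will still fragment or swap a small fraction of tracks.
- Penetrance depends on a configurable threshold rule; reported
  fractions are only comparable under the same rule and reference.
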
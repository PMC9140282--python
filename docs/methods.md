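# Methods

## Habituation scoring

A session is a fly's ordered per-trial jump outcomes under a protocol.
Two protocols are built in: habituation (100 pulses of 15 ms, 1 s
inter-trial interval, 500 ms recording window) and fatigue (50 pulses,
5 s interval). Raw amplitude traces are reduced to jumps by a single
threshold — a jump is any sample in the window at or above it. The
threshold is a configuration value in the trace's own amplitude units; no
per-chamber auto-calibration is attempted, since any such rule is specific
to the recording hardware, and a fixed declared threshold keeps reruns
reproducible.

**TTC (Trials To Criterion).** The criterion is a run of k = 5 consecutive
no-jump trials. The phrase "trials to criterion" is ambiguous about
whether the criterion run itself counts. The default convention here is
*last-jump*: TTC is the 1-based index of the last jump before the first
qualifying run, so a fly that jumps only on trial 1 has TTC = 1. This
matches healthy-control group means in the low single digits; the
alternative (*criterion_end*: the trial completing the run, giving that
same fly TTC = 6) is available via `compute_ttc(..., convention=
"criterion_end")`. A fly that never jumps has TTC = 0; a fly with no
qualifying run is censored at TTC = n_trials and, rather than receiving a
survival-analysis treatment, enters the linear model at that ceiling
value — censored flies are precisely the slow habituators the model should
see as slow.

**Performer filter.** A genotype is analysed only if at least 50% of its
tested flies jump on trial 1 (boundary included at exactly 50%). Only
those initial jumpers are scored: this both reflects that habituation of a
response that was never shown is unmeasurable, and guarantees TTC ≥ 1 so
the log transform below is defined.

## Statistics

Genotype effects are estimated by OLS of log(TTC) (natural log; the base
is inferentially irrelevant) on genotype plus testing day and recording
system as unpenalised categorical fixed effects, dummy-coded against a
designated control. Multi-genotype experiments are fit as one
mutant-vs-control model per mutant with the shared control, and the
family — defined as the set of comparisons requested in one invocation —
is corrected by step-down Bonferroni–Holm. Rank-deficient designs (e.g. a
genotype tested on only one day, aliasing genotype with day) raise an
error naming the aliased columns rather than silently dropping terms.

The fatigue rule is deliberately sign-gated rather than one-sided: the
two-sided model p is computed as elsewhere, and "fatigue" is returned only
when the test-group effect is negative *and* adjusted p < 0.05. A test
group jumping significantly longer than control is never fatigue.

Supporting tests follow standard practice and delegate to scipy /
statsmodels: one-way ANOVA with Tukey HSD for normally distributed
morphometry parameters, Wilcoxon rank-sum (exact when the pooled sample
is ≤ 12 and tie-free, normal approximation with tie correction otherwise)
and Kruskal–Wallis with Holm-corrected pairwise rank-sums for counts,
pooled-variance t-tests for survival proportions, and trapezoidal AUC for
island-assay curves. Degenerate inputs follow explicit conventions:
all-identical groups give F = 0 / H = 0 with p = 1, zero-variance t-tests
give p = 1 (equal means) or p = 0 (unequal). Fisher's two-sided p uses the
"sum of all tables no more likely than observed" rule, matching the
convention of the standard statistical environments; tail-doubling is
available as an option.

## NMJ morphometry

The membrane channel is smoothed (Gaussian, σ = 1 px), thresholded,
cleaned (objects below `min_area_um2` removed, holes filled) and reduced
to its largest 8-connected component. The default threshold is Otsu
followed by one refinement to the midpoint of the two class medians:
with a small bright object on a large background Otsu's criterion drags
the level toward the background class, which systematically dilates the
mask (several percent in area for thin tubes); the median-midpoint step
restores the half-intensity boundary.

The mask is thinned to a one-pixel skeleton. Pixels with ≥ 3 skeleton
neighbours are junction pixels and adjacent junction pixels merge into a
single branching point; pixels with exactly one neighbour are endpoints;
branches are the paths between nodes. Side twigs shorter than
`prune_spurs_um` (default 1 µm) that end at an endpoint are removed before
counting, suppressing thinning artifacts on rough boundaries.

Reported geometry: area is the foreground pixel count × pixel area;
perimeter is the summed segment length of the sub-pixel boundary contours;
length is obtained by tracing each skeleton path and summing Euclidean
chords over every 4th pixel. The chord construction matters: the naive
per-step chain sum (1 px per 4-neighbour step, √2 per diagonal)
overestimates digitised oblique curves by up to ~8% from boundary zigzag,
while subsampled chords are exact on straight segments and stay within
~1% on curves at the curvature scales of these structures.

Boutons are local maxima of the smoothed vesicle channel inside the mask,
above `bouton_threshold_rel` of the channel maximum and separated by at
least `bouton_min_distance_um` (default 1.5 µm); closer maxima merge into
one bouton, so the count is a lower bound when boutons nearly touch.
All defaults live in one `MorphometryParams` block for recalibration on
real micrographs. Discriminating terminal types (e.g. selecting type-1b
over other innervation in a crowded field) is out of automatic scope: the
user crops, or the largest component is taken.

## Synthetic data

**Behaviour.** Fly i of a genotype jumps at trial t with probability
p0 · exp(−λ_eff · (t−1)), λ_eff = λ_genotype · day_factor · system_factor,
with independent Bernoulli draws. This exponential-in-trial decay is the
simplest monotone model consistent with monotonically waning group
habituation curves; it is a stand-in, not a mechanism. Defaults: p0 =
0.65 (about two thirds initial jumpers, as healthy controls show), control
λ = 0.3 (mean TTC ≈ 4, the healthy-control regime), 96 flies per genotype
cycling over 3 testing days × 2 systems × 16 chambers, day factors
(1.0, 0.9, 1.1) and system factors (1.0, 1.15). Batch effects multiply the
decay rate — not p0 — so they act approximately additively on log-TTC,
i.e. the linear model is approximately well-specified; real batch effects
need not be so polite, which is exactly what the day/system covariates are
for. The fatigue generator forces λ = 0 (response stays high under 5 s
spacing); a positive `fatigue_decay` models true exhaustion. Traces, when
requested, are sub-threshold folded-normal noise with a supra-threshold
burst on jump trials.

**NMJ scenes.** A gently curving left-to-right backbone (random-walk
heading, bounded curvature) with perpendicular side branches is rendered
as a tube of width 1.25 µm (5 px at the default 0.25 µm/px) by exact
point-to-segment distance, plus unit-intensity bouton disks and Gaussian
noise (σ = 0.1 against unit foreground, i.e. SNR 10). Scenes are sampled
in µm coordinates, so one scene renders consistently at any pixel size.
Ground truth: counts from the construction, length as the generating
polyline length, area/perimeter measured on the noiseless rendering.
Infeasible placements retry a bounded number of times, then fail loudly.

**Gene universes.** Synthetic identifiers partitioned so each category's
realised (a, b, c, d) equal the planted values exactly.

Every generator is a pure function of config + seed; child seeds derive
from the master seed as `default_rng([seed, group_index, item_index])`, so
any subset regenerates identically.

What the generators do *not* emulate: spontaneous recovery and
dishabituation dynamics, within-fly trial-to-trial dependence (draws are
independent given the decay curve), chamber-level effects, anisotropic
imaging noise, out-of-focus light and varying marker expression, or
ortholog-mapping noise in gene lists. Passing tests therefore demonstrate
correctness of the measurement chain under these idealised conditions, not
robustness to every artifact of real rigs and microscopes.

## Calibration studies and problem sizes

The pipeline-level checks run at sizes chosen to keep the whole suite
fast while leaving Monte-Carlo error well inside the asserted margins:
type-I error of the full simulate → score → filter → model chain over
1000 null replicates at n = 32 flies/group (observed ≈ 0.04–0.05 at
α = 0.05, rate computed over replicates where both genotypes pass the
performer filter, since otherwise no comparison exists); power ≥ 90% over
200 replicates for a mutant at half the control decay with n = 96; fatigue
verdict rates over 200 replicates per condition; morphometry recovery over
100 random scenes (bouton and branching-point counts exact, length and
area within 5%); Fisher's exact test against full hypergeometric
enumeration for every valid table with universe ≤ 30; Holm procedures
against hand step-down on 1000 random vectors. The acceptance script runs
moderately smaller replicate counts (400/150/150) for the same quantities.

## Known limitations

- Censored (never-habituating) flies enter the model at the trial-count
  ceiling; with many censored flies the genotype effect is attenuated and
  a survival model would be more efficient.
- The per-pair linear model refits the control against each mutant rather
  than fitting one joint model with contrasts; with shared controls the
  comparisons are therefore not independent, which Holm tolerates but does
  not exploit.
- Bouton counting assumes roughly disk-like puncta; elongated or hollow
  boutons on real micrographs may need different `MorphometryParams`.
- The skeleton graph treats the NMJ as effectively planar (2-D
  projections); crossing branches in a projection would merge into
  spurious junctions.
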
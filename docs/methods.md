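# Methods

## The statistic

The package analyzes *network connectedness*: for a network mask N and a
voxel v ∈ N, a subject's connectedness in one scanning condition is

    C(v) = arctanh( (1/(|N|−1)) Σ_{u≠v} r(x_v, x_u) ),

the Fisher-z of the mean Pearson correlation of v's residual BOLD series
with every *other* network voxel. Self-correlation is excluded by default
("every other voxel"); an `include_self` flag reproduces the inclusive mean
some toolchains use, and a `z_before_average` flag averages arctanh(r)
instead of r as a sensitivity variant (it needs the dense correlation
matrix, so reserve it for small networks). Censored frames are dropped from
every correlation. The map is computed in a block matrix form — standardize
the in-mask series to unit columns, one matrix-vector product per run — so
a 15,000-voxel network costs O(T·V), not O(T·V²).

## Two-step inference

**Step 1 — hotspots.** For a pair of conditions (a, b), a paired t test per
voxel on the subjects' connectedness maps is standardized through the t CDF
to the normal scale (z(t)), thresholded two-tailed at |z| > 1.96 (p < 0.05),
and clustered by 6-connectivity, positive and negative voxels separately.
The cluster-size threshold is calibrated per contrast by a sign-flip
Monte-Carlo permutation: each of 100 permutations swaps the two conditions
for a uniformly random half of the subjects (exactly ⌊n/2⌋, fresh draw per
permutation), recomputes the z map, and records the maximum cluster size
over both signs jointly; the threshold is the smallest size whose
exceedance proportion falls strictly below α = 0.05 (ties broken upward).

**Step 2 — drivers.** Each surviving hotspot's spatially averaged series
seeds a network-constrained Fisher-z correlation map per subject and
condition; the same paired contrast at |z| > 3.291 (p < 0.001) and a
per-hotspot permutation threshold yield its drivers, with a conservative
20-voxel floor imposed on top of the permutation threshold. The hotspot's
own voxels are excluded from driver candidacy (the seed trivially
correlates with itself); `allow_self_drivers` restores inclusive behavior.
Driver detection is two-sided; driver sets from different hotspots may
overlap.

The t→z conversion composes the t survival function with the normal
quantile in log space (`ndtri_exp`), evaluated through the smaller tail, so
very large |t| maps to a finite, monotone z instead of overflowing; ±∞ t
becomes a ±40 sentinel. With few subjects this matters in the opposite
direction too: at df = 11 even enormous t values standardize to z ≈ 6–8,
so very strict voxel thresholds are only reachable with adequate group
sizes.

## Network definition and targeting

Group masks are built the way seed-defined resting-state networks are:
per-subject seed-mean correlation maps (Fisher z) over the sham runs, a
one-sample t across subjects, a strict positive-tail voxel threshold
(library default p = 10⁻⁸ on the group z map, the full-cohort setting; the
desk-scale demo pipeline uses 10⁻⁵ because standardized z saturates near 6
at df = 11), a cluster-size floor from smoothed
Gaussian noise simulations (the Monte-Carlo cluster-threshold mechanism),
one dilation step, and intersection with the brain mask. The overlap voxel
count of the two networks is reported as a first-class quantity.
Individualized seeds come from a baseline run: the hippocampal-like target
is the most interconnected fraction (default top 5%, configurable) of an
anatomical mask ranked by within-mask connectedness; the stimulation site
is the single search-mask voxel with peak Fisher-z connectivity to the
target mean series (ties to the lowest linear index, logged).

## Preprocessing model

Residualization is one simultaneous ordinary-least-squares fit per voxel:
intercept, linear trend, nuisance regressors, and sine/cosine regressors at
the DFT frequencies outside the 0.01–0.1 Hz band. Projecting out the
out-of-band Fourier terms *is* the bandpass, so filtering and nuisance
removal cannot interact as sequential filters would. Censored frames are
excluded from the fit, zero-filled in the output (format fidelity), and
kept flagged so correlations drop them; including the literal zeros would
bias r toward 0. The fit excludes censored rows, which also makes
residualization idempotent. Smoothing (Gaussian, σ = FWHM/2√(2 ln 2) per
axis, zero-padded edges) precedes residualization by default; intensity
normalization scales each voxel series to mean 100 over non-censored
frames and leaves empty voxels at zero.

## Synthetic cohort

Each run is `y_v(t) = Σ_k (λ_kv + Δ_kv(c))·g_k(t) + ε_v(t)`: one
unit-variance AR(1) latent per network per run (φ = 0.3), loadings λ
constant inside a network, condition-dependent coupling perturbations Δ
confined to declared effect regions, and AR(1) noise spatially smoothed
(default 3-mm FWHM) then rescaled so its marginal SD stays `noise_sd` —
bandpassed BOLD residuals are autocorrelated, hence AR(1) rather than
white noise. 5% of frames per run are zero-filled and flagged as censored.
Deterministic given the config seed.

Defaults define the desk-scale study: 12 subjects, 300 frames at
TR 0.555 s, a 20×20×12 grid of 2-mm voxels. Three design choices deserve
explanation because the first obvious alternatives fail:

* **Multi-region masks.** The two networks (596 and 496 voxels, 96
  shared) are unions of five spatially separated ~100–125-voxel blocks,
  not single solid boxes. Real seed-defined networks are distributed
  patch-works, and the geometry is load-bearing: inside one compact solid
  box a smooth null field grows connected excursions of a hundred-plus
  voxels, the permutation cluster threshold inflates past any plausible
  effect size, and cluster inference loses all resolution. Distributed
  masks bound the null excursions and put the cluster threshold
  (typically ~10–20 voxels here) on the right scale.
* **Weak, calibrated coupling.** Base loading is 0.2 over unit noise,
  i.e. a network-mean pairwise correlation near 0.04 — the order observed
  for whole-network mean connectedness in resting-state data, where
  averaging over all (mostly long-range) pairs dilutes correlation
  strength. The coupling level also controls a known artifact of the
  single-latent model: every voxel's connectedness shares the latent's
  sampling fluctuations, so the null contrast field carries a voxel-common
  factor whose weight grows with the squared loading. Exact-half sign
  flipping handles a heavy-tailed common factor imperfectly (the
  permutation distribution of a linear statistic of fixed values is
  bounded; the observed counterpart is t-tailed), so strong coupling makes
  cluster inference measurably anticonservative at n = 12 — the null
  family-wise hotspot rate climbs to ~0.10 by loading 0.3 and worsens
  beyond. The generator must satisfy the null exchangeability contract —
  no-effect conditions yield a family-wise hotspot rate near the
  permutation α — and the coupling level is the knob that sets it: at
  loading 0.2 the rate sits near ≈0.08 (pooled over 600 replicate
  studies; the residual excess over 0.05 is the exact-half flipping
  artifact, see limitations) while injected effects remain cleanly
  recoverable. Noise smoothness
  defaults to 3-mm FWHM on 2-mm voxels (mild genuine spatial correlation;
  the preprocessing module's smoothing operation is independent of this
  choice and documents the conventional 4-mm kernel).

The injected ground truths used by the recovery evaluations: a 40-voxel
block losing 80% of its network loading in one condition (a connectedness
decrease, i.e. a negative hotspot), and a separate configuration in which
an extra "coupling" latent (loading 0.35, deliberately stronger than the
network loading so the pair is tightly coupled) links the hotspot block to
a remote 30-voxel block and the remote block's share is removed in one
condition — changing hotspot-to-block coupling while leaving the hotspot's
own connectedness untouched, the driver situation.

What the generator does *not* emulate: hemodynamics, head motion and
scanner artifacts, between-subject anatomical variability, stable
individual differences in connectivity (across-subject variance here is
pure sampling noise), and multi-community network structure beyond the one
latent per network. Passing tests therefore show that the inference
machinery is correct and calibrated *under this model*, not that the
original scanner analysis is reproduced.

## Stimulation schedules

The schedule module is a deterministic pulse-time model: cTBS is 200
consecutive 50-Hz triplet bursts at 5 Hz (600 pulses, one 40-s train);
iTBS is 20 trains, 10 bursts per 2-s train, 8 s off (600 pulses; final
train onset at 19 × 10 s = 190 s — the printed "190-s duration" matches
the final-train-onset convention, while the literal first-to-last pulse
span is ~192 s); the 20-Hz protocol is 2-s 40-pulse trains with 28 s off
over 20 minutes (1,600 pulses), delivered as sham at 10% of resting motor
threshold (TBS protocols use 80%). The active 20-Hz condition's intensity
is modeled at 80% RMT, the TBS convention.

## Numerical choices

* Correlations are clipped to |r| ≤ 1−10⁻⁷ before arctanh (with a
  warning); constant series give NaN with a warning and are excluded from
  connectedness means.
* Adjacency defaults to 6-connectivity (faces only), the conservative
  choice; 18 and 26 are available.
* Permutation thresholds break ties conservatively upward (strict
  exceedance < α).
* Degenerate paired tests: zero spread with non-zero mean gives a signed
  infinity, standardized to a ±40 sentinel; all-zero differences give t=0.
* Cluster centers are unweighted means of member voxel-center world
  coordinates; volumes are exactly count × voxel volume. Reported x flips
  sign under the `right_negative_x` convention so right-hemisphere voxels
  print negative x, matching the reporting convention of the field's
  cluster tables.

## Problem sizes

The replicate evaluations run the full pipeline on the desk-scale study:
100 null replicates for the family-wise rate, 20 seeds for hotspot
recovery, 10 for driver recovery, 20 for null driver thresholds, each with
100 permutations. The full-cohort scale (24 subjects, 550 frames) is one
config change away but is not exercised by the default suite.

## Known limitations

* The permutation test flips exactly ⌊n/2⌋ subjects (the procedure being
  modeled does the same); it is not an exact group-invariance test, and
  under the generator's voxel-common factor it runs mildly anticonservative
  at n = 12 (see above). With larger cohorts the observed common factor's
  t-tails lighten and the gap narrows.
* Network definition treats all inputs as already co-registered in one
  space; no template normalization, and no Talairach/MNI distinction.
* The noise-simulation cluster threshold for mask formation is
  mechanism-faithful (smoothed Gaussian fields, max-cluster exceedance),
  not argument-faithful to any particular external tool invocation.
* `z_before_average` is O(V²) memory and intended for small networks.
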
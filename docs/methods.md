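# Methods notes

## The synthetic VNC model

The generator renders the ventral somatosensory neuropil of a larval VNC as
a set of co-registered channels on one voxel grid, arrays ordered
`(z, y, x)` with `x` mediolateral (midline at `midline_x`), `y`
anterior–posterior, 0-based indices, half-open voxel ROIs. Physical
coordinates are voxel index × voxel dimension, reported in µm as
`(x, y, z)`.

**Axons** are constant-intensity tubes: centerline polylines are rasterised
and dilated to `axon_radius` (default 0.5 µm) by a Euclidean distance
transform with anisotropic sampling, then convolved with a Gaussian PSF
(default σ 0.15 µm lateral, 0.5 µm axial) — a cheap approximation of
confocal blur, not an optics model. The cIV scaffold has two longitudinal
connectives at ±3 µm and one commissure per neuromere, each `full`,
`partial` or `absent`. Partial commissures reach 40% of the span from each
side (configurable); centerline stubs end one radius short so the rendered
tube tip — which carries a spherical end-cap — lands at exactly that
fraction. cIII tracts run at ±8 µm; FasII-like landmark tracts at
±5.5 µm, between the two classes, delimit the medial analysis region. An
optional sinusoidal wobble of the cIV tract positions produces scaffold
edges with known analytic tortuosity.

**Puncta** are sums of isotropic Gaussian spots (σ 0.15 µm, truncated at
3σ) placed inside cIII tubes: a sampled centerline point plus a radial
offset within 0.8 × `axon_radius`. Requested per-region counts are exact in
the ground truth by construction — radial jitter is clamped in `x` so a
punctum's region label (medial/lateral of the landmark tracts, with a
0.25 µm safety margin) always matches its position. A soft minimum
separation (default 0.8 µm) is enforced by rejection sampling and relaxed
rather than violated count conservation. The puncta channel is *not*
additionally PSF-blurred: the spot σ already plays that role.

**Dendrites** are a bilateral band with a raised-cosine mediolateral
profile on a thin z-slab spanning the neuromere range; the
`dendrite_shift` perturbation translates the band laterally. **GRASP** is
rendered as cIII membrane restricted to the dendritic-field footprint —
contact exists where a cIII axon runs inside the field — which reproduces
the lateral confinement of touch-receptor contact in controls and its
medial spread when ablation adds crossing cIII branches.

**Noise**: expected intensity = signal + background (+ optional x-gradient);
Poisson shot noise on expected counts (gain 1) followed by Gaussian read
noise (default background 10, read σ 2 on a 16-bit-like scale), clipped at
0. All randomness (puncta, blebs, noise) flows from one seeded generator in
a fixed order, so identical specs give voxel-identical stacks.

**Defaults as study conditions.** Voxel dims (0.5, 0.1, 0.1) µm match the
puncta acquisition scale; the line-scan scenario uses 0.29 µm lateral
pixels and a 40 µm-wide footprint so a 35 µm scan fits. Six neuromeres
(A2–A7) at 7 µm pitch; 50 lateral puncta ≈ 0.6 per µm of cIII axon.
Amplitudes ~100–150 over background 10 give peak SNR ≈ 10–15, a bright but
realistic confocal regime.

## What the generator does not emulate

No photorealistic PSF (no Airy rings, no depth-dependent aberration), no
tissue autofluorescence structure, no misregistration or larval movement,
no embryonic time-lapse dynamics, no cell bodies or peripheral dendrites.
Axon paths are idealised straight tracts; real scaffolds meander, so
passing tests demonstrate correctness of the *measurement chain*, not
robustness to every anatomical irregularity of real data.

## Image operations

Foreground is strictly greater than the threshold, everywhere. Histograms
use 256 levels: integer images with ≤256 distinct levels are binned at
integer values (thresholds are then exact intensities); wider or float
data use 256 equal bins and bin-centre thresholds. **Otsu** maximises
between-class variance by exhaustive scan. **Li** scans the 256 levels for
the global discrete minimiser of the cross entropy and then applies the
classical fixed-point refinement (`t ← (μ_bg−μ_fg)/(ln μ_bg−ln μ_fg)`,
stopping below 0.5 intensity units); the initial global scan matters
because the fixed point from a mean start can land in a local minimum on
overlapping histograms. Note the cross-entropy surface is exactly flat
across empty histogram gaps, so "the" minimiser is a set; the refinement
may settle anywhere on that plateau.

Manual noise clearing is automated as removal of 26-connected components
below `min_component_voxels` (default 5), exposed in every entry point.
**Rolling-ball** background is the grayscale opening of each z-slice with a
non-flat ball structuring element (the exact morphological ball, not the
paraboloid approximation used by some tools); output = input − background,
clipped at 0.

## Puncta detection

Optional Gaussian blur (σ in µm, converted per axis) → background
threshold (`absolute`, `otsu`, `li`, or `mean + k·sd`) → local-maximum
seeds → watershed region assignment by descending intensity → regions
whose peak rises less than `min_peak_height` above their highest saddle
merge into the higher neighbour (h-maxima); the global maximum of every
connected foreground component is always kept as a seed, so a large
`min_peak_height` merges a blob's sub-peaks into one punctum rather than
deleting the blob. Regions below `min_size` voxels are discarded;
centroids are intensity-weighted (above background); plateau ties resolve
to the lowest linear (z-major) index. Defaults (absolute background 15,
peak height 10, blur 0.1 µm, min size 4) account for axial undersampling:
with a 0.5 µm z-step and 0.15 µm spots, a punctum centred between planes
retains only ~25% of its amplitude.

Detection training replaces an opaque learned stage with a deterministic
grid search over `DetectionParams` maximising F1 against point
annotations, pooled over ROIs (pooled tp/fp/fn, a declared choice); ties
break by fewer false positives, then candidate order. Matching is greedy
by descending peak intensity; each detection claims the nearest unclaimed
truth point within `match_radius` (default 0.5 µm ≈ 5 lateral pixels / one
z-step — no radius is standard in the field, so it is explicit and
configurable).

## Morphometry

Tortuosity uses `math.fsum` for the arc length so straight polylines give
exactly 1. Scaffold edges are extracted per y-row from the z-projection
(extreme lateral foreground x on the requested side), then boxcar-smoothed
(0.5 µm) and resampled (0.5 µm): without this, pixel staircasing inflates
the arc length of a smooth sinusoidal edge by ~7%, far beyond the 2%
fidelity the sinusoid benchmark demands; with it the bias is <1%. Crossing
uses connected components (26-connectivity) within each neuromere's
y-slab: a segment crosses iff one component reaches the tract bands on
both sides (±1 µm tolerance). Line scans operate on a single z-plane (the
plane of maximal total signal by default, since plane choice is otherwise
unspecified) and use raw intensity; GRASP ROIs threshold with Otsu within
the ROI when no explicit threshold is supplied, reporting 0 for empty
ROIs. Bleb detection — a stand-in for visual scoring — finds 3D peaks
rising 1.15× above the tube amplitude; staging is then: ablated if either
hemisegment lacks tract signal (≥50% of rows in a ±1.2 µm band above half
amplitude), else blebbed at ≥2 blebs, else intact. Per-larva aggregation
is the arithmetic mean for every metric except puncta, which are summed.

## Statistics

Normality gate: Shapiro–Wilk per group at α = 0.05 (configurable);
both-normal → two-tailed unpaired t-test (equal variances), otherwise
Mann–Whitney U. Constant samples, on which Shapiro–Wilk is undefined, gate
as non-normal. Dunn's pairwise z-tests use pooled ranks with tie
correction and Bonferroni family adjustment (the classical Dunn
correction). Blinding pseudonyms are seeded hex codes checked to contain
no substring of any original name; the key table makes the mapping
lossless. Under the null the gated procedure is calibrated: ~5% rejections
at α = 0.05 (verified over 1000 seeded replicates in the test suite).

## Pipeline design

Child seeds derive from `SeedSequence(master, spawn_key=(group, index))`,
so enlarging a cohort never reshuffles existing larvae. Larva labels are
blinded before quantification and rejoined to groups only for statistics.
Per-larva puncta counts are Poisson-distributed by the pipeline around the
configured linear density (the generator itself keeps requested counts
exact); under ablation, medial branches receive puncta at the same per-µm
rate as the lateral tracts, with branch pieces trimmed by one radius at
tract junctions so sampled length tracks added volume — this is what makes
puncta *density* a constructed invariant while medial *counts* rise.
Problem sizes in the shipped experiments (six neuromeres, 24 × 42 × 4 µm
stacks, 5–15 larvae per group) were chosen so a full two-group experiment
runs in tens of seconds on one CPU while keeping every per-larva statistic
well above the detector's noise floor.

## Known limitations

The bleb detector and scaffold-edge extractor are parameterised stand-ins
for manual steps; both accept externally supplied features/polylines so
the downstream metrics can be used with hand annotation. The rolling-ball
ball differs from ImageJ's scaled paraboloid, so absolute background
estimates differ slightly from that tool. The crossing scorer can in
principle be bridged by contiguous super-threshold noise; component-size
filtering makes this vanishingly rare at the modelled noise levels but it
is not impossible at extreme noise. GRASP rendering equates membrane
proximity with reporter signal and ignores reconstitution kinetics.
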
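# Methods

`solepress` analyses spatio-temporal plantar pressure from instrumented
insoles: per-frame pressure matrices (kPa) sampled at 100 Hz, one grid
per foot, together with the wearer's body mass.  This note documents the
models, the numerical choices, and what the bundled synthetic generator
does and does not emulate.

## Coordinate frame and foot model

All computations run in a normalized, foot-aligned frame: the
anterior–posterior (AP) coordinate runs 0 (heel) to 1 (toes) along the
row axis, the medial–lateral (ML) coordinate 0 (lateral) to 1 (medial)
along the column axis; cell centres sit at `(i + 0.5) / n_rows`.  The
working grid defaults to 56 × 20 cells of 0.258 cm² each (3.9 sensors
per cm²), the resolution of a large-size commercial pressure insole.

The standardized outline is a plan-form half-width profile (rounded
heel, arch waist, metatarsal flare, toe taper) whose bounding box spans
the whole grid.  Four coarse regions — heel, arch, metatarsals, toes —
partition the in-outline cells by AP bands.  Their extents are
configuration, not constants (default 0.25 / 0.25 / 0.30 / 0.20 of foot
length): published region definitions vary widely between studies, so
the proportions are exposed rather than hard-coded.  Ties on a band
boundary break toward the posterior region so the partition is
deterministic.  Optional sub-regions (great toe, medial/lateral arch)
overlay their parent bands.

**Mapping raw matrices.** Border rows/columns that are empty across the
whole recording are trimmed, the remaining block is rescaled onto the
outline's bounding box, and out-of-outline cells are zeroed; the mapping
report states the fraction of raw pressure captured inside the outline.

**Rescaling between grids** (and the mapping above) uses exact
area-overlap rebinning rather than bilinear interpolation: each source
cell's pressure mass is split among the destination cells it
geometrically overlaps.  This was a deliberate design choice — rebinning
conserves the per-frame load exactly, keeps uniform fields uniform, and
confines a single-cell impulse to the image of its source cell, whereas
bilinear upsampling smears an impulse over a 4 × 4 footprint and needs a
post-hoc renormalization to conserve load.  AP and ML are stretched
independently (aspect ratio is not preserved), matching how an insole
matrix is fitted to a foot outline.

## Preprocessing

Stage order is fixed: spatial filter → temporal filter → recalibration →
synchronization → task trimming → step segmentation → turn exclusion →
step normalization.

* **Spatial filter**: isotropic Gaussian, σ = 0.5 sensors, zero-padded
  boundary.  Load is conserved except for mass convolved off the grid
  edge; with the outline inset from the border this loss stays well
  below 1% on loaded frames.
* **Temporal filter**: Butterworth low-pass at 18 Hz.  Order (4) and
  zero-phase (forward–backward) application are this package's choices:
  zero-phase filtering avoids shifting stance timings, at the cost of
  squaring the magnitude response (which only helps a low-pass).
  Negative ringing is clipped to zero — pressure cannot be negative.
* **Recalibration**: a single scalar, true body weight divided by the
  mean measured force over the most stable (minimum-variance) 5 s window
  of a single-foot-stance validation recording.  Drift over time is not
  modelled.
* **Synchronization**: insole and IMU streams each contain a stomp
  spike (≥ 5 × the median absolute level); streams are aligned on their
  spike maxima and everything up to and including the spike is deleted.
* **Trimming**: quiet standing skips 10 s and keeps 45 s; wobble-board
  skips 10 s and keeps 35 s; sit-to-walk keeps data before the first
  detected step; other tasks pass through.
* **Step segmentation**: stance phases are maximal runs where the
  whole-foot pressure sum exceeds a threshold, 500 kPa by default with
  per-participant overrides.  The threshold is interpreted as a sum over
  all cells — the plausible reading given overrides in the thousands of
  kPa.  Runs shorter than 0.2 s are rejected as threshold chatter (the
  debounce constant is this package's addition), and the first and last
  steps are dropped as partially captured.
* **Turn exclusion**: candidate turns are runs where |yaw rate| stays
  above a 10 °/s noise floor; a candidate is a turn when yaw integrated
  over some 2 s window inside it reaches 45° *and* its total integrated
  yaw reaches 115°.  The relationship between the two criteria is
  genuinely ambiguous; both thresholds are exposed in
  `PreprocessConfig`.  Steps overlapping a turn window are discarded.
* **Step normalization**: per-cell linear interpolation onto 100 time
  points, endpoints preserved exactly.

## Contact metrics

A sensor is *active* when its pressure strictly exceeds the
`ActivationRule` threshold (default 0 kPa, i.e. any positive reading
after filtering).  The threshold is exposed because it directly controls
contact area and no canonical value exists.

* **Total force**: `force_N = Σ p_kPa · A_cm² · 0.1`, reported as % body
  mass with g = 9.81 m/s².  Frames under 5% body mass are excluded from
  summaries (insole noise during swing); frames at exactly 5% are kept.
* **Contact area**: active in-outline cells as % of in-outline cells.
* **CoP / CoC**: pressure-weighted and unweighted centroids of active
  cell centres.  The CoP is deemed "in contact" when its nearest grid
  cell is active — no sub-cell interpolation.  Its local pressure
  percentile is the weak percentile (share of active cells at or below
  the CoP cell's pressure) so a single active cell scores 100.
  CoP region occupancy clamps out-of-outline CoP locations to the
  nearest in-outline cell and reports the clamped count separately.
* **Shared variance** between CoP and CoC per axis is the squared
  Pearson correlation; CoP–CoC distances are reported as % foot length
  (AP) and % foot width (ML), which in normalized coordinates are the
  raw differences × 100.
* **Force vs area**: Spearman's ρ (midranks for ties) with ρ² reported
  as shared variance, plus a 2-D histogram on [0, 100]².

## Spatial complexity (NMF)

Frames are flattened to a non-negative matrix X (T × 1120) and
factorized X ≈ W H by multiplicative updates minimizing the Frobenius
error (tolerance 1e-6 relative change per iteration, ≤ 500 iterations).
The solver is implemented in-house so that each fit can assert factor
non-negativity and monotone error decrease per iteration, and so restart
seeding is exactly reproducible (restart r uses seed + r; best final
error wins, ties to the lower index).  Spatial maps are normalized to
unit sum with the scale absorbed into the activations, and components
are sorted by activation energy (Σ w²), descending.

Variance explained is uncentred, VE = 1 − ‖X − WH‖²_F / ‖X‖²_F: NMF has
no intercept, so mean-centring has no natural place.  The spatial
complexity of a task is k\*, the smallest k with VE ≥ 0.90; a sweep over
thresholds 0.65–0.95 is available.  The fitted VE curve carries the
running best forward across k (a larger k can always represent a smaller
model), making k\* monotone in the threshold by construction.

**Cross-task clustering.**  Components pooled from all tasks (left-foot
maps mirrored to right-foot orientation first) are correlated pairwise
(Pearson on vectorized maps) and clustered hierarchically on distance
1 − r with average linkage, cut at distance 0.5 — i.e. components
correlating above 0.5 share a cluster.  The cut is a configurable
default, not a claim about any particular cluster count.  Cluster
*emergence order* grows the pooled set by each task's top-n components:
since including top-n components includes exactly the members with
within-task rank ≤ n, a cluster first becomes populated at the minimum
rank among its members; clusters are ordered by that n, ties broken by
total cluster energy.

**Subsample sensitivity** refits k\* components on random fractions of
the frames (default one third) and matches subset components to the
full-data components greedily by spatial correlation, reporting matched
correlations and centroid displacements in cells.

## Group statistics

Tasks within a category are compared with Kruskal–Wallis (tie-corrected,
χ² p-value) followed by two-sided Mann–Whitney U tests for all pairs
with Bonferroni correction (factor = number of pairs, capped at 1).
The observation unit is a per-participant (or per-chunk) task mean, not
raw frames, to avoid pseudo-replication.  Exact U distributions are used
for small samples without ties, the tie-corrected normal approximation
otherwise (scipy's policy).

## Synthetic generator

The generator provides recordings with the statistical structure the
pipeline assumes, plus exact ground truth; it is a test harness, not a
biomechanically validated gait model.

* **Standing / wobble**: unit-sum Gaussian load templates at the heel
  and metatarsals; the total vertical load equals body weight each
  frame, shared between feet by a low-frequency (< 1 Hz) two-component
  sway in the ML direction, with AP sway shifting load between heel and
  metatarsals (amplified 4× on the wobble board).
* **Walking / gravel**: each stance is a Gaussian blob whose AP centre
  travels heel → toe along a smoothstep path while its amplitude follows
  a double-humped (heel-strike / push-off) profile, scaled so the
  per-stride vertical impulse equals body weight × stride duration / 2
  per foot (mean stance force = BW / (2 × duty factor), ≈ 83% BM at duty
  0.6).  Stride rate defaults to 0.9 strides/s.  Gravel adds
  Poisson-placed stones (default 4 per stance) that multiply local
  ≤ 3 × 3 patches by 3 — multiplicative, so hotspots scale with load —
  drawn from a separate RNG stream so `hotspot_rate = 0` reproduces
  plain walking bit-exactly.
* **Sensor noise**: additive zero-mean Gaussian per in-outline cell
  (default σ = 0.5 kPa), clipped at zero, followed by a per-sensor
  activation floor of 2σ: readings indistinguishable from noise report
  zero.  The floor emulates the behaviour of resistive insoles, which
  under-read loads spread thinly over many sensors — this is why
  simulated two-foot standing averages just *below* 50% body mass per
  foot, as real insoles do.  With σ = 0 the generators conserve load
  exactly.
* **Planted components**: K unit-sum Gaussian blobs (σ = 2 cells,
  default centres ≥ ~5 cells apart; centres closer than 2 cells are
  rejected as unidentifiable) with rectified smooth activations that
  take turns dominating in randomly assigned time blocks and are
  normalized to equal per-component energy.  The epoch structure and
  energy equalization make the planted rank identifiable under the
  uncentred-VE criterion: each component contributes a comparable,
  separable variance share, so VE(k) grows roughly linearly to K.
  Default activation scale gives signal-to-noise well above 10.
* **Stomp and turns**: 1-D summed-pressure and yaw-rate traces with one
  coincident spike pair and constant-rate yaw segments integrating to
  requested angles.
* **Jump**: a single impact transient peaking at 3× body weight,
  settling to standing; used for force-range checks only.

Not emulated: realistic insole noise spectra and drift, shear forces,
anatomical left/right asymmetries beyond mirroring, muscle/skeletal
dynamics, and inter-participant variability.  Tests passing on this
generator therefore certify the *pipeline's* correctness and the
qualitative contrasts the generator encodes (standing vs locomotion
force, gravel vs flat complexity), not quantitative fidelity to any
human cohort.

## Problem sizes and runtime choices

The test suite and the reproduction script use deliberately compact
problem sizes chosen as the smallest that exercise each property
cleanly: 45 s standing and 10–12 s (about 10 strides) of gait at 100 Hz;
planted-component recovery on 200-frame recordings with 3 NMF restarts;
the gravel-vs-flat complexity contrast on 8 s recordings, every 4th
frame, single restart (spatial NMF is order-free in time, so frame
subsampling changes only the effective sample size); 2000 null datasets
for the family-wise-error calibration.  Full-scale analyses simply pass
larger durations and `n_restarts=10`.

## Known limitations

* The VE curve of multiplicative-update NMF is monotone in k only up to
  solver tolerance (~1e-4 in VE); the complexity sweep therefore carries
  the running best VE forward across k.
* The activation threshold for "active sensor" defaults to strictly
  positive pressure; measured contact areas depend directly on it.
* The region proportions of the standardized outline are placeholders;
  studies wanting cohort-specific outlines should measure and pass their
  own proportions.
* `cop_coc_relationship` pools frames; per-participant averaging before
  correlation is the caller's responsibility if desired.
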
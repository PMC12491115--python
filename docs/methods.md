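# Methods

This note records the models, defaults, and numerical choices behind
`odontomatch`, and what the synthetic evidence does and does not show.

## Comparison model

Two scans are compared as point clouds sampled area-uniformly from their
triangle meshes. Registration is trimmed point-to-point ICP: at each
iteration every (subsampled) source point is matched to its nearest target
point in a k-d tree, the `trim_fraction` worst pairs are discarded, and the
rigid transform is refit in closed form (SVD of the cross-covariance, with
the smallest singular vector sign-flipped if the unconstrained optimum is a
reflection). Iteration stops when the trimmed RMS changes by less than
`rel_tolerance` in relative terms, with a 1 nm absolute floor so that exact
data (RMS fluctuating near machine epsilon) terminates, or at
`max_iterations`.

The RMS is **one-directional** — source (PM) onto target (AM), over the
retained correspondences of the final iteration. For partially overlapping
clouds the measure is not symmetric; the PM→AM direction is fixed by
convention throughout. `trim_fraction = 0` recovers classical ICP; the
default 0.1 bounds the influence of capture-extent mismatch.

### ICP defaults

| parameter | default | meaning |
|---|---|---|
| `max_iterations` | 100 | iteration cap |
| `rel_tolerance` | 1e-6 | relative trimmed-RMS change at convergence |
| `trim_fraction` | 0.1 | worst correspondences dropped per iteration |
| `sample_size` | 20000 | seeded source subsample |
| `pre_align` | centroid_pca | coarse initialization |

### Pre-alignment

Coarse alignment matches centroids and principal axes. The PCA axis-sign
ambiguity leaves four proper-rotation hypotheses; on near-symmetric dental
arches the mirrored hypothesis can have a marginally *better* initial RMS
than the true one and then converge to a mirrored local minimum. Each
hypothesis is therefore refined by 12 trimmed-ICP iterations on a ~1500-point
probe subsample and the lowest refined RMS wins. The procedure is
deterministic (no randomness) and equivariant under a common rigid motion of
both clouds, which is what the frame-invariance tests rely on.

## Segmentation strategies

* **M2 / M3 (gingival reduction)** operate on tissue labels: M3 keeps exactly
  the tooth-labeled points; M2 additionally keeps gingiva points within
  `margin_offset` (default 0.5 mm) of any tooth point — the two differ only
  in the extent of soft-tissue removal, since the proprietary behaviour of
  semi-automatic tools is unobservable. Label-based reduction (rather than
  curvature-based margin detection) is used because ground-truth labels exist
  for the synthetic data; margin detection on real unlabeled scans is a
  non-goal.
* **M4 / M5 (planar slice)** cut with an oriented plane; points with
  non-negative signed distance are kept, and points exactly on the plane are
  retained (one fixed convention, tested). The plane is the least-squares
  plane of the cloud, its normal flipped toward the side holding the tooth
  point mass (fallback: the skewed side of the height distribution), then
  translated to the mean tooth–gingiva boundary height minus `plane_drop`
  (default 0 — keeps interdental papillae). Real operators place this plane
  by eye on anatomical landmarks; the deterministic rule plus an explicit
  jitter knob (`plane_jitter_sd`, a standard deviation in both mm of offset
  and degrees of tilt) stands in for that, and the jitter stream is what
  replicate/session/operator structure perturbs.
* **M5** registers the untrimmed clouds first, maps PM into the AM frame,
  fits **one** plane to the superimposed union, slices both clouds with it,
  and returns PM in its native frame. The secondary registration is
  warm-started from the recorded initial transform, mirroring the sequential
  workflow; because PM is restored to its own frame, the second registration
  is a genuine re-registration rather than a no-op. The joint plane is chosen
  in the AM frame; both this and the warm start are configurable decisions,
  since the underlying workflow does not pin them down. M4 places planes
  independently per image — that independence is precisely what
  distinguishes it from M5.

## Synthetic dentition generator

The generator emulates the study conditions: six participants, upper and
lower full arches, each captured directly (AM) and through an
impression/stone-cast chain (PM) — 24 scans.

Arch geometry: 14 superellipsoid crowns (second molar to second molar, FDI
numbering) placed along a parabolic arch curve by width-proportional arc
spacing, embedded 1.2 mm into a continuous gingiva ridge that descends
`gingiva_band_height` (5 mm) below the margin, with 0.9 mm interdental
papillae. Tooth widths and crown heights follow per-tooth-type factors. The
template deliberately carries a fixed 4% left/right width asymmetry: real
dentitions are not mirror-symmetric, and a perfectly symmetric template makes
the mirrored superimposition nearly as good as the true one, which no
registration algorithm could be expected to disambiguate.

Individuality comes from per-participant jitter (`shape_jitter`, default
0.05 ≈ 5% relative s.d.) on crown dimensions, placement, superellipsoid
exponent, a zero-mean quadratic surface modulation of each crown, and slow
undulation of the gingival margin. This is what makes different participants'
arches separable by surface comparison.

AM→PM degradation (defaults):

| parameter | default | meaning |
|---|---|---|
| `noise_sd` | 0.05 mm | i.i.d. vertex noise (capture/cast surface error) |
| `deform_amplitude` | 0.2 mm | bound on a smooth low-frequency deformation field (3 sinusoidal modes per axis; casts distort smoothly, not per-vertex) |
| `deform_wavelength` | 25 mm | spatial scale of that field |
| `gingiva_extra_sd` | 0.1 mm | extra noise on gingiva at the margin crest |
| `mucosa_gradient` | 2.0 | linear growth of the extra gingiva noise with depth below the margin (0.1 mm at the crest → 0.3 mm at the band bottom) |
| rigid offset | ≤30°, ≤20 mm | random placement; inverse returned as ground truth |

The depth-graded gingiva noise encodes that firmly attached marginal gingiva
is far more reproducible than mobile alveolar mucosa; it is the mechanism
that makes soft-tissue removal help, and it is what separates the unsegmented
control (M1) from every segmented method. The degradation assumes the
generator's frame convention (occlusal = +z) since it is applied before the
rigid placement.

No quantitative AM-vs-PM capture error is published for intra-oral scanners
against cast scans; these magnitudes are chosen to be plausible for modern
devices and are all config-exposed. They reproduce the qualitative RMS
structure (separation of matching and non-matching distributions), not any
particular instrument's error budget.

## Study pipeline

Pairings per arch with n participants: n matching (AM_i vs PM_i) and
n(n−1)/2 non-matching (AM_i vs PM_j, i<j) — never AM vs AM, mirroring the
forensic AM/PM asymmetry. Each cell of (pairing × method × replicate ×
session × operator) derives its random streams from a stable blake2s hash of
its coordinates plus the design seed, so cells are independent, replayable
in isolation, and order-independent. Replicates, sessions and operators
perturb *only* the plane-jitter stream: cloud sampling and ICP subsampling
are fixed per pairing, so replicate scatter isolates the segmentation step —
consequently the label-based methods (M2/M3) repeat exactly (SD = 0) and all
replicate variance of the planar methods is operator-model variance. The
total comparison count is left as an explicit product of design multiplicities
rather than a hard-coded constant, because the multiplicities are the design.

Each scan is sampled to 40,000 cloud points by default. Denser clouds reduce
the nearest-neighbour discretization floor (≈ 0.5/√density mean NN distance),
which would otherwise mask the millimetre-scale tissue effects; 40k points
puts the floor near 0.14 mm at full-arch area, small enough for the method
ordering to be stable while keeping a full 6-participant, 5-method study in
minutes on one CPU. The end-to-end tests and the acceptance script run the
6-participant design at ICP `sample_size` 5000 for the same reason.

## Decision statistics

On separable data the logistic MLE for the match/non-match threshold
diverges, so separation is detected explicitly (`max(matching) <
min(non-matching)`): the reported cutoff is then the midpoint of the gap and
the result is flagged `separable`, rather than reporting a numerically
unstable coefficient ratio. On overlapping data the midpoint mode returns the
accuracy-maximizing threshold (ties to the smaller value) and the logistic
mode the probability-0.5 point of an IRLS fit. The classification boundary
convention is fail-safe: `rms == cutoff` is a non-match.

Box-Cox power selection maximizes the profile log-likelihood (including the
Jacobian term `(λ−1)Σlog x`) over λ ∈ [−3, 3] in 0.01 steps. The selected λ
is scale-invariant (rescaling the data shifts the log-likelihood by a
λ-independent amount), which is tested exactly.

Pairwise method comparisons use Welch two-sample tests on cell means with
Bonferroni multiplication, separately within matching and non-matching
strata, at the documented α = 0.05. Mixed-effects marginal means are out of
scope by design; the CSV schema is arranged so external tools can fit them.

## What passing tests show — and what they do not

The synthetic cohort demonstrates that the pipeline *mechanics* reproduce the
expected structure: segmentation lowers matching RMS, matching and
non-matching RMS distributions separate completely for segmented methods, a
single threshold classifies perfectly, and plane jitter widens the planar
methods' replicate scatter relative to manual reduction. It does **not**
validate the method on real dentitions: the generator's crowns are smooth
superellipsoids without occlusal anatomy, restorations, wear, or pathology;
AM and PM scans share identical capture extent; arch-level deformation is a
benign sinusoid; and inter-participant differences are parametric jitter
rather than biological variation. Absolute RMS values and any fitted cutoff
are therefore properties of the simulation settings, not forensic reference
values.

## Other numerical choices

* STL vertices are merged at 1e-9 mm into a canonical lexicographic order so
  label sidecars align deterministically across write/read; binary STL
  stores float32, which bounds round-trip fidelity to ~4e-6 mm at arch-scale
  coordinates (ASCII is exact).
* Surface samples inherit the tissue label held by a majority of their
  face's vertices; three-way ties resolve to OTHER (never invent TOOTH).
* Degenerate inputs fail loudly: collinear point sets in the rigid fit,
  empty clouds after segmentation, all-degenerate faces in sampling,
  non-positive values in Box-Cox.
* Units are millimetres everywhere; STL carries no unit metadata, so the
  convention is documented rather than detected.
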
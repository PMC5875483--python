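# Methods

## The measurement problem

A CT simulator couples four components whose horizontal orientations must
agree: the flat tabletop, the couch longitudinal travel direction, the
imaging (axial) plane, and the external axial lasers. Three signed angles
describe the possible disagreements, all positive clockwise in the
bird's-eye view of the room:

* **A** — couch travel direction vs. the imaging-plane normal;
* **B** — tabletop longitudinal axis vs. couch travel direction;
* **C** — the plane defined by the external axial lasers vs. the imaging
  plane.

The probe is a rigid cross phantom: two perpendicular aluminum arms with
small radio-opaque spheres (1.5 mm diameter) embedded along them — 23 on the
longitudinal arm (including the shared central marker) and 11 on the
transverse arm, with end markers 200 mm from the centre. Two scans suffice:
one with the phantom clamped to the tabletop (*table* mode, measures A and
B) and one with the transverse arm aligned to the axial lasers (*laser*
mode, measures A and C).

## Forward model

During an axial acquisition the phantom is carried along the couch
direction `u = (sin A, 0, cos A)`. A lab point `p` crosses the fixed imaging
plane `Z = 0` at couch displacement `−p_z / cos A`, so its recorded volume
position is

```
( p_x − p_z·tan A,  p_y,  s0 − p_z / cos A )
```

an affine map combining an in-plane shear with a longitudinal stretch. On
the coronal reconstruction (image-horizontal × longitudinal axes) the arms
therefore appear at apparent angles `φ` (longitudinal arm vs. the vertical
image axis) and `θ` (transverse arm vs. the horizontal axis), clockwise
positive. Writing `γ` for the angle of the longitudinal arm to the
imaging-plane normal (`γ = A + B` in table mode, `γ = C` in laser mode —
aligning to the lasers pins the phantom in the room, independent of the
couch):

```
tan φ = sin(γ − A) / cos γ        tan θ = sin γ / cos(γ − A)
```

which linearizes for small angles to

```
table:  φ = B,      θ = A + B
laser:  φ = C − A,  θ = C
```

so in both modes `A = θ − φ`. The inter-arm angle on the coronal view is
`90° − |A|` to first order: a couch-direction error visibly breaks the
phantom's right angle, while tabletop or laser errors rotate the whole
cross rigidly.

The "clockwise" conventions of the coronal view and of the bird's-eye view
are tied together by a single parity choice: the coronal vertical display
coordinate is the negated couch-readout coordinate (first-scanned slice at
the top). This choice is locked by the worked single-scan examples (couch
+2° must read `θ ≈ +2°`, lasers −2° with couch +2° must read `φ ≈ −4°`).

## Inversion

Both inversions are provided. The first-order inversion is algebraic
(`B = φ, A = θ − φ` / `C = θ, A = θ − φ`). The exact inversion solves the
two trigonometric relations for `(A, γ)` with a 2×2 Newton iteration seeded
from the first-order solution (tolerance 1e−10 rad, cap 50 iterations); it
round-trips the exact forward map to below 1e−8 degrees and differs from
the first-order form by at most ~0.005° inside the ±2° validation region.
Exact inversion is the report default because it costs nothing; the
difference is negligible at clinical misalignment magnitudes.

## Synthetic scans

`simulate_scan` renders the phantom into an axial volume through the affine
crossing map. Defaults reproduce the validation protocol: 50 cm field of
view, 512 matrix (~0.98 mm pixels), 1.25 mm slice thickness and increment.
Markers are rendered with partial-volume fractions obtained by 6×6×6
sub-voxel sampling through the inverse map; arms are solid boxes
(25 × 6 mm cross-section) rendered by voxel-centre membership; optional
additive Gaussian noise (clipped at −1024 HU) is seeded, and a fixed seed
reproduces the volume bit-for-bit.

**HU palette.** The palette is deliberately synthetic: background −1000,
arms +800, markers +20000, detection threshold +1500. A 1.5 mm sphere on a
~1 mm × 1.25 mm grid occupies at best ~2/3 of any voxel — and, centred on a
voxel corner, as little as ~19% — so with a physical marker HU (~3000) no
voxel would ever cross a threshold that also excludes the arms. The
saturating marker value keeps the worst-case diluted peak (~2900 HU at the
default matrix) safely above threshold while arms stay below it. The
palette and threshold are configuration, not physics.

**Supersampling default of 6.** At 3 sub-samples per axis the fraction
quantization alone leaves ~0.06–0.14 mm centroid error on 1.25 mm slices,
comparable to the entire noiseless error budget; 6 per axis reduces the
sampling share well below the inherent discretization bias at negligible
cost (marker bounding boxes are tiny).

**Matrix choice.** All full-scale validation runs use the 512 default. At
256 the 2 mm pixels both break detection (see above) and contribute ~0.04°
of centroid quantization over the 400 mm lever, a large share of the 0.07°
headline. A 512-matrix scan simulates, detects and fits in ~3–5 s, so the
full 32-scan battery completes in a few minutes on one CPU.

## Marker detection

Voxels at or above the threshold are grouped by 26-connectivity
(`scipy.ndimage.label`); components smaller than `min_voxels` are dropped
(default 1 — a well-centred 1.5 mm sphere at the default grid yields exactly
one supra-threshold voxel, and false positives are impossible with a
2500 HU gap to the arms at 10–50 HU noise). Each component's centroid is
the intensity-weighted mean of voxel-centre positions with weight
`max(HU − floor, 0)` taken over the component **dilated by one voxel**: the
dilation recovers the partial-volume tails, and the floor is estimated per
component as the median HU of a one-voxel shell around the dilated region
(the local base material — the arm for embedded markers, the background for
free-standing ones), which makes the weight exactly proportional to the
in-voxel marker volume fraction and the centroid invariant to sub-threshold
structures. A fixed floor can be passed instead; pure `HU − threshold`
weighting on the raw component (`weight_floor=None`) is biased toward the
brightest voxel's centre and can err by half a voxel for a sphere spanning
1–8 voxels.

The dominant remaining error is irreducible at fixed slice thickness: the
weighted mean assigns each slab its *centre* coordinate rather than the
centre of mass of the sphere section inside it, leaving a position-dependent
longitudinal bias of up to ~0.06 mm for a 1.5 mm sphere on 1.25 mm slices
(~0.017° over the 400 mm lever, and the reason the headline is quoted at
0.07° rather than at the numerical-noise floor). The closed-form worst-case
bound `atan(max(slice − diameter, 0) / lever)` quantifies the degenerate
regime where slices are thicker than the marker (0.14° at 2.5 mm slices).

## Orientation estimation

The centre marker is the centroid nearest the marker-cloud mean; remaining
markers are attributed to an arm by the angle of their coronal offset from
the centre, with offsets within 5° of the 45° bisector rejected as
ambiguous. By default only the five key markers (centre + four extremes)
enter the fits, mirroring the five-marker physical analysis; an all-markers
mode exists and is recorded in the report. Each arm line is fitted by total
least squares (SVD of centred coronal coordinates); the centre participates
in both fits and the two lines are not forced to intersect. Angles are read
off the fitted directions with `atan2` and the parity convention above.

Tolerance verdicts default to warn at 0.3° and fail at 0.5°; the underlying
protocol speaks in millimetres, so these are a site configuration, not a
standard. Baseline subtraction (`subtract_baseline`) removes a scanner's
inherent deviations angle-wise from a known-error measurement, as one does
when validating against deliberately introduced errors.

## Validation battery

`make_battery(m)` enumerates, per mode, the eight known-error scenarios:
secondary angle alone at ±m, couch angle alone at ±m, and the four
combined ±m/±m cases — 16 scenarios over both modes, run at both 2° and 1°
(32 scans). Per-scenario noise seeds derive from one master seed via
`numpy.random.SeedSequence([seed, index])`. With 10 HU noise the maximum
recovery error over all 32 scans and all angle types is ~0.02°, comfortably
inside the 0.07° headline; noiseless it is ~0.02° as well, reflecting the
slice-discretization floor discussed above.

## What the simulator does and does not emulate

It reproduces the geometry that the method measures: the crossing-time
shear/stretch, partial-volume rendering of small spheres on anisotropic
voxels, sub-threshold arm structures, and stationary Gaussian noise. It
does **not** model X-ray physics (beam hardening, scatter, reconstruction
kernels, metal artifacts), helical acquisition, couch sag, gantry tilt, or
in-plane image distortion. Passing the battery therefore demonstrates the
correctness of the angular model and of the detection/fitting chain under
ideal imaging; it does not bound the additional error a real scanner's
artifacts may contribute (the physical validation of the method itself
addresses that).

## Degenerate inputs and numerical choices

* States and apparent angles are rejected outside |angle| < 45°.
* Detection raises on an empty volume or when the threshold removes
  everything; the pipeline tags each failure with its stage.
* Collinear or coincident points in a line fit raise; arm assignment
  requires at least two points per arm including the centre.
* All angle interfaces are degrees; internals are radians.
* Voxel centres sit at `origin + index · spacing`; slices are ordered by
  increasing longitudinal coordinate; DICOM series are written head-first
  supine with deterministic content-derived UIDs.

## Known limitations

* The intermediate marker layout (18.18 mm longitudinal spacing; transverse
  markers at the ±40..±200 multiples of 40 mm plus one at +20 mm — eleven
  non-central markers cannot be placed symmetrically) is nominal; only the
  five key markers affect the orientation result.
* Vertical misalignment components, couch vertical travel, and gantry tilt
  are out of scope.
* The longitudinal-distance and image-scaling checks that the full marker
  complement supports are not implemented; the markers are rendered for
  realism and for the detection/accounting tests only.
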
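# Methods

This note documents the models, numerical choices and limitations behind
`ventriflow`. It is the package's own account of its science; every number
quoted here is computed by the test suite or `scripts/acceptance.py`.

## Data model and units

A dataset is a time-resolved three-directional velocity field on a regular
grid (internally `(n_frames, nx, ny, nz, 3)` in m/s), binary LV masks at
end-diastole (ED) and end-systole (ES) on the same grid, two valve planes
(point + unit normal in mm, normal oriented into the LV blood pool), and the
ED/ES frame indices. Voxel indexing is 0-based; physical coordinates are
voxel-center based, in mm. Internal units are SI (m/s, s, J); reports use ml,
mJ and µJ/ml.

The time axis is periodic: retrospectively gated cine reconstruction yields
one averaged cycle, so frame `n` wraps to frame 0 and a trace that runs
backward from ED through the reconstruction boundary simply re-enters the
same cycle. There is no separate "previous beat" data; the backward trace
integrates the same periodic field with reversed time.

Blood density defaults to ρ = 1060 kg/m³, is configurable everywhere
(`--rho`), and is recorded in the run log and in every `ComponentResult`.

## Preprocessing

**Background offsets.** One 3D polynomial of total degree ≤ 4 (35 monomials)
per velocity component is least-squares fitted to the *time-averaged*
velocity over static-tissue voxels, with coordinates scaled to [−1, 1] per
axis for conditioning, then subtracted from every frame. Fitting the temporal
average rather than per-frame offsets reflects that an eddy-current-style
background is one static offset field per component; the choice is exposed
through the model object should per-frame fitting ever be needed. A
static-tissue mask is normally supplied; `auto_static_mask` (lowest
percentile of temporal speed SD) is a fallback helper, and a supplied mask
always wins. Fewer static voxels than monomials raises a rank-deficiency
error instead of returning a silently under-determined fit.

**Phase unwrapping.** Aliased velocities are corrected by a temporal
algorithm: walking each voxel's time series, any inter-frame jump larger
than VENC is compensated by the nearest multiple of 2·VENC applied to the
later samples. VENC is the tightest threshold that cannot fire on valid
data, since a true difference can exceed VENC only via a wrap. The first
frame anchors each series (assumed unwrapped — at ED velocities are far from
VENC). A series needing more than `max_wraps` corrections (default 3) is
left at its original values and flagged unreliable: that many alternating
jumps in one averaged cine series is more plausibly noise than aliasing.
The cap is configurable for data with genuinely long supra-VENC excursions.
Preprocessing never alters grid geometry, timing or masks.

## Pathline engine

One pathline is emitted per ED-mask voxel center and integrated forward
through systole to the next ES and backward through diastole to the previous
ES — exactly one cardiac cycle per trajectory. Velocity is interpolated
trilinearly in space and linearly in time (periodic wrap); integration is
classical fixed-step RK4 with step = `step_fraction` × frame interval
(default ¼, i.e. 4 substeps per frame). Fixed-step RK4 with a frame-aligned
step keeps samples exactly on reconstructed frame times and makes the
integrator's 4th-order convergence directly testable (observed order ≈ 4.00
on the rigid-rotation phantom; endpoint error ~3×10⁻⁸ relative at the
default step).

Pathlines that leave the imaged volume are *frozen* at their last inside
position and flagged `left_fov`, never discarded: each pathline represents
one voxel volume of blood, and keeping frozen pathlines in the accounting is
what makes the component volumes sum exactly to the segmented EDV. The
flagged fraction is reported in QC. Non-finite velocities flag a pathline
`unreliable` the same way.

## Flow components, E/A split, QC

Endpoint membership in the ESV uses nearest-voxel lookup of the binary mask,
not interpolation: membership is then reproducible and fraction-free, and
sub-voxel sensitivity is covered by the phantom tolerance (the phantom
samples displacements away from half-voxel boundaries, so a verdict never
hinges on a 10⁻¹² coin flip).

Mid-diastasis is the diastolic frame interval `[t_k, t_k+1)` with the fewest
mitral-plane sign changes among inflow pathlines, ties broken toward the
earliest frame — a deterministic surrogate for what is otherwise a visual
call. The E-wave is the interval from diastole onset to the mid-diastasis
frame time; crossing times are linearly interpolated between the bracketing
trajectory samples, and a crossing exactly at the mid-diastasis time counts
as A (the late interval runs from mid-diastasis to ED). Inflow pathlines
with no detected crossing (possible with frozen or noisy traces, and for
blood already between the mitral plane and the ES cavity at the previous
ES) are assigned by their nearest-approach time to the plane and counted in
the QC report, preserving the invariant E + A = parent component.

The inflow–outflow check uses inflow = Direct Flow + Retained Inflow,
outflow = Direct Flow + Delayed Ejection Flow, and
discrepancy = |inflow − outflow| / mean(inflow, outflow) × 100. The
symmetric mean denominator avoids biasing the rule toward either direction
of mismatch; the 15 % threshold is configurable
(`qc_max_discrepancy_pct`).

## Energetics

Per-frame pathline speed is the interpolated *field* speed at the pathline
position (default), which uses the measured data directly and is more
noise-robust than differencing positions; trajectory differencing is
implemented as an alternative (`speed_source="difference"`) and the two are
compared in a property test. KE curves satisfy exact additivity (the four
primary components partition the total KE at every frame) and E/A
sub-additivity; both are enforced at 10⁻⁹ relative in tests. An empty
component reports volume 0, zero curves and KE/ml = 0 with an `empty` flag
(never NaN), keeping result tables rectangular.

## Group statistics

Normality is checked per group with a Kolmogorov–Smirnov test. Because mean
and SD are estimated from the sample, the Lilliefors-corrected variant is
used (a plain KS test against a fitted normal is anti-conservative); this
choice is recorded in the routing result. Both groups passing at α = 0.05
routes to an unpaired pooled-variance Student's t test (Welch available by
flag); otherwise Mann–Whitney U. Zero-variance samples are degenerate for
the normality test and route to Mann–Whitney with a flag. The t branch also
accepts printed summary statistics (mean, SD, n), which are sufficient for
it — the suite verifies raw-data and summary inputs give identical t and P.
P values format to three decimals, "<0.001" below that. Simple OLS
regression (slope, R², two-sided P) covers associations with QRS duration.
A Monte-Carlo calibration utility draws both groups from the same normal
and measures the realized type-I error of the whole routed procedure
(≈ 5 % at n = 11/group over 10,000 repetitions).

## The slab phantom: what it emulates, and what it does not

The slab phantom stands in for patient data: a spatially uniform, purely
axial velocity field u(t)·ẑ sampled at 40 frames over a 1 s cycle on a
2.8 mm isotropic grid with VENC 120 cm/s — the target acquisition's
geometry. The ED mask is an axial slab; the ES mask is a sub-slab sharing
the distal (aortic) face; the mitral plane sits at the proximal ES face,
the aortic plane at the distal face. The waveform has four segments
(systolic ejection, E-wave, zero-flow diastasis, A-wave) built from sin² or
trapezoid pulses whose segment durations are whole numbers of frames, plus
a residual end-diastolic speed (default 8 cm/s) so that pre-systolic KE is
non-trivial. The default configuration was sized so that Direct Flow,
Retained Inflow and Delayed Ejection Flow are all non-empty, Direct Flow
splits into E and A parts, and inflow equals outflow exactly (QC 0 %);
its EDV is ~27 ml — a miniature ventricle, chosen for test speed, since
none of the verified properties depend on absolute scale.

Two design points make the phantom an *exact* oracle rather than an
approximate one. First, the ground-truth velocity is defined as the
piecewise-linear interpolation of the frame samples — the same function of
time the tracer integrates — and RK4 with frame-aligned substeps integrates
a piecewise-linear integrand exactly, so pipeline trajectories agree with
the analytic displacement integrals to rounding error. Second, the truth
module classifies seeds by interval arithmetic on the slab boundaries
(closed form) and, independently, by per-voxel endpoint lookups against the
actual ES mask (brute force), sharing no code with the pathline engine or
classifier; the suite requires closed form = brute force = pipeline with
zero-voxel error on ≥ 20 randomized configurations.

Known consequences of the 1D uniform geometry, stated so that test results
are not over-read:

- Direct Flow and Residual Volume cannot both be non-empty in one
  configuration (total displacement is either larger or smaller than the ES
  slab length), and only one of Direct Flow / Retained Inflow straddles the
  E/A depth boundary per configuration. The randomized sampler covers both
  regimes.
- With zero flow everywhere, the endpoint definitions label stationary
  blood outside the ESV as Direct Flow; the all-Residual-Volume phantom
  therefore uses identical ED and ES masks.
- Inflow seeds lying between the mitral plane and the ES cavity never cross
  the plane and exercise the nearest-approach fallback; their fraction is
  visible in the QC report.
- The phantom has no chamber geometry, no transverse flow, no turbulence,
  no valve motion and no MR physics; passing these tests demonstrates the
  correctness of the analysis chain, not the fidelity of any scanner.

The rotation phantom (rigid-body v = ω × r about the grid axis) is linear
in space, so trilinear interpolation is exact and traced circles isolate
pure integrator error — it backs the convergence-order and reversibility
tests. `corrupt_field` injects, in order: a polynomial background offset
expressed in the same scaled monomial basis the fitter uses (so in-basis
offsets are recoverable to rounding), phase wraps by modular reduction into
(−VENC, VENC], and Gaussian noise with an explicitly recorded seed.
Wrap injection followed by temporal unwrapping is bitwise-identity on
noiseless data in the single-wrap regime, and is tested as such.

## Degenerate inputs and tie-breaks

- Empty ED mask, empty static mask, mismatched grids, non-monotone frame
  times: typed errors naming the offending item.
- No inflow pathlines: the E/A split is skipped with a warning; the four
  primary components are still reported.
- Mid-diastasis ties: earliest frame. Mitral-crossing at a sample with
  signed distance exactly zero: attributed to the interval ending at that
  sample.
- Identical constant groups in statistics: P = 1 with a degenerate flag;
  zero-variance QRS: an explicit error.

## Problem sizes

Default test problems use 4–8 voxel transverse extents and ≤ 80 axial
voxels (≈ 1–3 × 10³ pathlines, 160 RK4 steps each), which keeps a full
pipeline run under half a second and the whole suite under a minute while
exercising every code path; the engine itself is vectorized over pathlines
and handles clinical grid sizes (~10⁴ pathlines) without modification.
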
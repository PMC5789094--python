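# Methods

`nanocal` treats an ensemble of two-mark DNA-origami nanorulers, imaged by
DNA-PAINT single-molecule localization microscopy, as a traceable distance
standard.  The measurand is the ensemble-mean 2D-projected intermark
distance ā_proj; the package simulates the measurement, performs it, and
propagates a full GUM uncertainty budget for it.  This note records the
models, the defaults and why, the numerical choices, and what the synthetic
data can and cannot show.

## Measurement model

For a single ruler the projected distance is

    a_proj = P · (d + Σ_j δd_j)

with P the object-space pixel size (nm/pixel), d the measured distance
(pixels) and δd_j zero-expectation corrections (pixels) for fit error,
fit-model imperfection, blinking kinetics, environment and false-positive
picking.  Independence of the inputs gives

    u²(a_proj) = u²(P)·(d + Σδd_j)² + P²·(u²(d) + Σ u²(δd_j))

For the mean over n structures, contributions split by character: *random*
effects (per-structure distance scatter u(d_k), per-structure fit
uncertainty u(δd_fit,k)) enter as P·u/√n; *systematic* effects (environment,
blinking, picking bias, model) enter as P·u, unattenuated.  The pixel-size
row enters with sensitivity (d̄ + Σδd); since every correction has
expectation zero this is d̄ in practice.  The combined u is the quadrature
sum and the expanded uncertainty is U = k·u with k = 2 (≈95 % coverage).
Corrections are stored in pixels and contributions reported in nm.
Correlated inputs and effective-degrees-of-freedom coverage calculus are
out of scope.

Worked example (`nanocal.example_budget()`): u(P) = 0.5 nm/px,
u(d_k) = 0.05 px and u(δd_fit,k) = 0.0035 px random over n = 1000,
u(δd_env) = 0.005 px, u(δd_blink) = 0.001 px, u(δd_fp) = 0.009 px,
u(δd_model) = 0.005 px systematic, P = 100 nm/px, d̄ = 0.6 px.
Contributions: 0.30, 0.16, 0.01, 0.50, 0.10, 0.90, 0.50 nm; U = 2.4 nm.
Display rounding is 2 decimals for contributions and 1 for U; the
combination always uses unrounded values.

## Blinking-kinetics simulator

Each DNA-PAINT binding site is a two-state renewal process: exponential
dark dwells (mean `t_off`, imager association) alternate with exponential
bright dwells (mean `t_on`, duplex lifetime), starting dark.  Events are
discretized onto camera frames; a site ON for a fraction f of a frame emits
Poisson(`photons_per_frame`·f) photons, and frames below `min_photons`
(default 50, mirroring SMLM detection thresholds) yield no localization.
Emitters simultaneously ON within `merge_radius` (default 2.5·σ_PSF) of one
another fuse into a single localization at their photon-weighted centroid —
the mechanism by which a high t_on/t_off duty cycle systematically shortens
measured distances.  Localization noise is isotropic Gaussian with
σ = σ_PSF/√N; background and pixelation excess noise are deliberately not
modelled (a config hook is left for a background term).  Linear drift
(nm/h) and uniform false positives (per µm² per frame) are optional.

Defaults and rationale (all changeable per `SimConfig`):

| parameter | default | why |
|---|---|---|
| t_on | 0.2 s | short imager duplex lifetime typical of 8–9 nt imagers |
| t_off | 200 s | gives duty cycle 1·10⁻³, the low-merging DNA-PAINT regime |
| frame_time | 0.1 s | common EMCCD integration time |
| n_frames | 10 000 | ≈17 min acquisition; ~90 localizations per mark |
| photons_per_frame | 400 | ≈5 nm localization precision at σ_PSF = 100 nm |
| σ_PSF | 100 nm | NA ≈ 1.4 objective, red emission |
| pixel_size | 100 nm/px | typical calibrated EMCCD object-space pixel |
| site layout | 3×3 grid, 5 nm pitch | nine docking protrusions per mark |
| site_activity_prob | 0.85 | realistic staple incorporation efficiency |
| true_distance_mean | 60 nm | the long-ruler design class |

The per-ruler random substreams are derived from the master seed with fixed
spawn keys, so enlarging `n_rulers` never reshuffles existing rulers, and
identical configs are byte-identical after serialization.

## Structure picking and distance fitting

Candidates come from DBSCAN (radius 90 nm = 1.5× nominal distance, 10
neighbours minimum), then pass filters in fixed order: localization count →
radius of gyration → bimodality (first-to-second principal-variance ratio
≥ 3) → field-edge margin; the first failed filter is recorded.  The filters
stand in for the "looks like a nanoruler" heuristics of interactive
analysis software, whose exact criteria are not public.  The picking-bias
uncertainty u(δd_fp) is estimated as the absolute difference of ensemble
means under two picking configurations (a permissive automated arm and a
strict manual-like arm); true interactive picking is out of scope.

Per candidate, the principal axis of the localization second-moment tensor
defines the projection direction (sign fixed so μ₁ < μ₂, angle reported in
[0, π)); a 1D equal-variance two-component Gaussian mixture is fitted by
EM (percentile initialisation, log-likelihood tolerance 10⁻¹²), points
farther than 3σ from both components are excluded once and the fit is
repeated.  d_k = μ₂ − μ₁; u_fit = σ·√(1/n₁ + 1/n₂) from the effective
component counts.  Fits with a component below the minimum mark count or
with μ₂ − μ₁ < 2σ (a single cloud splits into a spurious ~1σ separation
under maximum likelihood) are flagged failed and excluded from the
ensemble.  The equal-variance projected mixture is the documented model
choice; it is isolated behind `fit_two_marks` so a 2D mixture or another
refinement can be swapped in without touching the rest of the pipeline.

The blinking-bias curve (`estimate_blink_bias`) reruns the full
simulate→pick→fit pipeline over a grid of t_on/t_off ratios with fixed
per-point seeds.  All kinetic and geometric parameters except t_off are
held fixed; the acquisition length is scaled with the renewal period
t_on + t_off so the expected binding-event count per site — and hence the
localization statistics — is constant across the grid and only the
simultaneous-emission probability varies.  Without this scaling the
localization count would change ~1000-fold over the grid and confound the
duty-cycle effect with counting statistics.

## Pixel-size calibration

A stage-micrometre grating (10 µm nominal pitch) is imaged; columns are
averaged over a row band, each valley centre is refined by a 3-point
parabola, and per-interval pixel sizes P_i = L_ref,i/Δc_i are averaged.
u(P) combines three separately reported components: (a) the calibrated
reference-pitch uncertainties (expanded k = 2 values halved to standard,
independent between intervals, each entering the mean with sensitivity
1/n); (b) the scatter of the P_i as a field-variation/distortion term —
deliberately *not* divided by √n, because optical distortion makes the
local magnification position-dependent and a measured structure may sit
anywhere in the field (the distortion is treated as an uncertainty, not
corrected); (c) the sub-pixel line-centre uncertainty estimated from
row-to-row scatter.  The synthetic grating generator imposes distortion as
a smooth linear magnification gradient normalised so the relative standard
deviation of interval pitches equals the `distortion` parameter; its
default edge blur (800 nm) and pixel noise (100 counts) emulate the weakly
defined chrome edges of an inexpensive micrometre.  A 0.5 % distortion
yields ≈1 % expanded relative uncertainty, dominated by the
field-variation term.

## Two-colour registration and its evaluation

The green channel maps to red through x_r = a·x_g + b·y_g + c,
y_r = d·x_g + e·y_g + f, solved from matched bead centroids — exactly for
three non-collinear beads, by least squares for more (the overdetermined
behaviour is our choice; the determined solve is the classical one).
Quality over the field of view is judged from the correlation image (the
element-wise product of 10 nm-binned channel renderings, so uncorrelated
regions multiply to zero) summed in non-overlapping 1.6 × 1.6 µm² tiles
anchored at the origin with partial edge tiles dropped, normalized to the
maximum tile.  The uniformity statistic is the coefficient of variation of
the raw tile sums, compared against the structure-counting expectation
1/√(structures per tile): a valid correction is uniform within that noise;
a mis-registration shows as depressed or structured tiles.  Localization
*counts* (not rendered 8-bit intensities) feed the product — a dialect
choice, flagged here.

## Drift and resolution benchmarking

Drift is estimated by windowed centroids (default 500-frame windows): each
tracked structure's per-window centroid is taken relative to that
structure's own overall centroid, and windows are combined across
structures weighted by localization count.  The relative-centroid step is
essential — a global centroid of a many-structure field carries the
structure-position spread (~µm) into the estimate, whereas relative
centroids leave only localization noise, reaching the sub-0.5 nm floor
with a few constant fiducials.  The per-frame correction is linearly
interpolated between window midpoints and subtracted; the linear drift
rate (nm/h) is a least-squares slope with standard error.  Resolution is
read from rendered-image cross-sections: the intensity profile along a
segment (perpendicular averaging over a configurable width) is scanned for
peaks, each fitted with its own Gaussian-plus-offset, and
FWHM = 2√(2 ln 2)·σ is reported from the fitted σ, not from half-maximum
crossings.

## What the synthetic data does and does not show

The generator reproduces the features that drive the uncertainty budget:
renewal blinking with a controllable duty cycle, photon-limited
localization noise, simultaneous-emitter merging, labeling efficiency,
false positives, linear drift, and ruler-to-ruler structural variation
(Gaussian-distributed true distance — "inhomogeneous broadening").  With a
fixed true distance the fitted ensemble SD is ~1–2 nm, set purely by
counting statistics; adding a 4 nm structural spread reproduces the 4–5 nm
ensemble SDs typical of real samples, and the two variances add.  Not
modelled: EMCCD noise cascades, non-Gaussian PSFs, axial (z) effects and
tilt/bending of the origami, salt/temperature distance dependence (carried
only as the fixed δd_env uncertainty term), pixel-sensitivity variation,
and raw-movie rendering at experimental scale.  Passing tests therefore
demonstrate the correctness of the analysis chain and the propagation
arithmetic under the stated model, not hardware performance; measured
distances and pixel sizes of specific instruments are outside what
simulation can certify.

## Problem sizes used in the test suite

The suite runs the full pipeline at sizes chosen to keep Monte-Carlo error
well below the asserted tolerances: 1000 rulers for mean recovery (SE
≈ 0.06 nm against a 0.5 nm band), 150–300 rulers per duty-ratio grid point,
300 rulers per arm for variance addition, 20 seeded repeats for the
coverage check of U, and 500 seeded repeats for the 3·u_fit coverage of the
mixture fit.  A 6 h acquisition is simulated in full (43 200 frames at
0.5 s) for the resolution benchmark; event-driven simulation makes this
cheap because only frames with an active binding event are touched.
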
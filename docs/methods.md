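# Methods

## The capillarity model

A liquid-like tissue aggregate resting on a non-adhesive substrate under
gravity adopts an equilibrium shape set by the balance of surface tension
and hydrostatic pressure. With `z` the depth below the apex, the pressure
jump across the tissue–medium interface is `ΔP(z) = 2γ/R0 + Δρ·g·z`
(`R0` the apex radius of curvature, `Δρ` the tissue-minus-medium density
difference), and the Young–Laplace balance `ΔP = γ(1/R1 + 1/R2)` yields
the Bashforth–Adams arc-length system

    dx/ds = cos θ,   dz/ds = sin θ,
    dθ/ds = 2/R0 + (Δρ·g/γ)·z − sin θ / x,

with apex conditions `x(0) = z(0) = θ(0) = 0` and the umbilic limit
`sin θ/x → 1/R0`. The apex is a removable singularity; we step off it
with the series `θ = u + Bo·u³/8`, `x = R0(u − u³/6)`,
`z = R0·u²/2 + …` (u = s/R0, valid to O(u⁵)) at `u = 10⁻⁴` and hand the
state to an adaptive 8th-order Runge–Kutta (DOP853, relative tolerance
1e-9 by default) integrated in units of `R0`, so only the Bond number
`Bo = Δρ·g·R0²/γ` enters and scale equivariance is exact. Integration
stops at `θ = π` or a configurable arc-length cap; the step size is
bounded so the terminal event cannot be jumped at the `θ → π`, `x → 0`
closure of the spherical limit.

Two consequences of this parametrization worth stating explicitly:

- At `Bo = 0` the profile is a sphere and the shape carries **no**
  information about tension — this motivates the identifiability flag in
  the fitting stage.
- At fixed `R0`, increasing `Bo` makes mean curvature grow faster with
  depth, so the profile curls in sooner: the equator-to-apex-radius
  ratio *decreases* monotonically with `Bo` (0.98, 0.89, 0.70 at
  Bo = 0.1, 1, 5). "Gravity flattening" refers to the aspect of the
  whole drop, not to this ratio.

An independent classical fixed-step RK4 integrator
(`integrate_profile_fixed_rk4`) is kept alongside the adaptive path as a
cross-check; the two agree in equatorial radius to ~1e-11 relative.

## ADSA fitting

Tension is estimated by minimizing the mean squared nearest-point
distance between the observed outline and the mirrored theoretical
profile over `(log Bo, log R0, x0, z0)` (optionally tilt) with
Nelder–Mead, three starts bracketing an apex-curvature (Kasa circle fit)
estimate of `R0`. Fitting `(Bo, R0)` instead of `(γ, R0)` decorrelates
shape from scale; the tension follows as `γ = Δρ·g·R0²/Bo`. Distances
use a dense fixed-step RK4 sampling of the theoretical curve (step
0.005·R0, global error ~1e-9·R0) with a KD-tree vertex query refined
against adjacent segments.

Numerical choices:

- **Identifiability**: fits with recovered `Bo < 0.05` are flagged; below
  this the gravity deformation is beneath typical contour noise and the
  returned γ is reported as unconstrained. The flag trips for all
  synthetic contours generated with `Bo < 0.05` and stays clear above
  `2×` the threshold.
- **Substrate band**: contour points within 2 % of the profile height of
  the maximum depth are excluded from the objective. Rendered or imaged
  sessile drops terminate on a substrate chord that the free-surface
  model does not describe; the band removes it without measurably
  affecting contours that have no chord.
- **Tilt** is off by default (profile images are acquired level); a
  config switch enables it.
- `Δρ` is a required input everywhere. The tissue density is external
  knowledge (for *Xenopus* gastrula tissue the aggregate–medium
  difference is of order tens of kg/m³); no default is supplied, and the
  same `Δρ` is used for deep-tissue/epithelium interfacial fits unless
  the caller supplies an effective interface value.

Recovery performance under the synthetic generator: noise-free contours
over `Bo ∈ [0.2, 5]` return γ within 0.005 % (optimization-limited, far
inside the 0.5 % design target); at 1 % radial noise with 200 points the
median |error| over 20 seeds is ~1.2 % with median signed error ~−1 %
(slight low bias: noise inflates apparent flattening).

## Contour extraction and QC

Confocal stacks (slices typically 10 µm apart) are max-projected.
Extraction: Gaussian smoothing → Canny edges with automatic thresholds
(50th/90th percentiles of the *significant* gradient magnitudes, i.e.
those above 10 % of the robust peak — percentiles over all gradients
collapse onto sensor noise) → dilation, hole filling, erosion (seals
small gaps in the edge ring without net boundary displacement) → largest
region → subpixel iso-contour of the smoothed intensity at the midpoint
between object and background levels. The mask only localizes the
object; tracing the intensity mid-level avoids the ~edge-width boundary
bias a mask contour would carry.

QC operationalizes the rejection of aggregates too irregular to be drop
shapes: circularity `4πA/P² ≥ 0.6` and convexity deficiency
`1 − A/A_hull ≤ 0.15` (both configurable), closedness, and a
self-intersection check. These thresholds pass gravity-flattened drops
(circularity ~0.8–0.95 across Bo 0.5–2) and reject star-like or deeply
lobed outlines. They are an explicit automated stand-in for manual
inspection, not a reconstruction of it.

## Plate tensiometry and push-back analysis

The compression tension formula
`σ = F / (π·R3²·(1/R1 + 1/R2) − 2π·R3·sin A)` is evaluated with the
force reading after 3 min of stress relaxation (config constant). `R1`
is taken as the equatorial profile radius and `R2` the meridional radius
at the equator; the formula is symmetric in `1/R1 + 1/R2`, so the
assignment is immaterial and a config switch swaps them for sensitivity
analysis. A non-positive denominator (contact term dominating) raises a
geometry error. Strain `(h0 − h)/h0` is flagged `below_protocol` under
18 % and `solid_like_regime` above 22 %, where measured tension rises
suddenly and stops reflecting interfacial physics.

Push-back traces (platen held fixed after a 0.2–0.3 µN preload) are
decomposed as: moving-median smoothing (5 samples) → exponential fit
`a·exp(−t/τ) + b` to the early decay, relaxation ending when the fitted
transient falls below half the noise SD → plateau = median over the
following 20 min → onset = first sustained (10 min) excursion above
`plateau + 3·SD`, refined by intersecting a line fit of the early ramp
with the plateau level (removing threshold-crossing lag). The noise SD
comes from the median absolute first difference of the raw trace. The
force increase over 30 min is reported both from detected onset and from
the start of the trace, since either convention is defensible. The
k·SD sustained-excursion rule is this module's explicit
operationalization of onset scoring; nothing finer is implied by the
underlying assay.

## Morphometrics

Convergence is quantified as the width ratio `W_t/W_i` of paired
boundary points (Euclidean separation; measurements are made on 2-D
projections of approximately flat explants). **Rates in "% per hour" are
the OLS slope of `W_t/W_i` versus time × 100** — i.e. percent of
*initial* width per hour, positive = convergence. Relative-to-current-
width rates differ by <1 % over 2 h windows at these magnitudes, but the
conventions are not identical; the linear-in-ratio choice matches how
the ratio series are plotted and generated.

Changepoints use a continuous two-segment piecewise-linear (hinge) fit
with exhaustive search over interior sample points; a breakpoint is
reported only when it beats a single line by an F-criterion (default
F ≥ 10 with (2, n−4) df; a numerically perfect single line short-
circuits to "no changepoint").

Projected areas of regions concentric about the viewing axis of a
spherical embryo are corrected to true spherical-cap areas:
`θ = arcsin(r_proj/R)`, `A_true = 2πR²(1 − cos θ)`, annuli as cap
differences (hemisphere ratio exactly 2, vanishing caps → 1). The
polar-cap construction is this module's reconstruction of "corrected for
spherical geometry"; regions far from the viewing axis would need a
different treatment.

Cell-shape metrics use polygon formulas (shoelace area, perimeter,
circularity), a second-moment equivalent ellipse for the length–width
ratio, and centroid displacement for movement rate. Group summaries are
arithmetic mean, SEM = sd/√n (n−1 sd), and the classic pooled-variance
unpaired two-tailed t-test (Welch available by switch).

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions for validation:

- **Drop contours/images**: tension 0.22 mN/m, `Δρ = 50 kg/m³`, apex
  radii of a few hundred µm (Bond numbers 0.2–5 span usable flattening);
  radial noise applied normal to the curve so that its magnitude reads
  directly as contour roughness; images rendered as blurred silhouettes
  (2 px blur, 1 % pixel noise).
- **Push-back traces**: preload 0.25 µN, relaxation amplitude 0.1 µN
  with τ = 60 s, ramp 1.7e-10 N/s (≈0.3 µN per 30 min), sampled at 10 s
  over 3 h with 5 nN force noise (~2 % of preload).
- **Tracks**: IMZ at 10 %/hr throughout; NIMZ at 7 %/hr slowing to
  0 %/hr at −0.7 h relative to gastrulation onset; 1 mm initial widths,
  one frame per 3 min, 5 µm positional noise.

No noise magnitudes accompany the original recordings, so the values
above are calibration choices, set once at what experienced
microscopy/tensiometry practice would call realistic and not tuned
thereafter. The generators reproduce the *statistical structure* the
analyses assume — not tissue mechanics, cell behavior, or embryo
geometry. Passing recovery tests therefore demonstrates that the
analysis stack is correct and well-conditioned at realistic scales and
noise levels; it does not validate the biological model against real
images, and real aggregate outlines (irregularity, debris, uneven
illumination) are harsher than the synthetic ones (the QC gate exists
for exactly that reason).

## Known limitations

- The ADSA and plate-compression paths are independent measurements and
  are reported separately; no attempt is made to reconcile systematic
  scale differences between them (measured tensions from the two methods
  are known to disagree by large factors on real tissue).
- No pendant-drop branch and no liquid-bridge shape solver: plate
  compression is analyzed algebraically, not by shape integration.
- Point tracking is assumed done upstream (tracks arrive as tables).
- The changepoint model allows exactly one break; multi-phase series
  need windowing by the caller.
- Problem sizes in the validation suite (20 seeds per Monte-Carlo check,
  200-point contours, 3 h traces) were chosen as the smallest giving
  stable statistics for the recovery criteria.
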
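# tensiomorph

Tissue tensiometry and time-lapse morphometrics for studying **convergent
thickening (CT)** — the isotropic mediolateral convergence and radial
thickening of the involuting marginal zone (IMZ) that helps close the
blastopore in amphibian gastrulae. The working model is that CT is driven by
a rise in the interfacial tension between the deep IMZ and its overlying
epithelium; this package implements the measurement stack needed to test
that model quantitatively:

- **Young–Laplace forward model** (`tensiomorph.laplace`): integrates the
  axisymmetric Bashforth–Adams system
  `dx/ds = cos θ`, `dz/ds = sin θ`, `dθ/ds = 2/R0 + (Δρ·g/γ)·z − sin θ/x`
  from the drop apex, so that the pressure balance
  `ΔP0 + Δρ·g·z = γ(1/R1 + 1/R2)` holds pointwise along the profile. The
  dimensionless Bond number `Bo = Δρ·g·R0²/γ` controls gravity flattening.
- **Axisymmetric drop shape analysis** (`tensiomorph.adsa`): estimates
  tissue surface tension (TST) or interfacial tension (IFT) by fitting
  theoretical profiles to an aggregate outline, minimizing squared
  nearest-point distances over `(Bo, R0, apex position)` and converting
  `γ = Δρ·g·R0²/Bo`. Near-spherical shapes (`Bo` below a threshold) are
  flagged *unidentifiable*: a sphere carries no tension information.
- **Contour extraction** (`tensiomorph.extraction`): max-intensity
  projection of small confocal stacks, Gaussian smoothing, Canny edge
  detection, subpixel outline tracing, and shape QC (circularity,
  convexity deficiency) standing in for the by-eye rejection of irregular
  aggregates.
- **Parallel-plate tensiometry** (`tensiomorph.plate`): the
  compression-geometry tension formula
  `σ = F / (π·R3²·(1/R1 + 1/R2) − 2π·R3·sin A)` (force read after 3 min of
  stress relaxation; 18–22 % strain protocol), and push-back
  (thickening-force) trace analysis: stress relaxation → plateau → force
  ramp, with sustained-excursion onset detection.
- **Force model** (`tensiomorph.force`): the line-tension prediction
  `F = σ_em · L_i` — interfacial tension acting over the traced interface
  contour length in a cross-section.
- **Morphometrics** (`tensiomorph.morpho`): regional width/thickness/area
  ratios (`W_t/W_i`, `T_t/T_i`, `A_t/A_i`) from fiduciary-point tracks,
  convergence rates in %/hr, two-segment changepoint detection,
  spherical-cap area corrections, blastopore closure (`A_bp/A_we`),
  cell-shape metrics, and group summaries (mean, SEM, unpaired two-tailed
  t-test).
- **Synthetic data** (`tensiomorph.synthetic`): generators for every input
  the pipeline consumes — drop contours and rendered images of known
  tension, push-back traces of known onset, and track tables with known
  rate regimes (IMZ ~10 %/hr; NIMZ ~7 %/hr slowing to ~0 %/hr) — so every
  stage is validated by parameter recovery.

## Worked example

Generate a synthetic gravity-flattened aggregate contour (γ = 0.22 mN/m,
Bo = 1, 1 % radial noise) and recover its tension:

```bash
$ tensiomorph synth drop --bond 1.0 --noise 0.01 --seed 3 --out drop.csv
$ tensiomorph adsa fit --contour drop.csv --delta-rho 50
{
  "gamma_N_per_m": 0.0002150817834257421,
  "R0_m": 0.0006731455263887466,
  "bond_number": 1.033011077655854,
  "rms_residual_m": 6.85011971823618e-06,
  "identifiable": true,
  "converged": true,
  ...
}
```

The fit returns 0.215 mN/m against a generator truth of 0.22 mN/m (−2.2 %
at this noise level), a Bond number near 1, and an RMS contour residual of
~7 µm (the 1 % radial noise on a ~670 µm apex radius). `identifiable: true`
says the shape was flattened enough for the tension to be constrained.

The line-tension force prediction at the measured scale — an IFT rise of
0.22 mN/m acting over a 1.2 mm interface contour:

```bash
$ tensiomorph force predict --sigma 0.22e-3 --length 1.2e-3
{"sigma_em_mN_per_m": 0.22, "L_i_mm": 1.2, "F_uN": 0.26}
```

i.e. a predicted convergence force of 0.26 µN, the same order as forces
measured directly by tensiometry (~0.3 µN). Plate compression:

```bash
$ tensiomorph plate sigma --force 0.5e-6 --r1 250e-6 --r2 80e-6 --r3 150e-6 --angle 60
{"sigma_N_per_m": 0.001428136627316322, "sigma_mN_per_m": 1.4281366273163218}
```

The full synthetic demo pipeline (image → contour → fit; trace → onset;
tracks → rates; tension → force) runs with
`tensiomorph run --delta-rho 50 --seed 1 --out demo_out`.

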
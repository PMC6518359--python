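# Methods

## Phantom model

The image-quality phantom is a 30 mm diameter cylinder with three axial
sections:

- **Rod section** (20 mm): five fillable rods of 1-5 mm diameter at a
  7 mm pitch radius, hot rods in a cold solid body. The 1 mm rod is below
  the default voxel size and is flagged as sub-resolution rather than
  silently dropped.
- **Uniform section** (30 mm): uniformly filled.
- **Cold chambers**: two cylinders (8 mm inner / 10 mm outer diameter,
  15 mm long), one air- and one water-filled, centered at +/-7.5 mm in the
  top 15 mm of the uniform section.

Total activity is 3.7 MBq; the fill concentration is total activity
divided by the analytic fillable volume. Activity voxelization uses
fractional coverage (4x4 in-plane subsampling times exact axial-interval
overlap), which conserves total activity to 0.02% on the default grid;
label and attenuation maps use voxel-center membership. Attenuation is
water (0.0096/mm at 511 keV) in filled regions and the water chamber, zero
in air. The default grid is 128x128x159 at 0.776x0.776x0.796 mm; studies
run on a cropped 48x48x63 grid at the same voxel size.

## Projector, contamination, sampling

A pixel-driven parallel-beam projector with linear bin splatting is built
as a sparse matrix per (grid, geometry) pair; back-projection is its exact
adjoint. Line integrals are in mm so projections of concentration have
units concentration x mm. The default geometry uses 192 angles over 180
degrees (divisible by the 16 OSEM subsets) and bin width equal to the
voxel size.

Attenuation multiplies each ray by `exp(-integral of mu)` computed with
the same projector. Scatter is modelled as a Gaussian convolution of the
true sinogram along the bin axis (20 mm FWHM default), rescaled so the
scatter-to-total ratio equals the requested scatter fraction exactly; the
model returns both the contaminated sinogram and the exact scatter
estimate, so scatter correction can be studied without estimation error.
Poisson sampling rescales the sinogram to a target total count; the scale
is recorded so reconstructions can be calibrated back to concentration
units.

## Reconstruction

- **FBP**: rows are filtered in frequency space with `|f|` times an
  apodization window (ramp, Butterworth order 4, Hamming, Hanning, Parzen,
  Shepp-Logan), hard-truncated above the cutoff (0.5 x Nyquist by
  default). Rows are zero-padded to the next power of two at least 4x the
  bin count; 4x padding reduces the circular-convolution DC bias of the
  discrete ramp to ~0.5% (2x padding leaves ~4%). The back-projection is
  scaled by `pi / n_angles / dt^2`. Attenuation and scatter corrections
  are applied to the sinogram before filtering; cold regions may go
  negative (linear method, no clamping).
- **OSEM**: 16 subsets assigned round-robin over angles (subset count must
  divide the angle count), non-negative by construction. Attenuation
  enters the forward model as `1/ACF`; the scatter estimate enters as an
  additive background, which keeps the EM multiplicative update
  non-negative instead of subtracting counts.
- **MAP-EM**: one-step-late update with a quadratic 8-neighborhood prior
  (weights 1 for edge neighbors, 1/sqrt(2) for diagonal), 18 iterations by
  default; beta = 0 reduces exactly to MLEM.
- An optional Gaussian post-filter (sigma = FWHM/2.3548, reflect-mode,
  sum-preserving) is available for all algorithms.

## Image-quality metrics

- **NU**: 100 x population SD / mean in a 22.5 mm x 10 mm cylindrical VOI
  centered in the uniform section below the chambers.
- **RC**: per rod (2 mm and larger), the image is averaged axially over
  the central 10 mm of the rod section, the maximum is taken in a circular
  ROI of twice the rod diameter around the rod center, and divided by the
  true concentration. Values above 1 are reported as-is.
- **SOR**: mean of a 4 mm x 7.5 mm VOI centered in each cold chamber
  divided by the uniform-VOI mean, unclamped, so linear reconstructions
  can report negative spill-over.

## Selection criterion

A configuration is accepted when, with strict inequalities,
`0.9 < RC(3 mm) < 1.0` and `NU < 10%`. Entries with missing metrics are
flagged unevaluable rather than dropped; survivors are ordered by
ascending NU.

## Dosimetry chain

Decay-uncorrected %ID/g time-activity curves are integrated with the
value held constant from t = 0 to the first sample, trapezoid across the
samples, and a pure physical-decay tail `A(t_last)/lambda` after the last
sample (a conservative, clearance-free default). For a %ID/g curve the
residence time is `AUC x mass / 100`. The summed residence times of any
source partition are validated against the physical bound `1/lambda`.

Tumor dose is `tau x S(mass)` where S comes from a least-squares
power-law fit `S(m) = a m^b` of a sphere S-value table (log-log
`polyfit`); a power law is used instead of linear interpolation because
the table is convex decreasing. Organ doses are
`sum over sources of tau_s x S(target <- source)` from an S-factor
matrix with tissue weights summing to 1; the effective dose is the
weighted sum. Mouse residence times are scaled to a human phantom by the
ratio of relative organ masses.

The packaged sphere S-value and organ S-matrix CSVs are **synthetic**,
generated by `scripts/make_synthetic_dose_fixtures.py` from documented
functional forms (power-law self-dose, distance-falloff cross-dose).
They have the right qualitative structure (S decreasing in mass,
diagonally dominant S-matrix) but are not measured or Monte Carlo data;
dose numbers computed from them are internally consistent, not
physically calibrated.

## Kinetics generator

Each region follows `bio(t) = A2 exp(-k_clear t) - A1 exp(-k_uptake t)`
with `A2 >= A1` and `k_uptake > k_clear` — the rise-then-slow-washout
shape typical of radiolabeled monoclonal antibodies — multiplied by
physical decay (Cu-64, half-life 12.7 h). The defaults describe a ~25 g
tumor-bearing mouse (tumor ~0.2 g) imaged at 2/15/40/64 h after a
14.8 MBq injection. The decayed integral has the closed form
`A2/(k_clear + lambda) - A1/(k_uptake + lambda)`, used as analytic truth
in parameter-recovery tests: the 4-point schedule recovers residence
times within 15% (tail-dominated bias), dense 0.25 h sampling within 2%.
Optional measurement noise is multiplicative lognormal with a given CV,
mean-one, and requires an explicit random generator.

## Comparison engine

Dose tables are compared against the OSEM iteration-1 column with the
symmetric percent difference `200 (x - ref)/(x + ref)`, which is
antisymmetric, bounded in (-200, 200) for positive inputs, and
scale-invariant. Rendering rounds half-away-from-zero to one decimal;
internal values keep full precision. `range_spread` reports
`100 (max - min)/min`; correlation uses the squared Pearson coefficient.

## Numerical choices and limitations

- The projector is 2D slice-by-slice; no axial mixing, no 3D scatter,
  no randoms, no detector blurring or positron-range model. RC values
  here reflect voxelization and reconstruction only, so their absolute
  level differs from scanner measurements.
- The sparse projector is cached per (grid, geometry); the default study
  (48x48x63, 96 angles, 19 configurations x 2 correction levels) runs in
  tens of seconds on one CPU.
- Scatter estimates used for correction are the exact simulated scatter,
  isolating reconstruction effects from scatter-estimation error.
- Strict inequalities in the selection criterion mean boundary values
  (RC exactly 0.9 or 1.0, NU exactly 10%) fail.
- All stochastic behavior flows through explicit integer seeds; tests fix
  seeds and assert trend properties (monotonicity, orderings, signs)
  rather than exact noisy values.
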
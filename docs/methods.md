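# Methods

## Scope and model

`y90dosim` computes pre-treatment absorbed doses for ⁹⁰Y-microsphere
radioembolization from a ⁹⁹ᵐTc-MAA surrogate study, under the standard
planning assumptions: the MAA and microsphere biodistributions are
identical, the microspheres are permanently trapped (no biological
clearance, so cumulated activity is `1.443·T½·A` with no time-activity
fitting), and all compartments are uniform-density soft tissue. Four dose
calculations share one set of inputs (count image, VOI masks, administered
activity, lung shunt fraction):

1. **PM** — three-compartment partition model (aggregated tumor TL, target
   normal liver NL_t, lung). Mean doses follow the MIRD energy-balance
   form; the lung compartment enters only through the `(1−LSF/100)` factor
   (no lung dose is computed — out of scope).
2. **MTPM** — the (n+2)-compartment multi-tumor extension. Each tumor dose
   scales the NL_t dose by that tumor's TNRᵢ; the denominator keeps the
   aggregate TNR, which fixes the tumor/normal activity split. Two exact
   algebraic identities follow and are enforced as tests: the
   volume-weighted mean of per-tumor doses equals the PM tumor dose, and a
   single-tumor patient reproduces PM exactly.
3. **LDM** — local deposition: dose = cumulated activity × scalar S-value
   `⟨E_β⟩/M_voxel`. Requires cubic voxels (the scalar S is otherwise
   undefined).
4. **DPK** — discrete 3D convolution of cumulated activity with a voxel
   S-value kernel, zero-padded at the grid edge (the liver is interior in
   any realistic acquisition, so edge losses are immaterial; energy
   convolved past the border is deliberately dropped rather than
   renormalized).

VOI algebra: TL is the union of the individual tumors, NL_t = PTV − TL,
NL_w = WL − TL, all as binary voxel sets on the activity grid with no
sub-voxel partial volumes (contour resampling happens upstream of this
package). Tumors must be pairwise disjoint and contained in the PTV, which
must be contained in WL; violations are hard errors. Derived masks are
recomputed on access, never cached, so they cannot go stale.

## Constants and the consistency mode

| constant | default | units | role |
|---|---|---|---|
| energy per GBq | 49.67 | J/GBq | compartment equations |
| half-life | 64.2 | h | cumulation (`1.443·T½`) |
| mean β energy | 0.9267 | MeV/decay | voxel S-value |
| voxel density | 1.03 | g/mL | voxel mass in S |
| compartment density | 1.0 | g/mL | volume→mass in PM/MTPM |

These printed conventions are mutually inconsistent at the third digit:
0.9267 MeV/decay integrated over 1.443·T½ gives ≈49.52 J/GBq, not 49.67,
and the conventional S = 1.603 Gy/(GBq·s) at 4.48 mm implies 1.03 g/mL
while the compartment models assume 1.00 g/mL. Rather than silently picking
one side, `PhysicsConstants(consistency_mode=...)` makes the choice
explicit:

- `"paper"` (default): every constant as conventionally printed. A uniform
  phantom then shows a fixed ≈3.3 % offset between compartment doses and
  LDM voxel doses (the product of the 49.67/49.52 constant gap and the
  1.03/1.00 density gap) — a real feature of the printed conventions, and
  asserted to lie in [3.0 %, 3.6 %] by the tests.
- `"consistent"`: the voxel energy rate is derived from 49.67 J/GBq and
  voxels use the compartment density, so uniform-activity LDM equals
  PM/MTPM to machine precision. This mode exists for validation; clinical
  numbers should use `"paper"`.

Every CLI run logs the full constant set in effect, and dose-map sidecars
record it, so any number is auditable after the fact.

## Numerical conventions

- **LSF** uses the geometric mean of ROI *totals* across the two views
  (not a pixel-wise geometric mean, which differs under noise); no
  attenuation or scatter correction.
- **COV(TNRᵢ)** uses the sample (n−1) standard deviation. The population
  convention differs by <3 % at n ≥ 10 and the choice is documented here
  because published tables rarely state it.
- **Dₓ** uses a rank rule: sort VOI voxel doses descending and take rank
  `ceil(x·N/100)`, no interpolation — bit-reproducible and exact for the
  step-function DVH of a finite voxel set. Endpoints are always computed
  from raw voxel doses; the binned curve (default 0.5 Gy bins) is for
  plotting/export only.
- **Bland–Altman** limits are bias ± 2·SD (exactly 2, not 1.96), sample SD
  of the differences. Because bracketed ranges in published comparison
  tables are sometimes limits of agreement and sometimes a CI of the bias,
  the report emits both, labeled (`limits_of_agreement_Gy`,
  `bias_ci95_Gy`).
- **Lin CCC** uses population (1/n) moments; two constant equal series
  return 1 by convention. Pearson/Spearman/paired-t/Wilcoxon are taken
  from `scipy.stats`, not re-derived.
- **NMSE** is `100·Σ(test−ref)²/Σref²` over a VOI, with the LDM map as the
  conventional reference.
- **Calibration** normalizes by whole-liver counts only; counts outside WL
  are zeroed with a logged warning (no extrahepatic dose model exists at
  this stage of planning).
- Dose rounding to integer Gy happens only at print time; JSON/CSV carry
  full precision.

## The default kernel (synthetic)

Published ⁹⁰Y voxel S-value tables are distribution-restricted, so kernels
are pluggable text files (`nx ny nz spacing_mm` header, then z-major blocks
of rows, x fastest, Gy/(GBq·s); round trip lossless at 12 significant
digits). The built-in `build_default_kernel` exists so the toolkit runs
without external data: it is a *synthetic* kernel, not a transport
calculation. It Monte-Carlo integrates an analytic stand-in radial profile
— energy deposition radius drawn from a gamma distribution (shape 3, scale
0.9 mm: mean ≈2.7 mm, 90th percentile ≈4.8 mm) truncated at the ≈11 mm
maximum β range — over uniformly distributed decay sites in the source
voxel, then normalizes the tally so total deposited energy per unit
cumulated activity equals the β energy rate exactly. Consequences used by
the tests: exact energy closure, a center value strictly below the LDM
S-value (some energy always escapes the source voxel), and bit-identical
kernels for identical seeds. For clinical work, drop in a published kernel
file instead.

## Synthetic phantoms

The phantom generator emulates the *structure* of a planning study, not the
imaging chain: an ellipsoidal liver (default semi-axes 85×65×55 mm,
≈1.27 L) on a 64³ grid of 4.48 mm cubic voxels, spherical tumors with
uniform per-tumor uptake `TNRᵢ` over a unit normal-liver concentration
(default 1000 counts/mL, ≈1.3·10⁶ liver counts — a realistic SPECT count
level), a PTV that is either the whole liver or a half-plane cut (lobar),
optional Gaussian PSF blur (applied before Poisson sampling, mirroring
detector response followed by counting statistics), and a separate 2D
anterior/posterior planar pair whose lung field carries exactly the counts
implied by the prescribed shunt fraction. Cohort sampling draws tumor
volumes log-uniformly (small lesions dominate real cohorts, whose reported
range spans 0.6–351 mL), uptake ratios and shunts uniformly, and places
spheres by rejection inside the PTV with a one-voxel margin.

Because the noiseless, unblurred phantom is the exact inverse of the
estimation pipeline, ground-truth recovery tests assert equality to 1e-10
relative, not approximate agreement. What passing these tests does *not*
show: robustness to attenuation, scatter, collimator blur, reconstruction
artifacts, registration error, or intra-tumor heterogeneity — none of
which the phantom models.

## Problem sizes

The test suite runs entirely on synthetic data: the algebraic-identity
sweep uses 100 randomized noisy phantoms (1–8 tumors, 0.6–120 mL) on the
default 64³ grid; brute-force convolution oracles run on grids up to 8³
with kernels up to 5³; the Poisson-unbiasedness check uses 50 noise
realizations at ≈1.3·10⁶ liver counts. These sizes keep the full suite
under ten seconds while exercising every code path at clinically shaped
dimensions; the identities they check are exact at any scale.

## Known limitations

- No lung dose, no body-surface-area activity planning, no BED/radiobiology.
- No DICOM-RT import; VOIs arrive as NIfTI label maps with a JSON role map.
- No attenuation/scatter/PSF compensation; the identical-biodistribution
  assumption is taken as given.
- The default kernel is a documented stand-in; absolute DPK accuracy
  depends on the kernel file supplied.
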
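# Methods

## Forward model

Every pixel of a phantom is modeled as an optical chain acting on the
Stokes vector of the illumination, which is fully circularly polarized
(right-handed by default, S = (1, 0, 0, ±1)):

1. **reflectance mode only** — a helicity-flipping mirror,
   M = diag(1, 1, −1, −1). Backscattered circular light reverses
   handedness *at the reflection event*, before the exit pass through the
   birefringent medium; placing the mirror first is what makes the
   reflectance AoP a uniform +90° rotation of the transmission AoP at every
   pixel, independent of the local fiber axis. (Placing it after the
   retarder would instead reflect the AoP about 0°, producing an
   axis-dependent shift — not what this geometry exhibits.) A double-pass
   variant can be composed explicitly from `ModeChain` if desired.
2. a **linear retarder** with fast axis equal to the local fiber axis θ and
   retardance δ;
3. a **diagonal depolarizer** diag(1, d_lin, d_lin, d_circ), where the
   factors are *retained* polarization fractions;
4. a **neutral attenuator** T·I (Beer–Lambert absorption, already expressed
   as a fraction of control transmission).

Conventions: angles in degrees on the axial interval [−90°, 90°),
counterclockwise from the camera horizontal (y-up); retardance in radians,
validated to [0, 2π); S3 > 0 is right-handed. The illumination incidence
angle of a real reflectance rig is not modeled geometrically; its effect is
absorbed into the reflectance depolarization factor, since no conclusion
here depends on incidence geometry. The broadband source is treated as a
single effective channel (no spectral resolution).

## Phantom generator

`generate_scene` maps the factor levels of a collagen-gel experiment onto
per-pixel optical maps. All maps are constant within each 2×2 superpixel
so that a noise-free mosaic determines each superpixel's state exactly
(this is what makes the 1e-9 round-trip test meaningful rather than
interpolation-limited).

- **Fiber organization.** Each superpixel contains `fibers_per_superpixel`
  (default 12) fibers with axes drawn i.i.d. from an axial von Mises
  distribution: κ = 4 for aligned scenes, κ = 0.05 for disorganized ones
  (defaults, overridable). The incoherent mixture of equally-retarding
  retarders at axes {θ_i} acting on circular input is *exactly* equivalent
  to a single retarder at the circular mean axis followed by a linear
  depolarizer with retained fraction R2 = |mean(e^{2iθ_i})|. The generator
  uses that identity, so sub-resolution disorder is the mechanism by which
  disorganized phantoms lose DoLP — single fibers retard just as strongly,
  but their axes cancel within a pixel. With 12 fibers per superpixel a
  disorganized scene retains R2 ≈ 1/√12 ≈ 0.29 of its linear polarization,
  an aligned scene ≈ 0.87.
- **Collagen density** (1.5 / 3.0 / 4.5 mg/mL; 1.5 = control) sets
  retardance δ = c_ret · density · thickness_factor with c_ret = 0.7
  rad·mL/mg, chosen once so the control aligned transmission scene lands at
  AVG DoLP ≈ 0.75 — the regime reported for aligned gels. Absolute
  thickness-to-retardance constants for real gels are unknown, so only
  orderings and invariances are claimed, never absolute DoLP matches.
  Density and crosslinking also shrink the retained polarization
  (exp(−0.10·(density−1.5)), exp(−0.06·riboflavin_mM)): more scatterers,
  more depolarizing events. Retardance carries 5% lognormal
  per-superpixel jitter so scenes are not degenerate.
- **Reflectance geometry** multiplies the retained polarization by 0.36:
  backscattered photons undergo many more depolarizing scattering events
  than ballistic transmitted ones. The value reproduces the observed
  aligned-gel reflectance/transmission DoLP ratio; because it is a single
  scalar, the reflectance DoLP map is an exactly uniform rescaling of the
  transmission map (relative SD of the ratio ~1e-16 noise-free), which is
  the model's account of why rescaled reflectance color maps recover the
  transmission spatial pattern. Whether the real reduction includes a
  diattenuation component is unknown; the model attributes all of it to
  depolarization.
- **Absorber levels** set transmissivity directly to 1.0 / 0.67 / 0.33 of
  control — the Beer–Lambert exponent is already folded into the level
  definition.

The **sensor** renders Malus-law projections on a 2×2 analyzer mosaic
(default layout [[90, 45], [135, 0]] row-major from top-left —
configurable, since physical sensor layouts vary), then applies Poisson
shot noise at 1000 photoelectrons full scale and Gaussian read noise of
0.5% of full scale, quantized to 16 bits. These are plausible
machine-vision camera figures chosen once; no claim of matching a specific
sensor is made. Every stochastic operation takes an explicit seed; there
is no global random state.

What the generator does *not* emulate: speckle, depth-resolved scattering,
spatially correlated fiber bundles, sensor fixed-pattern nonuniformity and
finite extinction ratio, or wavelength dependence. Passing tests therefore
demonstrate the correctness and internal consistency of the processing
chain and the qualitative phenomenology of the two imaging geometries —
not quantitative agreement with any particular instrument or tissue.

## Processing chain

Demosaicing offers direct superpixel extraction (quarter resolution,
exact) and per-channel bilinear interpolation of each analyzer's stride-2
subgrid (full resolution, edge replication at borders; exact for linear
intensity fields away from a 2-pixel border). Intensities are interpolated
first and Stokes parameters computed afterwards. S0 is the
redundancy-averaged (I0+I45+I90+I135)/2. Pixels with S0 below 1e-3 of the
frame maximum are masked invalid rather than producing unstable DoLP
ratios. No gain or extinction-ratio calibration is applied — modern DoFP
sensors are uniform enough that the uncalibrated pipeline is the standard
configuration this package models.

Known estimator property, asserted in the tests: DoLP is positively biased
at low true DoLP under noise (√(S1²+S2²) is non-negative), which is
relevant when interpreting low-signal reflectance images.

## ROI statistics

AVG DoLP is an arithmetic mean. STD AoP defaults to the **recentred**
estimator: compute the circular mean axis from the doubled-angle
resultant, wrap every AoP into the 180° window centred on that axis, take
the population (divide-by-n) SD. This matches the naive SD for
concentrated data but is invariant to where the branch cut falls; for a
uniform axial sample it converges to 180/√12 = 51.96°. The **circular**
estimator 0.5·√(−2 ln R2) is provided for comparison; the two agree within
1% for concentrated samples. A zero resultant (no preferred axis) falls
back to a window centred at 0° with a warning.

## Fiber-orientation analysis

- **CED filter**: structure-tensor anisotropic diffusion (gradient scale
  σ_grad = 1 px, integration scale ρ = 4 px, α = 10⁻³, C = 1, explicit
  step 0.15, 20 iterations — standard values for fibrous imagery; the
  explicit scheme requires step ≤ 0.25 and raises otherwise). Diffusion is
  weak across coherent structures and strong along them, enhancing
  flow-like fibers while suppressing background noise.
- **FFT distribution**: Hann window, 2D power spectrum, accumulation into
  angular wedges over a radial band of 0.1–0.8 Nyquist (excluding DC /
  illumination gradients and the aliased corners). Wedge power is
  normalized by wedge occupancy — the discrete frequency grid fills wedges
  unevenly, and raw sums would be anisotropic even for white noise.
  Spectral energy lies perpendicular to the fibers, so angles are rotated
  90° to index fiber orientation.
- **Axial von Mises fit**: weighted nonlinear least squares of
  p(θ) ∝ exp(k·cos 2(θ−μ)) against the binned distribution, initialized
  from doubled-angle moment estimates (concentration from inverting the
  Bessel ratio I1/I0); on optimizer failure the moment estimates are
  returned flagged. The reported spread σ is the linear SD of the fitted
  density over its 180° window, which is bounded — σ → 51.96° as k → 0 and
  σ → 0 as k → ∞ — so isotropic and aligned textures are directly
  comparable on one scale. The classical circular SD
  0.5·√(−2 ln(I1(k)/I0(k))), which diverges as k → 0, is reported
  alongside as `sigma_circular_deg`. Recovered k values from FFT power
  distributions are comparable across conditions in ordering and
  approximate magnitude (end-to-end recovery within 25% over κ ∈ [0.5, 4])
  but depend on the texture rendering; they are not absolute material
  constants. Multi-slice stacks are analyzed per slice and k, σ averaged.

## Problem sizes and numerical choices

Simulated scenes default to 64×64–128×128 pixels and textures to 256×256
with 800 fibers — sizes at which every group-level effect the package
asserts (orderings across 20 seeded replicates, 25% concentration
recovery over 10 seeds) is stable, while the full suite runs in well under
a minute. AoP maps use the half-open interval [−90°, 90°) with the +90°
branch mapped to −90°; axial differences use
min(|Δ| mod 180, 180 − |Δ| mod 180). ROI masks are user-supplied binary
images; a rectangle helper is included. Outcome CSVs carry `#`-prefixed
provenance headers; HDF5 outputs embed the producing configuration as a
JSON attribute.

## Limitations

Single-frame processing only (no video-rate streaming or mechanical-test
synchronization); no S3 estimation (the sensor has no circular analyzer);
no polarization-sensitive Monte Carlo photon transport — the depolarizer
element is a lumped stand-in for what is, physically, a distribution of
scattering path lengths. Group-level numbers from real gel experiments
are not reproducible from simulation; only directions, orderings, and
exact geometric invariances (the 90° shifts, the uniformity of the
reflectance rescaling) are asserted.
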
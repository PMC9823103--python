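# Methods

## Model

A time-gated reflection matrix records the complex backscattered field
E(**r**ₒ; **r**ᵢₙ) for every focused-illumination position **r**ᵢₙ on a
raster, with the detection coordinate **r**ₒ conjugate to the sample
plane. A thin aberrating layer (the skull, modelled as a phase screen
φ_s) at distance z above the sample plane multiplies every traversing
wave by e^{iφ_s(**w**)} at its own plane. Re-expressing both matrix
indices at the plane conjugate to the layer — discrete Fresnel free-space
propagation applied over the output index (each column) and the input
index (each row) — turns the layer's effect into separable phase factors:

    E(w_o; w_in) = -(e^{2ikz}/λ²z²) e^{iφ_in(w_in)} Õ_M(k(w_o+w_in)/z) e^{iφ_o(w_o)} + E_M,

where φ_in(w) = φ_s(w) + (k/2z)|w|² and likewise φ_o, k = 2π/λ,
Õ_M = F[O(r)·e^{i(k/z)|r|²}] is the object spectrum carrying a geometric
quadratic phase, and E_M collects multiple scattering. Reciprocity makes
φ_in = φ_o physically, but the two are estimated independently, which
also absorbs illumination/detection path mismatch.

### Assumptions

- Paraxial (Fresnel) propagation; a single thin aberrating layer; no
  amplitude (absorption) component in the aberration.
- Time gating has already isolated ballistic photons; the coherence gate
  is treated as applied by the instrument.
- The scan lattice pitch is an integer multiple of the detection pixel
  pitch, so the sum coordinate **W** = **w**ₒ + **w**ᵢₙ lies on the pixel
  lattice and no interpolation enters the solver.

## Solver

After the shear to E(**W**; **w**ᵢₙ), the object spectrum is
shift-invariant in **w**ᵢₙ. For each **w**ᵢₙ the phase of the inner
product over shared **W** pixels with a reference estimates δφ_in;
swapping indices estimates δφ_o; corrections e^{−iδφ} are applied
multiplicatively and accumulated, alternating input/output until both
update RMS values drop below tolerance. The default reference is the
coherent sum of all *other* corrected columns — algebraically equal in
expectation to the printed w_in = 0 reference column at the first
iteration (up to gauge) but far better conditioned when that column is
weak; `SolverConfig(reference="zero")` gives the strict reference-column
form, and both are verified against brute-force double-loop inner
products to 1e−12. Inner products are plain complex correlations;
`amplitude_weighting=True` switches to magnitude-normalised products
(off by default, matching the model). Absent samples at the rim of the
Minkowski-sum W lattice are excluded per pixel with count normalisation.

Gauge handling. Piston is pinned by forcing the estimate to zero at the
lattice point nearest the optical axis. Tilt is an exactly flat direction
(a shared linear ramp in φ_in and φ_o only translates the reconstruction),
and the alternating iteration drifts along it; after convergence the
solution is re-gauged so the layer-screen part of the *output* phase
(total estimate minus the analytic (k/2z)|w|² term) carries no
amplitude-weighted tilt over the detection window. Fixing the gauge on
the output window — a support shared by all subregion solves of one
field — keeps independently solved tiles on a common lateral
registration; the corrected columns are adjusted consistently so the
accumulation is unchanged.

Convergence control. Defaults: tolerance 1e−2 rad RMS per update,
30 iterations maximum. Divergence is declared only on sustained growth
(five consecutive increases while >10× above the best level reached);
benign transient bumps of the alternating scheme are common on subregion
solves. On noise-free inputs the accumulated spectrum energy is
non-decreasing across iterations (regression-tested to 1e−9 relative).

Known fixed-point structure (measured on the simulator): full-field
solves at the default scales converge to the true phases to ≲1e−3 rad
(beyond the gauge freedoms). Small subregions are less well conditioned:
quadratic-like (defocus/astigmatism) directions become soft, and solves
on tiles ≲ 14 μm at z = 100 μm can converge to stationary points
0.6–0.7 rad from the truth. This is an identifiability property of the
data subset, not an iteration failure, and it motivates subregion sizes
of tens of micrometres — far larger than the isoplanatic patch — in the
tiled pipeline.

## Discretisation

All basis changes are exactly unitary on the stored lattice: the Fresnel
transfer function e^{ikd}e^{−iπλd|f|²} (unimodular) applied without
padding for matrix conversions, and unitary centred DFTs for the pupil
basis. Round trips invert to machine precision and the Frobenius norm is
preserved (regression-tested at 1e−9). The standalone `fresnel_propagate`
for single field maps zero-pads 2× by default to suppress wrap-around
(validated against the closed-form Gaussian-beam width to 1%).

Two sampling regimes bound the equal-pitch discretisation. The transfer
function is faithful to continuous propagation only for |d| < nΔ²/λ; the
conjugate-plane quadratic phase (k/2z)|w|² is well sampled only for
z ≳ (n+m)Δ²/λ (window n, scan span m pixels, pitch Δ). The two regimes
are disjoint, so: the lattice ("analytic") simulator — which evaluates
the model exactly on the lattice and is the solver's oracle — requires
the well-sampled-chirp regime and refuses to emit otherwise
(`check_sampling=False` overrides for support-confined comparisons);
the double-pass physical simulator requires the transfer-function regime;
`to_conjugate_basis` itself only warns on chirp undersampling because the
conversion remains an exact unitary re-expression and per-pixel phase
estimation is unaffected. The double-pass and lattice models agree to
complex correlation >0.95 on the NA-accessible support of each column.

The object is reconstructed by an exact separable chirp-DFT between the
W lattice (spatial frequencies q = kW/z) and the sample grid, removing
the model prefactor and the geometric quadratic phase. Positions with
|r| ≳ q_max·z/2k scatter outside the sampled spectral window — a physical
vignette of the finite detection window — so quantitative comparisons use
targets inside the captured field.

Corrected images in the *sample* basis (confocal images, PSF maps) are
formed by removing only the screen part φ̂_s of the correction and
inverse-converting; the quadratic conjugate-plane phase is part of the
physical propagation geometry, and removing it too would defocus the
columns.

## Synthetic study conditions

The phase screen is zero-mean Gaussian noise smoothed to a Gaussian
autocorrelation exp(−r²/l²) and rescaled to the target RMS; defaults
RMS = 3.0 rad, correlation l = 4.0 μm. These defaults are calibrated so
that, on the default geometry (0.65 μm pitch, tens-of-μm windows,
z = 60–100 μm), the uncorrected round-trip PSF is broadened well over
10× the simulated diffraction limit, the residual unscattered core
e^{−σ²/2} stays below the speckle halo, and the screen decorrelates
across the scan so the column-averaged PSF is a smooth blob (estimated
broadening ≈ 0.88·σS/l for scan extent S; measured 19–24×). Recovery
experiments that probe a prescribed screen use RMS 2 rad / l = 10 μm.
Multiple scattering is circular complex Gaussian scaled to a requested
power ratio against the ballistic signal.

The simulated diffraction limits used as closed-form PSF oracles are the
scan-lattice-limited width 1.2067·λz/S for the lattice model (stationary
phase result) and the amplitude Airy width ≈0.705·λ/NA for the
double-pass model (illumination and detection share the pupil, so the
round-trip amplitude PSF equals the single-pass Airy pattern).

Coherent-gain calibration uses i.i.d. uniform(−π, π] phase maps and
*independent* input and output screens: a single reciprocal screen makes
the symmetric column pairs (w_in, W − w_in) mutually coherent before any
correction, capping the measurable gain near 0.6N — a real interferometric
effect, not an estimator property. With independent screens the
spectrum-energy gain on the fully covered W support concentrates at N to
within a few percent. The reported enhancement statistic is this energy
ratio; a single-pixel peak ratio is an extreme-value statistic and is
reported only as a diagnostic.

What the simulator does not emulate: volumetric (multi-layer) scattering,
depth-dependent aberration growth, polarisation, coherence-gate spectral
effects, detector noise, and sample motion. Passing tests therefore
demonstrate correctness of the algorithmic chain under the stated model,
not end-to-end performance on tissue.

## Tiling

Fields wider than one solve are divided into overlapping subregions
(defaults mirror the instrument practice: 64 μm tiles at 50% overlap,
5×5 on a 160 μm field, the outer tiles overhanging symmetrically since
5 tiles at 32 μm stride span 192 μm). Each tile's submatrix is solved
independently, its reconstruction normalised to the 99th-percentile
amplitude over the tile footprint, registered to the first tile's frame
by subpixel cross-correlation, and blended with separable raised-cosine
weights normalised to an exact partition of unity (1e−12).

Measured consistency: with ground-truth phases, partitioning a field into
2×2 half-size tiles and merging reproduces the single solve to ~1% RMS,
so the mosaicking machinery itself is consistent. With *solved* phases the
merged mosaic differs from a single equal-size tile solve by ~13–16% RMS
under the best-conditioned configurations tested: each subregion's
estimate converges to a slightly different soft-mode stationary point of
its own data subset (0.05–0.1 rad), and these imprint on the images. A
stricter few-percent consistency would require coupling the subregion
solves (joint soft-mode regularisation), which is outside the present
algorithm.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| wavelength λ | 1.3 μm | source wavelength (vacuum) |
| numerical_aperture | 1.05 | objective NA (metadata; the simulator uses a paraxial effective NA ≤ 0.45) |
| sample_pixel_pitch Δ | 0.325 μm | camera pixel at the sample plane; scan_step must be an integer multiple |
| scan_step | 0.65 μm | illumination raster pitch |
| detection_extent | 25 μm | per-illumination camera window |
| conjugate_distance z | 100 μm | sample plane → aberrating layer |
| SolverConfig.tolerance | 1e−2 rad | per-iteration update RMS stop |
| SolverConfig.max_iterations | 30 | iteration cap |
| ScreenSpec (rms, l) | 3.0 rad, 4.0 μm | default skull-like screen |
| TileLayout (size, overlap) | 64 μm, 0.5 | subregion mosaics |

Experiments in the test-suite and the acceptance script use scan rasters
of 16²–48² positions and detection windows of 64–128 pixels — sizes
chosen so every experiment runs in seconds to a couple of minutes on one
CPU while keeping each regime (chirp sampling, transfer-function
validity, band capture) comfortably valid.

## Degenerate inputs and tie-breaks

Phases at pixels with zero inner-product weight are reported as 0 with
weight 0 and excluded from RMS statistics; arg(0) is defined as 0. The
gauge pixel is exactly 0 by construction. Empty shared support between a
column and the reference yields weight 0 rather than an error. FWHM
measurements with no half-maximum crossing report infinity with a flag.
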
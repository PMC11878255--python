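# Methods

## The optical model

A Bessel beam has an angular spectrum confined to a single cone of
wavevectors (a ring-delta spectrum). `bblattice` synthesizes such beams from
a *single* modulation plane: a binary annular amplitude mask selecting
`R − Δ ≤ r ≤ R` (both bounds inclusive) is combined with the exact,
non-paraxial phase of a converging lens,

    φ_ring(x, y) = −(2π/λ) · (√(r² + f²) − f),  r measured from the
    beamlet center,

so the one surface acts simultaneously as apodization filter and Fourier
transformer: the thin ring of light converges to a Bessel-like focus on the
beamlet axis near `z = f` without any downstream conjugation optics. `R` and
`f` set the cone angle (≈ R/f) and hence the central-lobe width; the ring
thickness `Δ` sets the Gaussian-versus-Bessel balance — the thinner the
ring, the longer the axial extent of the focus.

A *lattice* is a list of such beamlets laterally shifted by a period `P`
(or, in general, independently parameterized per beamlet — heterogeneous
`R`, `Δ`, `f` and arbitrary centers are first-class). Two multiplexing
rules map the list onto one phase-only surface:

- **sum** — the transmitted phase is the argument of the coherent sum of the
  beamlet fields, `arg Σⱼ E₀ⱼ e^{iφⱼ}`. The amplitude is clamped to 1 on the
  union of ring supports (a phase mask cannot transmit more than unity);
  samples where the sum cancels exactly transmit 0, since an undefined
  phase must not inject energy.
- **overwrite** — beamlets are written in list order and each one replaces
  whatever earlier beamlets put on its own ring support. Order is
  configurable; ascending list order is the default and is recorded in every
  report. With one beamlet both rules reduce bit-exactly to the plain
  beamlet transmission.

The overwrite rule produces an intrinsically *inhomogeneous* array: the
last-written ring survives intact while the first one loses every overlap
region to its successors. For the reference design below the simulated
focal peaks span roughly 0.21–1.0 of the brightest beamlet. This is a
property of the method, not a numerical artifact, and it drives two
metrology conventions documented further down.

## Propagation

Free-space propagation uses the exact scalar angular-spectrum transfer
function `H = exp(i·2π·dz·√(1/λ² − fx² − fy²))`, with evanescent components
zeroed. It is exact for homogeneous scalar fields at every numerical
aperture used here (≤ 0.06), and it is testable against closed forms — the
Gaussian waist law, the Airy pattern of a lens-phased disk, and a radial
Fresnel–Hankel quadrature of the annulus design are used as independent
oracles in the test-suite.

Numerical policy:

- **Band limit.** On a finite window the transfer-function phase aliases at
  high obliquity for long throws; frequencies beyond the local-frequency
  bound `f_lim = 1/(λ√((2·δf·dz)² + 1))` (δf the spectral sample pitch) are
  truncated. The design spectra (≤ 0.105 cycles/µm) sit well inside the
  bound even at dz = 3.5 mm (f_lim ≈ 0.15 cycles/µm), so truncation only
  removes the 1–3% of edge-wave power that a sharp binary mask sheds at
  angles that leave the window long before focus. A warning reports the
  measured truncated fraction when it exceeds a configurable threshold
  (default 5%, above the expected edge-wave scale).
- **No error accumulation.** Every plane of a z-stack is computed in a
  single step from the source plane, reusing one forward FFT.
- **Precision.** All fields are complex128; intensity stacks are stored as
  float32 (half-maximum metrology is insensitive to single precision, and a
  601-plane 1024² scan in float64 would be needlessly heavy).
- Zero-padding (`pad_factor = 2`) is available but off by default: the
  512-µm window already holds the 380-µm mask support plus the diverging
  cone over the full characterization range.

## Metrology

All widths are intensity FWHMs with half-maximum crossings located by
linear interpolation between the bracketing samples. Transverse metrology is
read at the plane of maximal on-axis intensity — which for an apertured
lens sits measurably *before* `z = f` (≈ 1810 µm for the reference single
beamlet, an ≈ 9% focal shift produced by the 1/z amplitude factor of
diffraction), exactly where the published diffraction-free range
(1520–1870 µm) lies. Longitudinal metrology is the FWHM of the on-axis
intensity versus z.

Beamlet detection on the focal x-profile uses two parameters:

- `min_sep` (default `P/2 = 10 µm`): a peak within `min_sep` of a stronger
  one is suppressed. This removes each beamlet's own first side lobes,
  which sit ≈ 5 µm from its center.
- `rel_thresh` (default **0.15** of the global maximum): the threshold is
  deliberately below the 0.162 first-side-lobe ratio of an ideal J0²
  profile, so even an isolated beamlet's side lobes are rejected, while
  beamlets up to ≈ 7× dimmer than the brightest are kept. A threshold of
  0.5 — natural for homogeneous arrays — would silently discard the dimmer
  beamlets of an overwrite-multiplexed array (8 of 10 detected for the
  reference design); the simulated second-order side lobes that survive
  `min_sep` stay below ≈ 0.09, leaving a clean factor-two margin on either
  side of 0.15.

Derived lattice quantities:

- **extent_x** — distance between the outermost detected beamlets' *own*
  half-maximum crossings on the focal x-profile. For homogeneous arrays
  this coincides with the half-maximum crossings of the global profile; for
  inhomogeneous ones it does not cut off dim edge beamlets.
- **diffraction-free range** — beamlet centers are detected once, at the
  focal plane, and the y-FWHM is then tracked at those fixed lateral
  positions through the z-scan (mirroring a camera z-scan of a fixed
  sheet). The range is the maximal contiguous z-interval containing the
  axial peak over which the *mean* tracked y-FWHM stays at or below the
  sheet-thickness threshold (default 7 µm). Re-detecting beamlets per plane
  instead would count spurious defocus structure far from focus.
- **transmittance efficiency** — power inside a circular aperture (default
  radius 100 µm, the fabricated element's active radius) at the focal plane
  divided by the power inside the same aperture at the reference plane
  (default the modulation plane, z = 0).
- Sub-pixel beamlet centers come from a parabolic fit through the three
  samples around each maximum.

## Reference design and study conditions

The committed `configs/paper_defaults.yaml` holds the design every
headline number refers to: `R = 100 µm`, `Δ = 17 µm`, `f = 2000 µm`,
`λ = 0.488 µm`, ten beamlets at `P = 20 µm`, overwrite multiplexing, on a
1024 × 1024 grid with 0.5-µm pitch (512-µm window — Nyquist-safe for the
design's finest fringe period ≈ 9.8 µm and wide enough for the 380-µm mask
support). The linear array is offset by `x0 = −90 µm` so its support is
centered in the window; every reported quantity is translation-invariant.
The fabrication design wavelength (0.478 µm) is carried as metadata.

The input beam is a **uniform unit-amplitude plane wave** by default. The
physical experiment illuminates the element with a collimated Gaussian whose
waist is not published; a Gaussian of configurable `w0` is available, and
the choice matters mostly for the axial extent (apodizing the annulus
weights the inner radii). Under uniform illumination the simulated
single-beamlet axial FWHM is ≈ 918 µm versus the published ≈ 700 µm — the
on-axis closed form `I(z) ∝ (k/z)²·sinc²(kΔu(1/z − 1/f)/4π)`,
`Δu = R² − (R−Δ)²`, predicts 917 µm, so the package agrees with theory to
0.1% and the residual gap to the published figure is attributable to the
unpublished apodization and measurement convention.

Problem sizes used by the reproduction script and the end-to-end tests:
the single-beamlet scan covers 1200–3200 µm and the lattice scan
1300–2700 µm, both at 10-µm steps — the same planes the full 5-µm
characterization schedule (500–3500 µm) contains, subsampled where the
metrology is interpolation-limited anyway.

## Metasurface discretization

The nanopillar response is *data*, not computation: full-wave
electromagnetic simulation of individual pillars is out of scope, so the
pillar library is either a user CSV (`side_nm, phase_rad, transmittance`)
or the built-in **synthetic** fixture — n uniformly spaced phases
(default 28) with monotone sides spanning the 60–340 nm fabrication range
and a flat transmittance of 0.8 (the admission rule requires > 0.5). Fixed
geometry mirrors the fabricated element: 400-nm pitch, 520-nm pillar
height, design wavelength 478 nm. (A 60–340 nm range at 10-nm steps would
imply 29 sides; the stated library size of 28 is retained.)

Discretization resamples the continuous transmission onto the pillar pitch
by nearest sample — interpolating a wrapped phase across a 2π zone boundary
would corrupt it — and assigns each occupied site the library entry nearest
in circular phase distance (ties to the lower index). The worst-case
quantization error is half the largest library phase gap (π/28 ≈ 0.11 rad
for the default library), and the quantized surface changes the simulated
focal FWHM by < 0.1% for the reference design. Sites where the mask is zero
remain unpatterned; an optional flag models an unmasked surround as unit
transmission. Layouts export to CSV (canonical row-major ordering, so
export → import → export is byte-identical) and to GDSII (single cell,
layer 1, 1-nm database unit, fixed timestamps for reproducibility).

## What the synthetic conditions do not capture

- Scalar theory: no polarization or vectorial focusing effects (negligible
  at NA ≤ 0.06, but unverified here).
- The synthetic pillar library has idealized uniform phases and flat
  transmittance; a measured library will add amplitude structure and phase
  error beyond quantization.
- No fabrication imperfections, substrate reflections, or the unmasked
  surround light the real chip transmits; fabrication-dependent figures
  (the measured 67% transmittance efficiency, 20:1 SNR, absolute z
  positions of the measured range) are therefore not simulation targets.
- No propagation through scattering tissue.

## Known limitations and degenerate inputs

- `fwhm_1d` requires the scan to bracket the half maximum; otherwise the
  profile is flagged as unbounded (axial reports carry `z_unbounded` instead
  of raising).
- Peak detection assumes the sheet lies along a single y-row (the row
  through the global maximum); 2D lattices are out of scope.
- Overwrite order between equal beamlets is the list order; reversing the
  list mirrors the brightness asymmetry.
- The band limit makes extreme-NA content (beyond `f_lim`) silently
  non-propagating; for short throws on this window the limit exceeds the
  Nyquist band and has no effect.
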
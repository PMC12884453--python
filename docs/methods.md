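# Methods

## Scope and data model

The package analyzes three kinds of measurement made on glyceryl
monooleate (GMO) liquid-crystalline nanoparticles and their hybrids
with extracellular vesicles: 1D small-angle X-ray scattering profiles
(q in nm⁻¹ against intensity in arbitrary units), batches of
single-particle Raman spectra (wavenumber in cm⁻¹ against counts, one
spectrum per optically trapped particle, plus an averaged buffer
blank), and scalar assay readouts (fluorescence intensities, absorbance
time courses, flow-rate ratios, binary micrograph masks). No public
dataset accompanies these measurements, so a synthetic forward model
with known ground truth backs every analysis stage.

## SAXS mesophase assignment

### Peak detection

Profiles are lightly smoothed (Savitzky–Golay, window 5, order 2) and
local maxima are picked by prominence relative to the profile's
intensity range (default 2%). The apex of each peak is refined below
the grid spacing by fitting a parabola through the three samples around
the maximum. A flat profile returns an empty peak set rather than an
error; detection requires at least 16 grid points.

### Indexing

Each candidate cubic space group carries its allowed reflections as
√N = √(h²+k²+l²) in increasing order (*Pn3m*: √2, √3, √4, √6, √8, √9;
*Im3m*: √2, √4, √6, √8; *Ia3d* is included for generality: √6, √8, √14,
√16). The first allowed reflection is anchored on the lowest-q detected
peak, the remaining reflections are predicted and matched to detected
peaks within a relative tolerance (default 2%), and the slope of
q = (2π/d)·√N is refit through the origin on the matched pairs — the
closed form Σ(√N·q)/Σ(N), equivalent to the least-squares regression
through zero.

Candidates are ranked by (i) fewest detected peaks left unmatched,
(ii) fewest reflections predicted inside the observed peak range but
matched to nothing, (iii) lowest RMS relative residual. Criterion (ii)
is essential: the *Im3m* reflection set is a subset of *Pn3m*'s, so
*Pn3m* can always tile an *Im3m* peak series — what rules it out is the
absence of the (111) peak where *Pn3m* predicts one. A cubic call
requires at least two matched reflections and a residual below a cap
(default 2%); a single detected peak is read as the sponge phase when
L3 is allowed; otherwise the profile is reported unassigned.

The lattice parameter is reported both as the regression slope and as
the per-reflection mean of d = 2π√N/q; the two agree on consistent
data and both are exposed.

### Geometry

The water-channel radius of a bicontinuous cubic phase uses the
minimal-surface relation r_w = √(−A₀/(2πχ))·d − l with the standard
surface constants (*Pn3m*: A₀ = 1.919, χ = −2; *Im3m*: A₀ = 2.345,
χ = −4; *Ia3d*: A₀ = 3.091, χ = −8). The hydrophobic chain length
defaults to l = 1.8 nm (GMO) and is caller-overridable. A non-positive
radius is returned flagged as unphysical rather than raised — it simply
means the lattice cannot host a water channel at the assumed l.

For the sponge phase, d_s = (2π/q₁)·√2 treats the broad correlation
peak as the melted remnant of the lowest cubic (110) reflection, and
r_w(s) = (d_s/d_c)·r_w(c) scales the channel radius from a reference
cubic phase (the one formed at slightly lower ethanol content). The
caller must supply that reference; there is no universal default.

### Dilution series

`analyze_series` orders profiles by decreasing ethanol fraction (the
direction dialysis drives the system), indexes each, reports every
L3→cubic transition at the ethanol fraction where the cubic phase first
appears, and classifies the trend of the cubic lattice parameter versus
ethanol as increasing / decreasing / non-monotone.

## Single-particle Raman pipeline

The chain runs in a fixed order, and each stage stamps a flag on the
spectrum that blocks accidental double application:

1. **Cosmic-spike removal** (limit 40). Spikes are flagged where the
   modified z-score (0.6745·(x − median)/MAD) of the first *or* second
   difference of the trace exceeds the limit; the second difference is
   the sensitive detector for isolated single-channel spikes, while the
   first difference catches the edges of two-to-three-channel runs,
   whose second differences partially cancel. Flagged runs, dilated by
   one channel, are bridged by linear interpolation from the nearest
   clean channels.
2. **Blank subtraction**: intensity − 0.95 × averaged blank,
   elementwise, on an identical grid.
3. **Truncation** to the 416–1800 cm⁻¹ region of interest.
4. **Baseline correction**: asymmetric least squares (a Whittaker-type
   penalized smoother with asymmetric weights), penalty weight
   λ = 10^smoothness with smoothness 7, difference order 2. The
   "smoothness factor 7" of the originating acquisition software is
   read as the decadic exponent — the conventional log-scale
   parametrization of Whittaker penalties; the vendor's exact algorithm
   is not public, so this mapping is a documented choice. The
   asymmetry parameter is p = 0.05 with up to 30 reweighting
   iterations: at the more aggressive p = 0.01 the converged baseline
   undershoots a smooth band-free input by about 2% of its range,
   while p = 0.05 keeps that residual under 1% and still recovers
   planted band heights to better than 1%. The banded system is solved
   by banded Cholesky (the penalty matrix is pentadiagonal), which
   keeps a 200-spectrum batch under a second.
5. **Smoothing**: Savitzky–Golay, order 2, window 7.
6. **Normalization**: the trapezoidal integral over the ROI is set to
   1; all downstream band areas are therefore in normalized units.

Band areas are trapezoidal integrals over closed intervals with the
end points included exactly by linear interpolation, so the
1000–1007 cm⁻¹ protein area does not depend on grid alignment. No
local baseline is re-subtracted under the band (spectra are already
baselined).

**Subpopulation removal.** Lipid-containing samples show a minority
population (roughly 7–15% of trapped particles) distinguished by a band
near 965 cm⁻¹ that interferes with the protein readout. Particles whose
integrated 955–975 cm⁻¹ area exceeds a threshold are split off before
scoring. The threshold has no published value; the default (0.03 in
normalized-area units) was calibrated on the synthetic fixture, where
planted subpopulation particles integrate to 0.08–0.09 and the main
population stays below 0.011, and it is an explicit config parameter
for real data.

**Classification.** The threshold is the nearest-rank percentile
(default 95th) of the pure-reference protein areas: the smallest
reference value with at least 95% of the reference at or below it. A
particle is hybrid iff its area is *strictly greater* (ties count as
pure, matching the "exceeds" convention). With continuous areas and
n = 200 this leaves exactly 5% of the reference itself above its own
threshold — the designed type-I rate, which also means a measured
hybrid fraction runs above the true one by about 0.05·(1 − f). The
fraction's 95% CI is a percentile bootstrap over particles (2000
seeded resamples). Classification is invariant under any strictly
monotone rescaling applied identically to sample and reference areas,
since only ranks enter.

The instrument's spectral response correction and empty-trap removal
are instrument-specific and are modeled as identity.

## Assay formulas

- **Dye leakage**: Φ = (I_sample − I_AVs)/(I_TX − I_AVs) × 100, with
  the intact-vesicle and detergent-lysed fluorescence as the 0% and
  100% anchors. Values outside [0, 100] are returned unclipped with a
  flag — residual self-quenching can legitimately cross either anchor.
  The formula is invariant to a common offset or scale on all three
  intensities.
- **Enzymatic activity retention**: per-timepoint ratio of
  baseline-subtracted 415 nm absorbances, hybrid over native, averaged
  over usable timepoints × 100, with the standard error over
  timepoints and replicates. t = 0 and any timepoint whose native
  signal does not exceed baseline are excluded (zero-denominator
  points carry no information); excluding every timepoint is an error.
  The underlying protocol's prose describes a native-to-hybrid ratio,
  but the quantity reported alongside it ("reduced to 32% of native")
  is hybrid-to-native; the implementation computes hybrid/native.
- **Outlet ethanol fraction**: 100/(1 + FRR) for a water-to-ethanol
  flow-rate ratio FRR; strictly decreasing in FRR.
- **Domain shape statistics**: connected components (8-connectivity)
  of a binary mask; per-domain area, equivalent-circle diameter
  2√(A/π), perimeter, circularity 4πA/P² clipped at 1. The perimeter
  is the length of the marching-squares sub-pixel contour after a
  short circular moving average (7 contour points). The raw
  marching-squares polygon overestimates smooth boundaries by ~6%
  (every pixel crossing adds a zig-zag) and chain-code estimators do
  the same, which biases disk circularity to ~0.91; the light
  smoothing restores rasterized disks to 0.997–0.998 and 2:1 ellipses
  to within 0.003 of the Ramanujan-perimeter value while barely
  rounding true corners (a large square reads 0.794 against the
  analytic π/4 ≈ 0.785). Perimeters of shapes much smaller than ~10 px
  across remain approximate.

## Synthetic forward models

The generators define the test conditions; all randomness flows from a
single integer seed per call, and identical specs give bit-identical
output.

- **SAXS**: Lorentzian reflections (FWHM 0.03 nm⁻¹, typical of
  finite-domain Bragg broadening) at the allowed q_hkl, amplitudes
  decaying as 1/(1+order) unless overridden, on a q⁻² power-law
  background (diffuse particle scattering), with multiplicative
  Gaussian noise. The grid defaults to the instrument range
  0.054–3.232 nm⁻¹. The L3 profile is a single broad Lorentzian (FWHM
  ≥ 0.15 nm⁻¹) at 2π√2/d_s with an optional weak high-q bump. A spec
  whose grid misses the first reflection is rejected as unindexable.
- **Raman**: Gaussian bands; the lipid set at 1300/1445/1650 cm⁻¹ and
  the vesicle (EV) set at 700/715/1000/1660 cm⁻¹, so hybrids carry
  both sets and pure particles only the lipid set; an optional planted
  subpopulation adds a 965 cm⁻¹ band. Particles are drawn hybrid with
  the planted probability (a Bernoulli process — the realized count is
  binomial, not fixed). Spectra sit on a shared degree-3 polynomial
  fluorescence baseline with per-particle log-normal intensity scatter
  (σ = 0.15, emulating trap-position and size variation), additive
  Gaussian counting noise, and Poisson-count cosmic spikes of ≥ 100×
  the noise SD at random channels. Defaults (n = 200 particles, 63%
  hybrids, ~1600 channels over 300–1900 cm⁻¹) mirror the scale of a
  real single-particle session.
- **Masks**: non-overlapping ellipses rasterized on a canvas, returned
  with analytic area (πab), Ramanujan perimeter, circularity, and
  equivalent diameter; overlap or out-of-canvas placement raises, so
  planted statistics stay exact.
- **Activity series**: linear absorbance growth in time for the native
  sample and a planted multiple of it for the hybrid, with optional
  Gaussian noise and replicates.

What the generators deliberately do **not** model: real scattering
physics (form factors, instrumental smearing, absolute intensities),
resolution effects, detector artifacts beyond single-channel spikes,
Raman band shape details (Lorentzian/Voigt profiles, band overlap
chemistry), optical-trapping selection biases, or spatial correlation
in micrographs. Passing tests therefore demonstrate that the analysis
chain is correct and self-consistent under controlled conditions — not
that it is robust to every artifact of real instruments.

## Problem sizes and determinism

The test suite runs synthetic populations of 60–200 particles and
profile grids of ~1200 points; the hybrid-fraction recovery study uses
20 seeds × 190 particles per planted fraction with a fresh 200-particle
pure reference per seed — the scale at which the binomial error budget
of a real single-session measurement applies. All stochastic tests and
the bootstrap are seeded; CLI reports round floats to 6 significant
digits and echo their full configuration, so identical configs and
seeds reproduce byte-identical reports.

## Known limitations

- Indexing anchors the lowest detected peak on the first allowed
  reflection; if the first reflection is genuinely outside the
  measured q-range the assignment fails rather than sliding the
  anchor. Hexagonal and micellar cubic (Fd3m) phases are out of scope.
- The sponge-phase channel radius requires a caller-supplied reference
  cubic; published reference lattices for specific ethanol fractions
  are not bundled.
- The AsLS baseline mapping ("smoothness 7" → λ = 10⁷, p = 0.05) is a
  documented reading of a closed-source preprocessing chain, not a
  reimplementation of it; absolute band areas from differently
  configured software will differ even though threshold-based
  classification, which only uses ranks, is insensitive to monotone
  distortions shared by sample and reference.
- The percentile classifier's ~5% false-positive rate is structural;
  measured hybrid fractions are upper-biased by 0.05·(1 − f) and no
  correction is applied, matching the originating protocol.
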
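# Methods

## Spectral templates

Each built-in spectrum is a truncated Fourier series
`F(θ) = a0 + Σₖ (aₖ cos kθ + bₖ sin kθ)` over half a period (θ ∈ [0, π]) of
a mapped wavelength axis. The mapping and post-scale differ by template
class and are stored with the coefficients in the bundled registry
(`data/coefficients.json`, schema versioned):

| template | order | axis | support (nm) | post-scale | outside support |
|---|---|---|---|---|---|
| L, M, S absorbance | 8 | log10 λ | 360–850 | `s` added (log units) | error |
| L(ser180), common | 8 | log10 λ | 360–850 | `s` added | error |
| macular density | 11 | linear λ | 375–550 | `d` multiplied | exactly 0 |
| lens density | 9 | linear λ | 360–660 | `d` multiplied | exactly 0 |

Half a period is used because the spectra differ at their two ends; a full
2π period would force them equal. The additive `s` and multiplicative `d`
renormalisations are not interchangeable and are encoded per template: `s`
lives inside the log-domain expression, `d` scales the density polynomial.
Density values are clamped at 0 from below (the fitted polynomials dip
negative by < 0.005 near their edges); log-absorbance values are never
clamped. Absorbance templates raise outside 360–850 nm rather than
extrapolate; density templates return exactly 0 outside their fitted
support, in line with the assumption that both pigments are transparent
there.

The θ mapping computes the unit fraction of the axis before multiplying by
π, so θ is exactly 0 and π at the support endpoints; a 1e-6 nm tolerance
absorbs floating-point rounding when shifted supports are sampled at their
edges.

## Peak location

`find_lambda_max` evaluates the linear spectrum on a uniform grid at 0.1 nm
(default) over the template support and reports the argmax, rounded to the
grid, ties broken toward shorter wavelengths. At this resolution the mean
absorbance templates peak at 551.9 (L), 529.8 (M) and 417.0 nm (S); the
S-cone value is one grid step from the commonly quoted 416.9 nm — the
template's value at 417.0 exceeds that at 416.9 by ~1e-6 log units, so the
difference is a rounding convention, not a model difference.

## Individual variation

Shifts are translations on the log10-wavelength axis: the shifted spectrum
at λ equals the base spectrum at λ·10^(−Δ), so the peak moves from λ_ref to
λ_ref·10^Δ and shifts compose additively. Shifts quoted in nm are converted
at a reference peak via Δ = log10((λ_ref + shift)/λ_ref), using the mean
template peaks (551.9, 529.8, 416.9 nm) as references.

Genotype-derived shifts combine additively across the seven spectrally
active L/M opsin codons (116, 180, 230, 233, 277, 285, 309; 233 and 309 are
spectrally silent). The published per-site shifts are slightly asymmetric
between the M→L and L→M directions, and the codon-180 table value (−4 nm
for L→M) differs from the 2.7 nm used for the L(ser180)/L(ala180)
polymorphic templates; the genotype pathway uses the table, the polymorphic
templates use 2.7 nm (0.002125 log10 nm), and both are exposed as distinct
APIs rather than reconciled.

Mixtures are formed in linear absorbance with non-negative weights summing
to 1, then rescaled to unit peak (peak located at 0.1 nm over the common
support). The population-mean L from the common template weights the copy
shifted by −0.002108 log10 nm at 0.56 and the unshifted copy at 0.44, which
reproduces the published combined peak of 556.0 nm; note the plain
0.44-shifted/0.56-unshifted reading would give 556.3 nm. The `mean` L
variant in observer parameters uses the mean L template directly (it is
already the population mix); explicit re-mixing of the polymorphic pair is
available. The common template is a deliberate compromise fit (its
per-cone peaks 557.5/527.3/418.5 nm differ from the individual templates)
and is kept out of the standard-observer pipeline.

## Fundamentals pipeline

Per cone: template selection (variant + shift) → linear absorbance →
absorptance `1 − 10^(−OD·A)` (self-screening: larger OD broadens the curve
but cannot move its argmax, since the transform is pointwise monotone) →
multiplication by `10^(−[k_lens·lens + k_mac·mac])` (the exponent is
negative: the filters attenuate) → optional energy conversion (×λ) → unit-
peak normalisation. Quantal outputs are normalised too, for symmetry, with
the applied scale recorded as the set's α. Normalisation divides by the
grid peak, so the peak sample is exactly 1.0 in IEEE arithmetic.

Default grid: 390–830 nm at 1 nm, the standard tabulation range. The full
360–850 nm support is available but rests on extrapolated measurements at
both ends and should be used with caution; reference comparisons exclude
λ < 400 nm by default because the templates deliberately depart from the
tabulated standard there.

Observer parameters and defaults: peak photopigment optical densities in
(0, 2] log units, standard (0.50, 0.50, 0.40) at 2 deg and
(0.38, 0.38, 0.30) at 10 deg; k_mac 1 / 0.271 and k_lens 1. Macular and
lens scalings may equivalently be given as anchor densities (D460/0.350,
D400/1.7649). The 10-deg macular value at 460 nm is defined as the product
0.271 × 0.350 ≈ 0.0949 rather than an independently rounded 0.095.
Age-dependent lens-shape models and eccentricity-resolved macular profiles
are out of scope; filtering is a scalar per pigment.

## Colorimetry

Tristimulus integration uses the rectangle rule on the uniform grid
(Σ P·cmf·Δλ), matching discrete tabulation practice; energy-unit power
spectra must meet energy-unit CMFs (units are tagged and checked).
Transformed CMFs are not renormalised — the published matrices embed their
scaling conventions (blue column of the RGB→LMS matrix normalised to 1,
S-cone response to the red primary exactly 0, ȳ a non-negative combination
of l̄ and m̄, z̄ a pure scaling of s̄). Matrix inverses are computed
numerically; round trips hold to better than 1e-10. User primary sets are
supported either as monochromatic wavelengths (columns are the fundamentals
at those wavelengths) or as broadband power spectra (columns are
integrals).

## Synthetic fixtures

`make_fixtures` emulates the small inputs the I/O paths consume: narrowband
Gaussian power spectra (representative of LED-like stimuli; they do not
model real illuminant structure), random positive tristimuli, and a
5-nm-step, truncated, slightly perturbed copy of the generated standard
table to exercise reading, masking and MAE reporting. These exercise the
plumbing, not the physiology: passing them says nothing about agreement
with externally tabulated standards, which requires a reference CSV via
`compare`.

## Numerical notes and limitations

- Fourier coefficients are stored exactly as published (6 decimals) and
  never re-derived; density-template coefficients reach ~7×10³, so
  evaluation carries cancellation roundoff of order 1e-12 — comparisons
  against the term-by-term oracle allow for this.
- Peak searches at 0.1 nm cost ~5k evaluations per template; all quantities
  in the acceptance script are deterministic.
- Written tables carry 8 decimal places.
- The generated S-cone absorbance smooths a small perturbation present in
  the tabulated standard near 480–510 nm; external comparisons will show
  this as structured residual.
- Luminous efficiency functions, rod/melanopsin spectra, MacLeod–Boynton
  and appearance spaces are out of scope.
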
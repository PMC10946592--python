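# conefund

Continuous, closed-form human cone spectral sensitivities — and the
colorimetry built on them — for standard and individualized observers.

Photopic color vision starts with the quantum catches of the long- (L),
middle- (M) and short-wavelength-sensitive (S) cones. The standard
"physiologically relevant" cone fundamentals are published as discrete
tables at fixed wavelength steps, which makes it awkward to resample them,
to shift a photopigment's peak for an individual observer, or to vary the
ocular media. `conefund` replaces the tables with closed-form templates:
8th-order Fourier polynomials for the log10 photopigment absorbance spectra
on a log10-wavelength axis (360–850 nm), and 11th/9th-order Fourier
polynomials for the macular and lens pigment density spectra on a linear
axis. From these it assembles corneal cone fundamentals for any observer and
transforms them into other color-matching spaces.

## Model

Photopigment absorbance templates are evaluated as

    log10 A(λ) = a0 + Σₖ [ aₖ cos kθ + bₖ sin kθ ] + s,
    θ = π · log10(λ/360) / log10(850/360),

with per-cone coefficient sets (the additive `s` puts the linear peak at 1).
The corneal fundamental of a cone with peak axial photopigment optical
density OD behind lens and macular filtering is

    l̄_Q(λ) = [1 − 10^(−OD·A(λ))] · 10^(−[k_lens·lens(λ) + k_mac·mac(λ)]),
    l̄(λ)  = α · λ · l̄_Q(λ)            (energy units, unit peak),

where `lens(λ)` and `mac(λ)` are the standard density spectra (anchored at
1.7649 at 400 nm and 0.350 at 460 nm) and `k_lens`, `k_mac` scale them per
observer. Standard observers: 2-deg ODs (0.50, 0.50, 0.40) with k_mac = 1;
10-deg ODs (0.38, 0.38, 0.30) with k_mac = 0.271.

Because the absorbance templates live on a log-wavelength axis, an
individual's shifted photopigment is the same template translated by
log10(λ_max,new/λ_max,ref): the package derives such shifts from L/M opsin
genotypes (additive per-codon peak shifts at the seven spectrally active
codons), provides the L(ser180)/L(ala180) polymorphic templates (peaks
553.1/550.4 nm) and a common shape-invariant template, and mixes variants in
linear absorbance. Fundamentals convert exactly to Stiles–Burch 10-deg RGB
and to 2-deg/10-deg XYZ via the published 3×3 matrices, with chromaticity
projection (l,m / r,g / x,y) and tristimulus integration for arbitrary
lights.

## Worked example

```python
from conefund import compute_fundamentals, find_lambda_max, standard_observer

fund = compute_fundamentals(standard_observer("deg2"))   # 390-830 nm, 1 nm
for name, chan in fund.channels().items():
    print(name, find_lambda_max(chan))
```

prints the corneal peak wavelengths of the standard 2-deg observer,

```
L 569.0
M 544.0
S 443.0
```

i.e. the L, M and S fundamentals peak at 569, 544 and 443 nm — longward of
the underlying absorbance peaks (551.9, 529.8, 417.0 nm) because the inert
pigments absorb short wavelengths and energy units weight long wavelengths.
Integrating a narrowband 580-nm Gaussian light against these fundamentals
(`examples/space_transforms.py`) gives LMS tristimulus values
(35.50, 24.22, 0.0116), chromaticity (l, m) = (0.5943, 0.4055) and
XYZ = (34.88, 32.93, 0.0225): a yellowish-orange light that excites L
slightly more than M and S hardly at all. The other scripts in `examples/`
cover individualized observers, genotype-derived shifts, and the spectrum
locus in the three chromaticity spaces.

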
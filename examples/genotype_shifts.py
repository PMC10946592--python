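"""Spectral shifts of hybrid and polymorphic L/M opsins.

Each genotype string names a backbone opsin (L or M) and residue
substitutions at the seven spectrally active codons; the per-codon peak
shifts combine additively. The resulting shift is converted to log10
wavelength units and applied to the backbone absorbance template, moving its
peak by the stated amount.
"""

from conefund import genotype_shift_nm, genotype_template, parse_genotype
from conefund.variation import LAMBDA_MAX_REFERENCE

for text in ("M[A285T]", "M[A180S]", "L[S180A]", "L[Y277F,T285A]", "M"):
    g = parse_genotype(text)
    nm = genotype_shift_nm(g)
    peak = genotype_template(g).lambda_max()
    print(f"{text:16s} base {g.base} ({LAMBDA_MAX_REFERENCE[g.base]} nm) "
          f"shift {nm:+5.1f} nm -> template peak {peak:.1f} nm")
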
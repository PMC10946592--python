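"""Individual variation: spectral shifts, opsin genotypes, and L-cone variants.

Photopigment absorbance spectra are approximately shape-invariant when
plotted against log10 wavelength, so an individual's spectrum with a
different peak wavelength is modelled by translating a template along that
axis: a shift of ``delta`` log10 nm means the shifted spectrum at wavelength
``l`` equals the base spectrum at ``l * 10**(-delta)``. Positive shifts move
the peak to longer wavelengths.

Shifts are commonly quoted in nm at the peak; the log-axis shift between two
peaks is log10(lmax1 / lmax2), and in phase-angle units of the 360-850 nm
log axis, pi * log10(lmax1/lmax2) / log10(850/360).

The L-cone opsin gene is polymorphic: the common serine/alanine substitution
at codon 180 shifts the peak by 2.7 nm (0.002125 log10 nm), and L/M hybrid
opsins produced by intragenic crossover carry mixtures of L- and M-type
residues at seven spectrally active codons whose per-site peak shifts are
tabulated here and combined additively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import re

import numpy as np

from .templates import FourierTemplate, builtin_template, find_lambda_max, _grid

__all__ = [
    "ShiftedTemplate",
    "MixtureTemplate",
    "GenotypeSpec",
    "delta_theta",
    "shift_template",
    "shift_for_peaks",
    "nm_shift_to_log10",
    "genotype_shift_nm",
    "genotype_template",
    "parse_genotype",
    "polymorphic_L",
    "mix_templates",
    "common_template_shifted",
    "combined_common_L",
    "SER_ALA_SHIFT_LOG10",
    "COMMON_ALA_SHIFT_LOG10",
    "COMMON_M_SHIFT_LOG10",
    "COMMON_S_SHIFT_LOG10",
    "SPECTRAL_CODON_SHIFTS",
    "LAMBDA_MAX_REFERENCE",
]

_LOG_SPAN = np.log10(850.0 / 360.0)

#: log10-nm shift between the L(ser180) and L(ala180) polymorphic templates
#: (2.7 nm at the L(ser180) peak of 553.1 nm).
SER_ALA_SHIFT_LOG10 = 0.002125
#: Shifts of the common shape-invariant template (aligned to L(ser180),
#: peak 557.5 nm) that best fit the other spectra.
COMMON_ALA_SHIFT_LOG10 = -0.002108
COMMON_M_SHIFT_LOG10 = -0.024187
COMMON_S_SHIFT_LOG10 = -0.124549

#: Peak wavelengths of the mean absorbance templates, used as reference
#: points when converting nm shifts to log10 units.
LAMBDA_MAX_REFERENCE = {"L": 551.9, "M": 529.8, "S": 416.9}

#: Per-codon peak shifts in nm for the seven spectrally relevant L/M opsin
#: codons: value when an M opsin carries the L-type residue (M->L) and when
#: an L opsin carries the M-type residue (L->M). Codons 233 and 309 are
#: spectrally silent. Residues are (M-type, L-type) one-letter codes.
SPECTRAL_CODON_SHIFTS = {
    116: {"residues": ("Y", "S"), "M_to_L": 0.0, "L_to_M": -3.0},
    180: {"residues": ("A", "S"), "M_to_L": 3.0, "L_to_M": -4.0},
    230: {"residues": ("T", "I"), "M_to_L": 3.0, "L_to_M": -3.0},
    233: {"residues": ("S", "A"), "M_to_L": 0.0, "L_to_M": 0.0},
    277: {"residues": ("F", "Y"), "M_to_L": 7.0, "L_to_M": -7.0},
    285: {"residues": ("A", "T"), "M_to_L": 14.0, "L_to_M": -14.0},
    309: {"residues": ("F", "Y"), "M_to_L": 0.0, "L_to_M": 0.0},
}


# ----------------------------------------------------------------------
# Shift arithmetic
# ----------------------------------------------------------------------

def delta_theta(lambda_max_1: float, lambda_max_2: float) -> float:
    """Phase-angle shift between two peak wavelengths on the log axis."""
    for lm in (lambda_max_1, lambda_max_2):
        if not 360.0 < lm < 850.0:
            raise ValueError("peak wavelengths must lie within (360, 850) nm")
    return float(np.pi * np.log10(lambda_max_1 / lambda_max_2) / _LOG_SPAN)


def shift_for_peaks(lambda_max_new: float, lambda_max_ref: float) -> float:
    """log10-nm shift that moves a peak from lambda_max_ref to lambda_max_new."""
    return float(np.log10(lambda_max_new / lambda_max_ref))


def nm_shift_to_log10(shift_nm: float, lambda_max_ref: float) -> float:
    """Convert a peak shift in nm (at the reference peak) to log10 units."""
    return shift_for_peaks(lambda_max_ref + shift_nm, lambda_max_ref)


# ----------------------------------------------------------------------
# Shifted and mixed absorbance evaluators
# ----------------------------------------------------------------------

class ShiftedTemplate:
    """An absorbance template translated along the log10-wavelength axis."""

    def __init__(self, base, delta_log10_nm: float):
        if not getattr(base, "is_absorbance", False):
            raise TypeError("only absorbance templates can be spectrally shifted")
        self.base = base
        self.delta_log10_nm = float(delta_log10_nm)

    is_absorbance = True

    @property
    def name(self) -> str:
        return f"{self.base.name}{self.delta_log10_nm:+g}log10nm"

    @property
    def support(self) -> tuple:
        lo, hi = self.base.support
        f = 10.0 ** self.delta_log10_nm
        return (lo * f, hi * f)

    def log_absorbance(self, lambda_nm):
        lam = np.asarray(lambda_nm, dtype=float)
        return self.base.log_absorbance(lam * 10.0 ** (-self.delta_log10_nm))

    def linear_absorbance(self, lambda_nm):
        return np.power(10.0, self.log_absorbance(lambda_nm))

    def shift(self, delta_log10_nm: float) -> "ShiftedTemplate":
        return ShiftedTemplate(self.base, self.delta_log10_nm + delta_log10_nm)

    def lambda_max(self, resolution: float = 0.1) -> float:
        return find_lambda_max(self, resolution=resolution)


def shift_template(template, delta_log10_nm: float) -> ShiftedTemplate:
    """Shift an absorbance template by ``delta_log10_nm`` along log10 wavelength.

    The shifted evaluator's value at wavelength ``l`` equals the base value at
    ``l * 10**(-delta)``; its peak moves to ``lambda_max * 10**delta``.
    Compositions add: shifting a shifted template accumulates the deltas.
    """
    if isinstance(template, ShiftedTemplate):
        return template.shift(delta_log10_nm)
    return ShiftedTemplate(template, delta_log10_nm)


class MixtureTemplate:
    """Weighted linear-absorbance mixture of templates, unit-peak normalised.

    Mixing is performed in linear absorbance (weights non-negative, summing
    to 1) and the result rescaled so its peak, located at 0.1 nm resolution
    over the common support, is exactly 1.
    """

    def __init__(self, components, weights, resolution: float = 0.1):
        weights = [float(w) for w in weights]
        if len(components) != len(weights) or not components:
            raise ValueError("need one weight per component")
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if not all(getattr(c, "is_absorbance", False) for c in components):
            raise TypeError("mixture components must be absorbance templates")
        self.components = tuple(components)
        self.weights = tuple(weights)
        lo = max(c.support[0] for c in components)
        hi = min(c.support[1] for c in components)
        if not lo < hi:
            raise ValueError("component supports do not overlap")
        self._support = (lo, hi)
        lam = _grid(lo, hi, resolution)
        raw = self._raw_linear(lam)
        i = int(np.argmax(raw))
        self._peak_scale = 1.0 / float(raw[i])
        decimals = max(0, int(round(-np.log10(resolution))))
        self._lambda_max = float(np.round(lam[i], decimals))

    is_absorbance = True
    name = "mixture"

    @property
    def support(self) -> tuple:
        return self._support

    def _raw_linear(self, lambda_nm):
        lam = np.asarray(lambda_nm, dtype=float)
        out = np.zeros_like(lam, dtype=float)
        for w, c in zip(self.weights, self.components):
            out = out + w * c.linear_absorbance(lam)
        return out

    def linear_absorbance(self, lambda_nm):
        out = self._peak_scale * self._raw_linear(lambda_nm)
        return float(out) if np.ndim(lambda_nm) == 0 else out

    def log_absorbance(self, lambda_nm):
        return np.log10(self.linear_absorbance(lambda_nm))

    def lambda_max(self, resolution: float = 0.1) -> float:
        if resolution == 0.1:
            return self._lambda_max
        return find_lambda_max(self, resolution=resolution)


def mix_templates(components, weights) -> MixtureTemplate:
    """Linear-absorbance mixture of absorbance templates (unit-peak)."""
    return MixtureTemplate(components, weights)


# ----------------------------------------------------------------------
# Polymorphic and common L templates
# ----------------------------------------------------------------------

def polymorphic_L(variant: str):
    """The L(ser180) or L(ala180) polymorphic absorbance template.

    ``ser180`` is the fitted template (peak 553.1 nm); ``ala180`` is the same
    template shifted 0.002125 log10 nm toward shorter wavelengths
    (peak 550.4 nm).
    """
    base = builtin_template("L_ser180_poly")
    if variant == "ser180":
        return base
    if variant == "ala180":
        return shift_template(base, -SER_ALA_SHIFT_LOG10)
    raise ValueError("variant must be 'ser180' or 'ala180'")


def common_template_shifted(cone: str):
    """The common shape-invariant template shifted to a given cone class.

    ``L`` (ser180-aligned, unshifted, peak 557.5 nm), ``L_ala180``
    (-0.002108 log10 nm, peak 554.8 nm), ``M`` (-0.024187, peak 527.3 nm) or
    ``S`` (-0.124549, peak 418.5 nm). Not CIE-compliant; the per-cone
    templates should be used where compliance with the standard is required.
    """
    base = builtin_template("L_common")
    shifts = {
        "L": 0.0,
        "L_ser180": 0.0,
        "L_ala180": COMMON_ALA_SHIFT_LOG10,
        "M": COMMON_M_SHIFT_LOG10,
        "S": COMMON_S_SHIFT_LOG10,
    }
    if cone not in shifts:
        raise ValueError(f"cone must be one of {sorted(shifts)}")
    if shifts[cone] == 0.0:
        return base
    return shift_template(base, shifts[cone])


def combined_common_L() -> MixtureTemplate:
    """Population-mean L built from the common template's two L variants.

    A 0.44:0.56 linear-absorbance mixture of the unshifted common template
    and its copy shifted by -0.002108 log10 nm, the shifted copy carrying the
    0.56 weight; the mixture peaks at 556.0 nm.
    """
    base = builtin_template("L_common")
    shifted = shift_template(base, COMMON_ALA_SHIFT_LOG10)
    return mix_templates([base, shifted], [0.44, 0.56])


# ----------------------------------------------------------------------
# Genotypes
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeSpec:
    """An L/M opsin described by its residue state at the spectral codons.

    ``base`` is the backbone opsin ('L' or 'M'); ``states`` maps codon number
    to 'L_like' or 'M_like'. Unlisted codons take the base's own state.
    """

    base: str
    states: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.base not in ("L", "M"):
            raise ValueError("base must be 'L' or 'M'")
        for codon, state in self.states.items():
            if codon not in SPECTRAL_CODON_SHIFTS:
                raise ValueError(f"codon {codon} is not a spectral codon")
            if state not in ("L_like", "M_like"):
                raise ValueError(f"bad residue state {state!r}")


def genotype_shift_nm(genotype: GenotypeSpec) -> float:
    """Peak shift in nm of a genotype relative to its base opsin.

    Per-codon shifts combine additively: for an M backbone, each L-type
    residue contributes its M->L shift; for an L backbone, each M-type
    residue contributes its (signed) L->M shift.
    """
    total = 0.0
    for codon, state in genotype.states.items():
        row = SPECTRAL_CODON_SHIFTS[codon]
        if genotype.base == "M" and state == "L_like":
            total += row["M_to_L"]
        elif genotype.base == "L" and state == "M_like":
            total += row["L_to_M"]
    return total


_GENO_RE = re.compile(r"^([LM])(?:\[([^\]]*)\])?$")
_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_genotype(text: str) -> GenotypeSpec:
    """Parse a genotype string such as ``M[A285T]`` or ``L[S180A,Y277F]``.

    The base letter names the backbone opsin; each bracketed token is a
    substitution ``<from><codon><to>`` at one of the seven spectral codons,
    where ``from`` must be the backbone's native residue and ``to`` the other
    opsin's residue at that codon.
    """
    m = _GENO_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse genotype {text!r}")
    base, subs = m.group(1), m.group(2)
    states: dict = {}
    if subs:
        for token in filter(None, (t.strip() for t in subs.split(","))):
            sm = _SUB_RE.match(token)
            if not sm:
                raise ValueError(f"cannot parse substitution {token!r}")
            aa_from, codon, aa_to = sm.group(1), int(sm.group(2)), sm.group(3)
            if codon not in SPECTRAL_CODON_SHIFTS:
                raise ValueError(f"codon {codon} is not a spectral codon")
            m_res, l_res = SPECTRAL_CODON_SHIFTS[codon]["residues"]
            native = m_res if base == "M" else l_res
            other = l_res if base == "M" else m_res
            if aa_from != native:
                raise ValueError(
                    f"{token}: {base} opsin residue at codon {codon} is {native}, not {aa_from}")
            if aa_to != other:
                raise ValueError(
                    f"{token}: substituted residue at codon {codon} should be {other}")
            states[codon] = "L_like" if base == "M" else "M_like"
    return GenotypeSpec(base=base, states=states)


def genotype_template(genotype: GenotypeSpec):
    """Absorbance template for a genotype: the base template shifted by the
    additive codon shift converted to log10 units at the base peak."""
    shift_nm = genotype_shift_nm(genotype)
    base = builtin_template(genotype.base)
    if shift_nm == 0.0:
        return base
    delta = nm_shift_to_log10(shift_nm, LAMBDA_MAX_REFERENCE[genotype.base])
    return shift_template(base, delta)
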
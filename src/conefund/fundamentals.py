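"""Corneal cone fundamentals for standard and individual observers.

Pipeline per cone class: linear photopigment absorbance A(l) (from a
template, possibly spectrally shifted) -> absorptance of an outer segment of
peak axial optical density OD, 1 - 10**(-OD * A(l)) (self-screening: higher
OD broadens the spectrum without moving its peak) -> attenuation by the lens
and macular pigments, * 10**(-[k_lens*lens(l) + k_mac*mac(l)]) -> quantal
corneal sensitivity; energy-unit sensitivity is the quantal curve multiplied
by wavelength and renormalised to unit peak.

Standard observers: 2-deg ODs (0.50, 0.50, 0.40) with k_mac = 1; 10-deg ODs
(0.38, 0.38, 0.30) with k_mac = 0.271; k_lens = 1 for both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .prereceptoral import FilterScaling, total_prereceptoral_density
from .templates import SpectralFunction, builtin_template, _grid
from .variation import (
    mix_templates,
    polymorphic_L,
    shift_template,
)

__all__ = [
    "ObserverParameters",
    "ConeFundamentalSet",
    "standard_observer",
    "absorptance",
    "corneal_quantal",
    "to_energy_normalized",
    "compute_fundamentals",
]


@dataclass(frozen=True)
class ObserverParameters:
    """Physiological parameters defining an observer's fundamentals.

    ``l_od``, ``m_od``, ``s_od`` are peak axial photopigment optical
    densities (log10 units, in (0, 2]); ``scaling`` the pre-receptoral filter
    multipliers; ``shift_l/m/s`` signed peak shifts in log10 nm; ``l_variant``
    selects the L photopigment: 'mean' (the population-average template),
    'ser180', 'ala180', or 'mixture' with weights ``l_mixture`` =
    (w_ala, w_ser) applied to the polymorphic pair.
    """

    field_label: str = "custom"
    l_od: float = 0.50
    m_od: float = 0.50
    s_od: float = 0.40
    scaling: FilterScaling = field(default_factory=FilterScaling)
    shift_l: float = 0.0
    shift_m: float = 0.0
    shift_s: float = 0.0
    l_variant: str = "mean"
    l_mixture: tuple = (0.44, 0.56)

    def __post_init__(self) -> None:
        for od in (self.l_od, self.m_od, self.s_od):
            if not 0.0 < od <= 2.0:
                raise ValueError("photopigment optical densities must lie in (0, 2]")
        if self.l_variant not in ("mean", "ser180", "ala180", "mixture"):
            raise ValueError(f"unknown L variant {self.l_variant!r}")
        if self.l_variant == "mixture":
            w = self.l_mixture
            if len(w) != 2 or any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
                raise ValueError("l_mixture weights must be non-negative and sum to 1")


@dataclass(frozen=True)
class ConeFundamentalSet:
    """L, M, S spectral sensitivities on a shared grid plus normalisation.

    ``alpha_l/m/s`` are the scale factors that brought each curve to unit
    peak (applied to the raw pipeline output in the set's units).
    """

    L: SpectralFunction
    M: SpectralFunction
    S: SpectralFunction
    units: str  # 'quantal' | 'energy'
    alpha_l: float
    alpha_m: float
    alpha_s: float
    observer: ObserverParameters

    @property
    def wavelengths(self) -> np.ndarray:
        return self.L.wavelengths

    def channels(self):
        return {"L": self.L, "M": self.M, "S": self.S}


def standard_observer(fov: str) -> ObserverParameters:
    """The standard mean observer for 'deg2' or 'deg10' viewing."""
    if fov in ("deg2", "2", 2):
        return ObserverParameters(field_label="2-deg standard",
                                  l_od=0.50, m_od=0.50, s_od=0.40,
                                  scaling=FilterScaling(k_mac=1.0, k_lens=1.0))
    if fov in ("deg10", "10", 10):
        return ObserverParameters(field_label="10-deg standard",
                                  l_od=0.38, m_od=0.38, s_od=0.30,
                                  scaling=FilterScaling(k_mac=0.271, k_lens=1.0))
    raise ValueError("field must be 'deg2' or 'deg10'")


def absorptance(absorbance: SpectralFunction, od: float) -> SpectralFunction:
    """Photopigment absorptance 1 - 10**(-od * A) from linear absorbance."""
    if od <= 0:
        raise ValueError("optical density must be positive")
    if absorbance.units != "linear_absorbance":
        raise ValueError("absorptance expects linear absorbance input")
    vals = 1.0 - np.power(10.0, -od * absorbance.values)
    return absorbance.with_values(vals, "quantal_sensitivity")


def corneal_quantal(absorpt: SpectralFunction,
                    scaling: FilterScaling = FilterScaling()) -> SpectralFunction:
    """Apply lens + macular filtering to an absorptance spectrum."""
    dens = total_prereceptoral_density(absorpt.wavelengths, scaling)
    vals = absorpt.values * np.power(10.0, -dens)
    return absorpt.with_values(vals, "quantal_sensitivity")


def _unit_peak(values: np.ndarray):
    peak = float(np.max(values))
    if peak <= 0:
        raise ValueError("cannot normalise an all-zero spectrum")
    return values / peak, 1.0 / peak


def to_energy_normalized(quantal: SpectralFunction):
    """Convert a quantal sensitivity to energy units, unit-peak normalised.

    Photon energy is inversely proportional to wavelength, so the energy-unit
    sensitivity is the quantal curve multiplied by wavelength, rescaled to
    peak at 1. Returns ``(spectrum, alpha)`` with alpha the applied scale.
    """
    if quantal.units != "quantal_sensitivity":
        raise ValueError("expected a quantal sensitivity spectrum")
    vals, alpha = _unit_peak(quantal.values * quantal.wavelengths)
    return quantal.with_values(vals, "energy_sensitivity"), alpha


def _l_template(observer: ObserverParameters):
    if observer.l_variant == "mean":
        return builtin_template("L")
    if observer.l_variant in ("ser180", "ala180"):
        return polymorphic_L(observer.l_variant)
    w_ala, w_ser = observer.l_mixture
    return mix_templates([polymorphic_L("ala180"), polymorphic_L("ser180")],
                         [w_ala, w_ser])


def compute_fundamentals(observer: ObserverParameters | None = None,
                         lambda_start: float = 390.0,
                         lambda_end: float = 830.0,
                         step: float = 1.0,
                         units: str = "energy") -> ConeFundamentalSet:
    """Corneal cone fundamentals for an observer on a uniform grid.

    The default grid (390-830 nm at 1 nm) matches the standard tabulation
    range; the templates extend from 360 to 850 nm, but the extensions rest
    on extrapolated data and should be used with caution. All returned
    channels are normalised to unit peak (quantal sets included; the applied
    scales are recorded as the set's alphas).
    """
    if observer is None:
        observer = standard_observer("deg2")
    if units not in ("quantal", "energy"):
        raise ValueError("units must be 'quantal' or 'energy'")
    lam = _grid(lambda_start, lambda_end, step)
    templates = {
        "L": (_l_template(observer), observer.l_od, observer.shift_l),
        "M": (builtin_template("M"), observer.m_od, observer.shift_m),
        "S": (builtin_template("S"), observer.s_od, observer.shift_s),
    }
    out = {}
    alphas = {}
    for cone, (tpl, od, shift) in templates.items():
        if shift != 0.0:
            tpl = shift_template(tpl, shift)
        lin = SpectralFunction(lambda_start, step, tpl.linear_absorbance(lam),
                               "linear_absorbance")
        quantal = corneal_quantal(absorptance(lin, od), observer.scaling)
        if units == "energy":
            spec, alpha = to_energy_normalized(quantal)
        else:
            vals, alpha = _unit_peak(quantal.values)
            spec = quantal.with_values(vals)
        out[cone] = spec
        alphas[cone] = alpha
    return ConeFundamentalSet(L=out["L"], M=out["M"], S=out["S"], units=units,
                              alpha_l=alphas["L"], alpha_m=alphas["M"],
                              alpha_s=alphas["S"], observer=observer)
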
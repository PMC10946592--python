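"""Pre-receptoral filtering: macular and lens pigment densities.

Light entering the eye passes through the lens and, near the fovea, the
macular pigment before reaching the photoreceptors. Both act as inert
short-wavelength-absorbing filters whose attenuation is expressed as a log10
optical density; densities add across filters and transmittance is
10**(-density).

Observer-specific filtering is a scalar rescaling of the standard density
spectra: ``k_mac`` (1 for the standard 2-deg observer, 0.271 for 10-deg,
where the macular pigment is sparser) and ``k_lens`` (1 for the standard
observer). Equivalently, users may quote the macular density at 460 nm
(standard 0.350) or the lens density at 400 nm (standard 1.7649); the
scalings are those anchors divided by the standard values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .templates import builtin_template

__all__ = [
    "FilterScaling",
    "MACULAR_D460_STANDARD",
    "LENS_D400_STANDARD",
    "macular_density",
    "lens_density",
    "total_prereceptoral_density",
    "transmittance",
]

#: Standard macular pigment density at 460 nm (2-deg observer).
MACULAR_D460_STANDARD = 0.350
#: Standard lens pigment density at 400 nm.
LENS_D400_STANDARD = 1.7649

_MACULAR = builtin_template("macular")
_LENS = builtin_template("lens")


@dataclass(frozen=True)
class FilterScaling:
    """Scalar multipliers on the standard macular and lens density spectra."""

    k_mac: float = 1.0
    k_lens: float = 1.0

    def __post_init__(self) -> None:
        if self.k_mac < 0 or self.k_lens < 0:
            raise ValueError("filter scalings must be non-negative")

    @classmethod
    def from_peak_densities(cls, d_mac_460: float | None = None,
                            d_lens_400: float | None = None) -> "FilterScaling":
        """Build scalings from anchor densities (460 nm macular, 400 nm lens)."""
        k_mac = 1.0 if d_mac_460 is None else d_mac_460 / MACULAR_D460_STANDARD
        k_lens = 1.0 if d_lens_400 is None else d_lens_400 / LENS_D400_STANDARD
        return cls(k_mac=k_mac, k_lens=k_lens)


def macular_density(lambda_nm, k_mac: float = 1.0):
    """Macular pigment optical density; zero outside 375-550 nm."""
    if k_mac < 0:
        raise ValueError("k_mac must be non-negative")
    return k_mac * _MACULAR.evaluate(lambda_nm)


def lens_density(lambda_nm, k_lens: float = 1.0):
    """Lens pigment optical density; zero above 660 nm."""
    if k_lens < 0:
        raise ValueError("k_lens must be non-negative")
    return k_lens * _LENS.evaluate(lambda_nm)


def total_prereceptoral_density(lambda_nm, scaling: FilterScaling = FilterScaling()):
    """Combined lens + macular optical density for an observer."""
    return (lens_density(lambda_nm, scaling.k_lens)
            + macular_density(lambda_nm, scaling.k_mac))


def transmittance(density):
    """Fraction of light transmitted through a filter of the given density."""
    d = np.asarray(density, dtype=float)
    if np.any(d < 0):
        raise ValueError("density must be non-negative")
    t = np.power(10.0, -d)
    return float(t) if t.ndim == 0 else t
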
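"""Tristimulus values of a light and exact color-space transformations.

Integrates a narrowband Gaussian light against the 2-deg fundamentals to get
its LMS tristimulus values, converts them to XYZ and to chromaticity, and
shows a matrix round trip through the Stiles-Burch RGB space.
"""

import numpy as np

from conefund import (
    SpectralFunction,
    chromaticity,
    compute_fundamentals,
    lms_to_rgb_10deg,
    lms_to_xyz,
    rgb_to_lms_10deg,
    tristimulus,
)

fund = compute_fundamentals()  # standard 2-deg, energy units
lam = fund.wavelengths
light = SpectralFunction(lam[0], 1.0, np.exp(-0.5 * ((lam - 580) / 15.0) ** 2), "power")

lms = tristimulus(light, fund)
print("LMS tristimulus:", np.round(lms, 4))
print("lm chromaticity:", tuple(round(c, 4) for c in chromaticity(lms)))
print("XYZ (2-deg):    ", np.round(lms_to_xyz(lms, "deg2"), 4))

rgb = lms_to_rgb_10deg(lms)
back = rgb_to_lms_10deg(rgb)
print("RGB10:          ", np.round(rgb, 4))
print("round-trip error:", float(np.abs(back - lms).max()))
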
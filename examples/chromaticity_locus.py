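"""The monochromatic spectrum locus in three chromaticity spaces.

Projects the standard 10-deg fundamentals onto cone (l,m), Stiles-Burch
(r,g) and CIE (x,y) chromaticity coordinates. Cone and XYZ coordinates are
everywhere non-negative (imaginary primaries enclosing the locus); RGB
coordinates go negative away from the 444/526/645 nm primaries because real
primary lights cannot enclose the locus.
"""

import numpy as np

from conefund import compute_fundamentals, spectrum_locus, standard_observer

fund = compute_fundamentals(standard_observer("deg10"))
lam = fund.wavelengths
for space in ("lm", "rg", "xy"):
    pts = spectrum_locus(fund, space)
    print(f"{space} locus: ")
    for target in (450.0, 520.0, 600.0):
        i = int(np.nonzero(lam == target)[0][0])
        print(f"  {target:.0f} nm -> ({pts[i, 0]:+.4f}, {pts[i, 1]:+.4f})")
    print(f"  min coordinate {pts.min():+.4f}")
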
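"""Generate the standard 2-deg and 10-deg corneal cone fundamentals.

Builds each observer's L-, M- and S-cone spectral sensitivities on the
390-830 nm tabulation grid (energy units, unit peak) and prints the peak
wavelengths plus a few sample values. The peaks are the wavelengths of
maximum corneal sensitivity; they sit longward of the photopigment
absorbance peaks because of pre-receptoral filtering and the quantal-to-
energy conversion.
"""

from conefund import compute_fundamentals, find_lambda_max, standard_observer

for fov in ("deg2", "deg10"):
    fund = compute_fundamentals(standard_observer(fov))
    print(f"{fund.observer.field_label}:")
    for name, chan in fund.channels().items():
        print(f"  {name}-cone peak {find_lambda_max(chan):6.1f} nm, "
              f"value at 550 nm {chan.value_at(550.0):.6f}")
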
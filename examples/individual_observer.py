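"""Cone fundamentals for a non-standard observer.

Models an observer with dense macular pigment (0.70 at 460 nm, twice the
standard), an L(ser180)-only photopigment, and a lower S-cone optical
density, then reports how far their fundamentals depart from the standard
2-deg observer (mean absolute error per channel, 400 nm up). Differences of
this size are enough to change color matches between observers.
"""

from conefund import ObserverConfig, compare_mae, compute_fundamentals

standard = compute_fundamentals()
custom = ObserverConfig(d_mac_460=0.70, l_variant="ser180", s_od=0.30).compute()

report = compare_mae(custom, standard)
print(report.summary())
print("S-cone value at 460 nm: standard %.4f vs custom %.4f"
      % (standard.S.value_at(460.0), custom.S.value_at(460.0)))
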
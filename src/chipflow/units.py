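"""Unit conversion constants.

Everything inside the package is SI (metres, seconds, pascals).  The
cell-culture literature reports wall shear stress in dyne/cm^2 and syringe
pump rates in ml/h or ul/day, so conversions live at the reporting boundary.
"""

#: 1 Pa = 10 dyne/cm^2
PA_TO_DYNE_CM2 = 10.0

#: 1 ml/h in m^3/s
ML_PER_H = 1e-6 / 3600.0

#: 1 ul/day in m^3/s
UL_PER_DAY = 1e-9 / 86400.0

#: 1 ul in m^3
UL = 1e-9
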
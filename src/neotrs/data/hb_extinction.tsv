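# Hemoglobin extinction coefficients, uM^-1 mm^-1 (e-base attenuation:
# mu_a[mm^-1] = eps_oxy * [oxyHb, uM] + eps_deoxy * [deoxyHb, uM]).
# Compiled from standard literature tabulations of molar extinction
# (common-log, M^-1 cm^-1) and converted via the ln(10) x 1e-7 factor.
# Not the (unpublished) table of any specific instrument.
wavelength_nm	eps_oxy	eps_deoxy
762	1.386e-4	3.247e-4
801	1.888e-4	1.773e-4
836	2.418e-4	1.635e-4
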
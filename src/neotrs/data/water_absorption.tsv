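# Pure-water absorption coefficient, mm^-1, near-infrared.
# Approximate literature values; multiplied by a tissue water volume
# fraction (default 0.90, neonatal brain) to form the background term.
wavelength_nm	mu_a_water
762	2.70e-3
801	2.22e-3
836	3.90e-3
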
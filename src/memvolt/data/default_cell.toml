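# Reference MC38-like cell and baseline buffer (HEPES) parameters.
# Flat key-value layout; units are encoded in the key names.
radius_m = 5.5e-6
membrane_thickness_m = 5.0e-9
membrane_conductivity_S_per_m = 2.5e-7
membrane_areal_capacitance_F_per_m2 = 0.01
intracellular_conductivity_S_per_m = 0.5
extracellular_conductivity_S_per_m = 0.05
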
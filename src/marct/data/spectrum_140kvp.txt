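# marct 140 kVp spectrum (generated by scripts/make_attenuation_table.py)
[spectrum]
kvp 140
reference_energy_keV 61.1
energies_keV 25.0 35.0 45.0 55.0 65.0 75.0 85.0 95.0 105.0 115.0 125.0 135.0
weights 1.930109e-02 1.222629e-01 1.714149e-01 1.655519e-01 1.415642e-01 1.147898e-01 9.023496e-02 6.838724e-02 4.939193e-02 3.287095e-02 1.845515e-02 5.775001e-03
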
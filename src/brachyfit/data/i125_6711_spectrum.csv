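# photon emission spectrum of the 125I model-6711 seed exterior
# Te K X-ray / gamma lines plus silver fluorescence (22.1, 25.2 keV)
# yields rescaled so total_yield = 1.5951 photons/disintegration
energy_kev,photons_per_decay
22.1,0.1981490683
25.2,0.0495372671
27.2,0.3665757764
27.5,0.6836142857
31.0,0.2377788820
35.5,0.0594447205
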
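species_id,plasma_ph,assay_temperature_c,assay_plasma_fraction
human,7.4,37,1.0
rainbow_trout,7.9,15,1.0
koi_carp,7.7,25,1.0
fathead_minnow,7.7,25,0.1
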
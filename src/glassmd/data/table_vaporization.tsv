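compound	temperature_K	h_vap_md	h_vap_md_sd	h_vap_exp	h_vap_exp_sd
Naproxen	410	108.2	1.0	106.9	3.0
Ibuprofen	410	90.0		84.4	3.0
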
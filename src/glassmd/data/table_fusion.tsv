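compound	phase	temperature_K	h_fus_md	h_fus_exp	printed_deviation_pct
Carbamazepin	Crystal III	293	30.6	27.4	12
Ibuprofen	Crystal I	296	15.1	26.4	-43
Indomethacin	Crystal gamma	203	20.6	38.1	-46
Naproxen	Crystal	293	29.1	32.4	-10
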
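compound	phase	temperature_K	rho_md	rho_exp	printed_deviation_pct
Carbamazepine	Crystal III	293	1.335	1.333	0.1
Ibuprofen	Crystal I	296	1.115	1.117	-0.2
Ibuprofen	Liquid	350	1.006	0.966	4.1
Ibuprofen	Liquid	400	0.968	0.924	4.7
Indomethacin	Crystal alpha	203	1.408	1.420	-0.9
Indomethacin	Crystal gamma	120	1.418	1.401	1.2
Indomethacin	Liquid	400	1.284	1.231	4.3
Indomethacin	Liquid	450	1.264	1.183	6.9
Naproxen	Crystal	293	1.308	1.263	3.6
Naproxen	Liquid	430	1.154	1.088	6.1
Naproxen	Liquid	480	1.116	1.048	6.5
Adenine	Crystal	293	1.506	1.494	0.8
Cytosine	Crystal	293	1.537	1.502	-1.6
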
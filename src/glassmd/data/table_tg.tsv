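compound	tg_md_rho	tg_md_D	tg_md	tg_exp	printed_deviation_pct
Carbamazepin	384	374	379	315	20
Ibuprofen	295	286	290	228	27
Indomethacin	388	388	388	313	24
Naproxen	343	347	345	278	24
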
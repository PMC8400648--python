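{
 "version": 1,
 "sha256": {
  "table_densities.tsv": "2fd6cd436b61f4eb2667ec18cd91a4f0716cb42887a504360c7b9d10acfe1b9f",
  "table_fusion.tsv": "d0f3dbbf9782421fc7afef77fd96aee044fd5ad70260abd9525db07edf6aefe0",
  "table_tg.tsv": "82f442ed3189faf6a377f203426881f3c47cc86373d53a644fd26d55b414931f",
  "table_vaporization.tsv": "d9ae822c93c6fd42b5e2580349c4a9495c082745d796759501d3c0997b2063b8"
 }
}
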
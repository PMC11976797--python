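{
 "classification_table.tsv": "8ea7594b2d99bce8dbdfcf6f634042c69d056c5550e7300b5158f52570141043",
 "activity_table.tsv": "98a360e3d8c5f56bfb84388286ffa6c4eb231529a2b4c7046f2f4006e5e4759e"
}
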
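taxon,level,n_total,n_with_gene
Hyphomicrobiales,genus,171,46
Rhodobacterales,genus,203,3
Rhodospirillales,genus,106,73
Sphingomonadales,genus,51,9
other,genus,78,7
Hyphomicrobiales,genome,2618,791
Rhodobacterales,genome,1337,4
Rhodospirillales,genome,673,475
Sphingomonadales,genome,1129,123
other,genome,753,16
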
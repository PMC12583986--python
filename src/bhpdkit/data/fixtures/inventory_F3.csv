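species,structure_code,rel_abundance_pct
Rhizomicrobium palustre,IIIc,100
Novosphingobium rosa,IIIc,100
Azospirillum brasilense,Ia,100
Limimonas halophila,Va,100
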
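species,me2_hop22_29_ene,me2_hop17_21_ene,me2_diplopterol,me2_tetrahymanol,me2_c31_hopanol,me2_c32_hopanol,me3_c31_hopanol,me3_c32_hopanol
Rhodopila globiformis,BD,BD,BD,BD,BD,BD,BD,0.13
Komagataeibacter europaeus,BD,BD,BD,BD,BD,BD,25,4.1
Kozakia baliensis,BD,BD,BD,BD,BD,BD,BD,0.10
Acetobacter pasteurianus,BD,BD,BD,BD,BD,BD,BD,0.12
Tistlia consotensis,BD,BD,BD,BD,BD,BD,BD,0.02
Hypericibacter terrae,BD,BD,BD,BD,BD,BD,BD,0.23
Rhodoligotrophos appendicifer,29,36,39,BD,BD,BD,BD,BD
Enterovirga rhinocerotis,BD,BD,2.0,BD,BD,BD,BD,BD
Methylobacterium soli,7.2,53,76,BD,BD,BD,BD,BD
Methylobacterium oxalidis,14,73,72,BD,BD,0.10,BD,0.19
Methylorubrum rhodesianum,89,93,91,BD,BD,0.69,BD,BD
Methylobacterium aquaticum,17,55,73,BD,BD,0.66,BD,BD
Methyloferula stellata,BD,BD,23,BD,BD,0.09,BD,BD
Beijerinckia indica,BD,BD,23,BD,BD,0.17,BD,BD
Rhodoplanes elegans,BD,BD,18,77,BD,BD,BD,BD
Afipia broomeae,BD,BD,BD,BD,BD,0.06,BD,BD
Rhodopseudomonas parapalustris,26,BD,34,13,0.93,1.4,BD,BD
Bradyrhizobium elkanii,BD,BD,78,76,3.3,5.1,BD,BD
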
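species,hop22_29_ene,hop17_21_ene,diplopterol,tetrahymanol,sum_bhpds,pct_22s,n_bhpds,pct_unsaturated,pct_pentol_plus_hexol
Muricoccus pecuniae,BD,BD,BD,BD,0.1,BD,1,0,0
Rhodopila globiformis,0.12,BD,BD,BD,1.3,BD,5,0,19
Acidocella aminolytica,0.11,BD,BD,BD,2.7,BD,11,3,21
Gluconacetobacter diazotrophicus,BD,BD,BD,BD,27.3,79,15,49,6
Komagataeibacter xylinus,NA,NA,NA,NA,NA,NA,23,71,24
Komagataeibacter europaeus,BD,BD,0.12,BD,1.3,7,25,54,50
Kozakia baliensis,BD,BD,0.14,BD,5.3,15,33,56,29
Asaia siamensis,0.07,0.08,0.88,BD,12.9,14,18,58,15
Gluconobacter oxydans,BD,BD,0.87,BD,13.3,27,19,56,18
Acetobacter pasteurianus,BD,BD,1.7,BD,14.9,25,15,82,19
Limimonas halophila,BD,BD,0.05,BD,1.4,BD,1,0,0
Pelagibius litoralis,BD,BD,BD,BD,2.2,BD,2,0,0
Tistlia consotensis,BD,BD,BD,BD,3.9,BD,4,0,0
Rhodospirillum rubrum,0.38,BD,BD,BD,8.1,BD,4,0,0
Magnetospirillum fulvum,BD,BD,BD,BD,0.9,BD,5,0,0
Enhydrobacter aerosaccus,BD,BD,BD,BD,1.4,BD,9,1,77
Hypericibacter terrae,0.27,0.04,BD,BD,3.9,BD,17,4,5
Skermanella aerolata,BD,BD,BD,BD,BD,BD,9,37,26
Nitrospirillum amazonense,0.20,BD,BD,BD,16.2,BD,11,0,44
Azospirillum brasilense,BD,BD,BD,BD,BD,BD,1,0,0
Novosphingobium nitrogenifigens,0.51,0.03,0.06,BD,5.5,BD,9,0,15
Novosphingobium acidiphilum,BD,BD,BD,BD,BD,BD,0,NA,NA
Novosphingobium rosa,BD,BD,BD,BD,6.5,BD,1,0,0
Sphingomonas mali,BD,BD,BD,BD,1.1,BD,2,0,90
Stakelama sediminis,2.1,0.07,BD,BD,1.0,BD,6,0,20
Sphingomonas alpina,BD,BD,BD,BD,BD,BD,0,NA,NA
Sphingomonas changbaiensis,0.34,BD,BD,BD,1.4,BD,4,0,0
Sphingomonas formosensis,BD,BD,BD,BD,0.5,BD,5,1,23
Sphingomonas haloaromaticamans,0.03,BD,BD,BD,0.6,BD,6,0,51
Sphingobium estronivorans,BD,BD,BD,BD,0.4,BD,5,0,41
Rhizomicrobium palustre,BD,BD,BD,BD,11.9,BD,2,0,1
Rhizobium tropici,BD,BD,BD,BD,BD,BD,0,NA,NA
Ensifer sojae,BD,BD,BD,BD,BD,BD,0,NA,NA
Roseibium album,BD,BD,BD,BD,BD,BD,0,NA,NA
Roseibium marinum,BD,BD,BD,BD,BD,BD,0,NA,NA
Rhodoligotrophos appendicifer,BD,BD,2.8,BD,1.3,BD,4,0,0
Rhodomicrobium vannielii,0.48,BD,BD,BD,12.9,BD,8,0,0
Hyphomicrobium facile,BD,BD,0.02,BD,3.0,BD,4,0,0
Chelatococcus reniformis,BD,BD,BD,BD,1.3,BD,4,0,0
Enterovirga rhinocerotis,0.05,0.06,0.46,BD,0.3,BD,10,1,1
Microvirga massiliensis,BD,BD,BD,BD,BD,BD,2,0,0
Methylobacterium soli,0.13,0.09,1.4,BD,3.1,BD,12,0,0
Methylobacterium oxalidis,0.37,0.15,1.3,BD,1.4,BD,12,0,0
Methylorubrum rhodesianum,BD,0.03,0.34,BD,2.4,BD,11,0,0
Methylobacterium aquaticum,0.08,0.02,1.6,BD,5.0,BD,9,0,0
Roseiarcus fermentans,BD,BD,BD,BD,2.4,BD,6,0,0
Methyloferula stellata,BD,BD,3.8,BD,7.1,BD,15,0,0
Methylocella palustris,NA,NA,NA,NA,NA,BD,5,0,0
Beijerinckia indica,BD,BD,1.8,BD,1.5,BD,7,0,0
Rhodoplanes elegans,BD,BD,0.09,0.69,0.9,BD,17,0,0
Variibacter gotjawalensis,0.91,0.06,BD,BD,1.0,BD,5,0,0
Afipia broomeae,0.12,BD,0.20,BD,8.3,BD,16,43,0
Rhodopseudomonas parapalustris,BD,BD,1.2,1.1,2.5,BD,10,0,0
Bradyrhizobium elkanii,BD,BD,0.26,0.61,2.1,BD,12,0,0
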
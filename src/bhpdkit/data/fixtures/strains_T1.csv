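order,family,species,strain,dsm
Rhodospirillales,Acetobacteraceae,Muricoccus pecuniae,N75,25622
Rhodospirillales,Acetobacteraceae,Rhodopila globiformis,7950,161
Rhodospirillales,Acetobacteraceae,Acidocella aminolytica,101,11237
Rhodospirillales,Acetobacteraceae,Gluconacetobacter diazotrophicus,PA 5,5601
Rhodospirillales,Acetobacteraceae,Komagataeibacter xylinus,R-2277,NA
Rhodospirillales,Acetobacteraceae,Komagataeibacter europaeus,JK2,13110
Rhodospirillales,Acetobacteraceae,Kozakia baliensis,YO-3,14400
Rhodospirillales,Acetobacteraceae,Asaia siamensis,S60-1,15972
Rhodospirillales,Acetobacteraceae,Gluconobacter oxydans,CN 1221,2003
Rhodospirillales,Acetobacteraceae,Acetobacter pasteurianus,190,3509
Rhodospirillales,Rhodovibrionaceae,Limimonas halophila,IA16,25584
Rhodospirillales,Rhodovibrionaceae,Pelagibius litoralis,CL-UU02,21314
Rhodospirillales,Rhodovibrionaceae,Tistlia consotensis,USBA 355,21585
Rhodospirillales,Rhodospirillaceae,Rhodospirillum rubrum,S 1,467
Rhodospirillales,Rhodospirillaceae,Magnetospirillum fulvum,1360,113
Rhodospirillales,Reyranellaceae,Enhydrobacter aerosaccus,G,8914
Rhodospirillales,Rhodospirillaceae,Hypericibacter terrae,R5913,109816
Rhodospirillales,Azospirillaceae,Skermanella aerolata,5416 T-32,18479
Rhodospirillales,Azospirillaceae,Nitrospirillum amazonense,Y-1,2787
Rhodospirillales,Azospirillaceae,Azospirillum brasilense,Sp 7,1690
Sphingomonadales,Erythrobacteraceae,Novosphingobium nitrogenifigens,Y88,19370
Sphingomonadales,Erythrobacteraceae,Novosphingobium acidiphilum,FSW 06-204d,19966
Sphingomonadales,Erythrobacteraceae,Novosphingobium rosa,R13-5,7285
Sphingomonadales,Sphingomonadaceae,Sphingomonas mali,Y-347,10565
Sphingomonadales,Sphingomonadaceae,Stakelama sediminis,CJ70,27203
Sphingomonadales,Sphingomonadaceae,Sphingomonas alpina,S8-3,22537
Sphingomonadales,Sphingomonadaceae,Sphingomonas changbaiensis,V2M44,25652
Sphingomonadales,Sphingomonadaceae,Sphingomonas formosensis,CC-Nfb-2,24164
Sphingomonadales,Sphingomonadaceae,Sphingomonas haloaromaticamans,A175,13477
Sphingomonadales,Sphingomonadaceae,Sphingobium estronivorans,AXB,102173
Micropepsales,Micropepsaceae,Rhizomicrobium palustre,A48,19867
Hyphomicrobiales,Rhizobiaceae,Rhizobium tropici,HAMBI 1163,11418
Hyphomicrobiales,Rhizobiaceae,Ensifer sojae,CCBAU 05684,26426
Hyphomicrobiales,Stappiaceae,Roseibium album,50 M6,18320
Hyphomicrobiales,Stappiaceae,Roseibium marinum,mano 18,17023
Hyphomicrobiales,Parvibaculaceae,Rhodoligotrophos appendicifer,120-1,23582
Hyphomicrobiales,Hyphomicrobiaceae,Rhodomicrobium vannielii,ATH 3.1.1,162
Hyphomicrobiales,Hyphomicrobiaceae,Hyphomicrobium facile,H-526,1565
Hyphomicrobiales,Chelatococcaceae,Chelatococcus reniformis,JCM 30308,105737
Hyphomicrobiales,Methylobacteriaceae,Enterovirga rhinocerotis,YIM 100770,25903
Hyphomicrobiales,Methylobacteriaceae,Microvirga massiliensis,JC119,26813
Hyphomicrobiales,Methylobacteriaceae,Methylobacterium soli,YIM 48816,21955
Hyphomicrobiales,Methylobacteriaceae,Methylobacterium oxalidis,35a,24028
Hyphomicrobiales,Methylobacteriaceae,Methylorubrum rhodesianum,D2_2,103741
Hyphomicrobiales,Methylobacteriaceae,Methylobacterium aquaticum,GR16,16371
Hyphomicrobiales,Roseiarcaceae,Roseiarcus fermentans,Pf56,24875
Hyphomicrobiales,Beijerinckiaceae,Methyloferula stellata,AR4,22108
Hyphomicrobiales,Beijerinckiaceae,Methylocella palustris,K,NA
Hyphomicrobiales,Beijerinckiaceae,Beijerinckia indica,B.102.C,591
Hyphomicrobiales,Nitrobacteraceae,Rhodoplanes elegans,AS130,11907
Hyphomicrobiales,Nitrobacteraceae,Variibacter gotjawalensis,GJW-30,29671
Hyphomicrobiales,Nitrobacteraceae,Afipia broomeae,B91-007286,7327
Hyphomicrobiales,Nitrobacteraceae,Rhodopseudomonas parapalustris,Dr.1,130
Hyphomicrobiales,Nitrobacteraceae,Bradyrhizobium elkanii,USDA61,11554
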
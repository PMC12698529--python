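drug_name,n,median_days,q1_days,q3_days
Pegvaliase,3,187,176,530
Thyroid,59,146,4,1130
Mogamulizumab,5,143,0,952
Docetaxel,7038,119,27,283
Leniolisib,3,116,76,289
Infigratinib,1,113,113,113
Eflornithine,4,95.5,13.5,812.5
Lindane,1,93,93,93
Anastrozole,140,89.5,13,365
Palbociclib,791,77,13,293
Teriflunomide,941,75,17,215
Vismodegib,206,59,14,156
"Estradiol, norethisterone and relugolix",4,59,18.5,115.5
Leflunomide,67,56,9,123
Teprotumumab,46,55,7,151
Levothyroxine and liothyronine,42,54.5,7,118
Fremanezumab,63,52,3,148
Peginterferon alfa-2A,275,51,7,121
Phentermine and topiramate,15,51,8,212
Erlotinib,189,47,7,143
Erenumab,242,45,5,122
Liothyronine,17,44,0,196
Selumetinib,10,43.5,10,137
Pemigatinib,7,42,0,102
Abemaciclib,39,40,8,80
Galcanezumab,159,37,7,100
Acitretin,34,35,0,106
Sonidegib,17,32,17,200
Benzyl alcohol,1,31,31,31
Colchicine and probenecid,1,31,31,31
Exemestane,49,30,0,334
Voclosporin,48,30,1.5,82.5
Elagolix,6,30,3,39
Ripretinib,102,29,4,134
Levothyroxine,907,28,2,108
Fumaric acid,414,26.5,0,136
"Elagolix, estradiol and norethisterone",7,20,4,61
Deoxycholic acid,15,19,1,28
Ribociclib,168,17.5,3,120
Tisotumab vedotin,2,17,17,17
Letrozole,218,16.5,5,61
Abaloparatide,66,16.5,0,62
Letrozole and ribociclib,2,16,0,32
Selenium,1,16,16,16
Ropeginterferon alfa-2B,21,15,0,75
Trastuzumab deruxtecan,36,14,0,154.5
Enfortumab vedotin,89,13,6,20
Vemurafenib,74,10,4,27
Alpelisib,33,9,0,64
Futibatinib,3,8,0,35
Sorafenib,370,7,2,18
Sacituzumab govitecan,35,7,2,22
Pentosan polysulfate,20,6.5,0,648
Albendazole,17,6,2,19
Tazemetostat,16,4.5,0,57.5
Prasterone,6,3.5,0,92
Nirogacestat,15,2,0,12
Ketoconazole,56,0,0,0
Permethrin,32,0,0,1.5
Selenium sulfide,6,0,0,28
Ciclopirox,3,0,0,43
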
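drug_name,documented
Docetaxel,yes
Teriflunomide,yes
Levothyroxine,yes
Palbociclib,yes
Fumaric acid,yes
Vismodegib,yes
Erenumab,yes
Peginterferon alfa-2A,yes
Leflunomide,yes
Erlotinib,no
Sorafenib,yes
Letrozole,yes
Ribociclib,yes
Galcanezumab,no
Anastrozole,yes
Vemurafenib,yes
Ripretinib,yes
Abaloparatide,yes
Teprotumumab,yes
Ketoconazole,no
Abemaciclib,yes
Trastuzumab deruxtecan,yes
Exemestane,yes
Fremanezumab,no
Alpelisib,yes
Enfortumab vedotin,yes
Acitretin,yes
Pentosan polysulfate,yes
Phentermine and topiramate,yes
Sacituzumab govitecan,yes
Voclosporin,yes
Pegvaliase,yes
Thyroid,yes
Liothyronine,yes
Permethrin,no
Levothyroxine and liothyronine,yes
Elagolix,yes
Sonidegib,yes
"Elagolix, estradiol and norethisterone",yes
Deoxycholic acid,no
"Estradiol, norethisterone and relugolix",yes
Ropeginterferon alfa-2B,yes
Prasterone,yes
Tazemetostat,yes
Pemigatinib,yes
Selenium sulfide,no
Mogamulizumab,yes
Albendazole,no
Selumetinib,yes
Nirogacestat,yes
Ciclopirox,no
Eflornithine,yes
Letrozole and ribociclib,yes
Leniolisib,yes
Tisotumab vedotin,yes
Colchicine and probenecid,no
Infigratinib,yes
Lindane,no
Futibatinib,yes
Trilaciclib,yes
Selenium,no
Spinosad,no
Acetohydroxamic acid,no
Benzyl alcohol,no
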
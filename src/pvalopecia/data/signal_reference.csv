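drug_name,category,n_reports,ror,ror_lo,ror_hi,prr,chi2,ic,ic025
Docetaxel,oncology,29249,70.38,69.43,71.33,59.05,1405223,5.64,5.61
Teriflunomide,immune,5702,13.06,12.72,13.42,12.58,59068.2,3.61,3.57
Levothyroxine,endocrine,5644,8.11,7.89,8.33,7.93,33211.8,2.95,2.91
Palbociclib,oncology,5553,7.03,6.84,7.22,6.90,27241.4,2.75,2.71
Fumaric acid,skin,2109,2.16,2.07,2.26,2.15,1289.96,1.10,1.03
Vismodegib,oncology,1328,20.88,19.75,22.08,19.61,23354.6,4.28,4.18
Erenumab,nervous,1287,3.56,3.37,3.77,3.53,2329.45,1.81,1.73
Peginterferon alfa-2A,immune,1050,2.73,2.57,2.90,2.71,1131.87,1.43,1.34
Leflunomide,immune,1014,2.94,2.76,3.12,2.92,1274.11,1.54,1.44
Erlotinib,oncology,818,2.24,2.09,2.40,2.23,554.34,1.15,1.05
Sorafenib,oncology,808,2.97,2.77,3.18,2.95,1040.93,1.56,1.45
Letrozole,endocrine,781,2.94,2.74,3.16,2.93,988.92,1.54,1.44
Ribociclib,oncology,745,2.93,2.73,3.15,2.91,934.38,1.54,1.43
Galcanezumab,nervous,651,4.01,3.71,4.33,3.97,1446.40,1.99,1.86
Anastrozole,endocrine,608,3.34,3.08,3.61,3.31,980.69,1.72,1.60
Vemurafenib,oncology,538,5.62,5.16,6.12,5.53,1997.81,2.46,2.33
Ripretinib,oncology,430,10.35,9.40,11.39,10.04,3502.70,3.32,3.15
Abaloparatide,endocrine,397,2.24,2.03,2.47,2.23,270.23,1.16,1.01
Teprotumumab,immune,351,5.86,5.28,6.52,5.77,1386.81,2.53,2.35
Ketoconazole,skin,329,8.60,7.71,9.60,8.39,2145.81,3.07,2.87
Abemaciclib,oncology,278,2.86,2.54,3.21,2.84,331.61,1.50,1.32
Trastuzumab deruxtecan,oncology,251,4.03,3.56,4.56,3.99,562.88,1.99,1.79
Exemestane,endocrine,239,3.16,2.78,3.59,3.14,349.11,1.65,1.45
Fremanezumab,nervous,237,3.00,2.64,3.41,2.98,311.93,1.57,1.37
Alpelisib,oncology,192,2.49,2.16,2.88,2.48,170.28,1.31,1.09
Enfortumab vedotin,oncology,169,5.28,4.54,6.15,5.21,576.50,2.38,2.12
Acitretin,skin,166,6.46,5.54,7.54,6.35,750.09,2.67,2.39
Pentosan polysulfate,other,160,4.34,3.72,5.08,4.30,405.63,2.10,1.84
Phentermine and topiramate,nervous,155,5.12,4.37,6.00,5.05,505.27,2.34,2.07
Sacituzumab govitecan,oncology,151,4.15,3.53,4.87,4.11,355.53,2.04,1.77
Voclosporin,immune,147,3.40,2.89,4.00,3.37,245.65,1.75,1.49
Pegvaliase,other,143,2.79,2.37,3.29,2.78,163.05,1.47,1.21
Thyroid,endocrine,137,6.99,5.90,8.28,6.86,687.18,2.78,2.47
Liothyronine,endocrine,125,5.33,4.46,6.36,5.25,431.39,2.39,2.08
Permethrin,other,98,11.38,9.30,13.93,11.01,893.98,3.46,3.02
Levothyroxine and liothyronine,endocrine,85,6.85,5.52,8.49,6.72,414.76,2.75,2.34
Elagolix,endocrine,77,2.72,2.17,3.40,2.70,82.97,1.44,1.08
Sonidegib,oncology,76,9.40,7.48,11.82,9.15,553.45,3.19,2.71
"Elagolix, estradiol and norethisterone",endocrine,69,16.99,13.33,21.65,16.14,982.74,4.01,3.37
Deoxycholic acid,other,57,3.21,2.47,4.17,3.19,85.89,1.67,1.24
"Estradiol, norethisterone and relugolix",endocrine,57,7.01,5.39,9.12,6.88,287.13,2.78,2.26
Ropeginterferon alfa-2B,immune,53,2.74,2.09,3.59,2.73,58.07,1.45,1.01
Prasterone,endocrine,48,4.79,3.60,6.37,4.73,141.69,2.24,1.72
Tazemetostat,oncology,48,3.68,2.77,4.89,3.65,92.44,1.87,1.37
Pemigatinib,oncology,46,7.47,5.57,10.00,7.31,251.34,2.87,2.26
Selenium sulfide,skin,43,11.94,8.80,16.19,11.53,414.61,3.53,2.77
Mogamulizumab,oncology,41,3.15,2.32,4.29,3.13,59.54,1.64,1.13
Albendazole,other,37,3.06,2.21,4.23,3.04,50.77,1.60,1.06
Selumetinib,oncology,32,4.42,3.12,6.26,4.37,83.40,2.13,1.48
Nirogacestat,oncology,28,3.82,2.63,5.55,3.79,57.57,1.92,1.25
Ciclopirox,skin,27,5.34,3.65,7.82,5.27,93.70,2.40,1.64
Eflornithine,oncology,25,9.42,6.33,14.03,9.17,182.57,3.20,2.23
Letrozole and ribociclib,oncology,21,5.37,3.49,8.27,5.30,73.44,2.41,1.53
Leniolisib,immune,17,8.44,5.21,13.67,8.24,108.52,3.04,1.86
Tisotumab vedotin,oncology,15,4.20,2.52,6.98,4.15,36.00,2.05,1.07
Colchicine and probenecid,other,11,5.18,2.85,9.39,5.11,36.43,2.35,1.09
Infigratinib,oncology,11,7.53,4.14,13.71,7.38,60.83,2.88,1.42
Lindane,other,8,6.47,3.21,13.04,6.36,36.25,2.67,1.02
Futibatinib,oncology,7,4.34,2.06,9.16,4.30,17.76,2.10,0.58
Trilaciclib,other,7,4.54,2.15,9.57,4.49,19.03,2.17,0.61
Selenium,other,5,25.29,10.15,62.97,23.42,107.66,4.55,1.07
Spinosad,other,5,41.01,16.12,104.33,36.24,171.91,5.18,1.14
Acetohydroxamic acid,other,3,7.52,2.39,23.65,7.37,16.56,2.88,0.04
Benzyl alcohol,skin,3,8.06,2.56,25.35,7.87,18.06,2.98,0.06
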
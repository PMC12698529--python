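block,level,count
sex,F,139084
sex,M,18433
sex,unknown,23532
reporting_year,2004Q1-2010Q4,13601
reporting_year,2011Q1-2015Q4,29375
reporting_year,2016Q1-2020Q4,87379
reporting_year,2021Q1-2024Q4,50694
region,US,134199
region,CA,13238
region,GB,5380
region,FR,5136
region,DE,3168
occupation,consumer,101167
occupation,physician,24722
occupation,pharmacist,21587
occupation,lawyer,15753
occupation,other_health_professional,12092
occupation,unknown,5728
severity,non_serious,96511
severity,serious,84538
outcome,LT,3769
outcome,HO,18354
outcome,DS,9746
outcome,DE,3544
outcome,CA,692
outcome,RI,721
outcome,OT,72151
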
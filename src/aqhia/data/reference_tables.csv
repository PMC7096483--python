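section,endpoint,kind,label,central,low,high
burden,IHD,mortality,2013,4246,3946,4508
burden,IHD,mortality,2017,3577,3282,3846
burden,IHD,mortality,scenario,1704,1525,1877
burden,IHD,mortality,benefit,669,621,710
burden,IHD,mortality,scenario_benefit,2542,2362,2699
burden,stroke,mortality,2013,6401,3390,8343
burden,stroke,mortality,2017,5326,2679,7255
burden,stroke,mortality,scenario,1601,722,2415
burden,stroke,mortality,benefit,1075,569,1401
burden,stroke,mortality,scenario_benefit,4800,2542,6256
burden,LC,mortality,2013,617,419,758
burden,LC,mortality,2017,383,249,486
burden,LC,mortality,scenario,135,81,185
burden,LC,mortality,benefit,234,158,287
burden,LC,mortality,scenario_benefit,482,327,591
burden,COPD,mortality,2013,1327,726,1740
burden,COPD,mortality,2017,988,518,1347
burden,COPD,mortality,scenario,361,173,534
burden,COPD,mortality,benefit,339,185,444
burden,COPD,mortality,scenario_benefit,966,528,1267
burden,RHA,morbidity,2013,7540,4672,10166
burden,RHA,morbidity,2017,4394,2669,6039
burden,RHA,morbidity,scenario,436,260,613
burden,RHA,morbidity,benefit,3147,1745,4738
burden,RHA,morbidity,scenario_benefit,7104,4021,10485
burden,CHA,morbidity,2013,4630,2575,6567
burden,CHA,morbidity,2017,2645,1451,3802
burden,CHA,morbidity,scenario,257,139,375
burden,CHA,morbidity,benefit,1986,1025,3034
burden,CHA,morbidity,scenario_benefit,4373,2288,6591
burden,CB,morbidity,2013,12077,6305,17062
burden,CB,morbidity,2017,7143,3609,10413
burden,CB,morbidity,scenario,721,352,1087
burden,CB,morbidity,benefit,4934,2143,8364
burden,CB,morbidity,scenario_benefit,11356,5101,18641
burden,AA,morbidity,2013,12346,9101,15405
burden,AA,morbidity,2017,7178,5222,9073
burden,AA,morbidity,scenario,711,510,912
burden,AA,morbidity,benefit,5168,3538,6941
burden,AA,morbidity,scenario_benefit,11634,8074,15419
burden,REV,morbidity,2013,1356,696,1983
burden,REV,morbidity,2017,769,391,1138
burden,REV,morbidity,scenario,74,37,111
burden,REV,morbidity,benefit,587,283,913
burden,REV,morbidity,scenario_benefit,1281,626,1972
economics,IHD,mortality,2013,570000000,530000000,610000000
economics,IHD,mortality,2017,480000000,440000000,520000000
economics,IHD,mortality,scenario,230000000,210000000,250000000
economics,IHD,mortality,benefit,90000000,80000000,100000000
economics,IHD,mortality,scenario_benefit,340000000,320000000,360000000
economics,stroke,mortality,2013,860000000,460000000,1130000000
economics,stroke,mortality,2017,720000000,360000000,980000000
economics,stroke,mortality,scenario,220000000,100000000,330000000
economics,stroke,mortality,benefit,150000000,80000000,190000000
economics,stroke,mortality,scenario_benefit,650000000,340000000,840000000
economics,LC,mortality,2013,80000000,60000000,100000000
economics,LC,mortality,2017,50000000,40000000,70000000
economics,LC,mortality,scenario,20000000,10000000,30000000
economics,LC,mortality,benefit,30000000,20000000,40000000
economics,LC,mortality,scenario_benefit,70000000,40000000,80000000
economics,COPD,mortality,2013,180000000,100000000,240000000
economics,COPD,mortality,2017,130000000,70000000,180000000
economics,COPD,mortality,scenario,50000000,20000000,70000000
economics,COPD,mortality,benefit,50000000,30000000,60000000
economics,COPD,mortality,scenario_benefit,130000000,70000000,170000000
economics,RHA,morbidity,2013,11600000,7200000,15700000
economics,RHA,morbidity,2017,6800000,4100000,9300000
economics,RHA,morbidity,scenario,700000,400000,900000
economics,RHA,morbidity,benefit,4900000,2700000,7300000
economics,RHA,morbidity,scenario_benefit,11000000,6200000,16200000
economics,CHA,morbidity,2013,10900000,6000000,15400000
economics,CHA,morbidity,2017,6200000,3400000,8900000
economics,CHA,morbidity,scenario,600000,300000,900000
economics,CHA,morbidity,benefit,4700000,2400000,7100000
economics,CHA,morbidity,scenario_benefit,10300000,5400000,15500000
economics,CB,morbidity,2013,86500000,45100000,122200000
economics,CB,morbidity,2017,51100000,25800000,74600000
economics,CB,morbidity,scenario,5200000,2500000,7800000
economics,CB,morbidity,benefit,35300000,15300000,60000000
economics,CB,morbidity,scenario_benefit,81300000,36500000,133500000
economics,AA,morbidity,2013,100000,100000,100000
economics,AA,morbidity,2017,100000,0,100000
economics,AA,morbidity,scenario,0,0,0
economics,AA,morbidity,benefit,0,0,100000
economics,AA,morbidity,scenario_benefit,100000,100000,100000
economics,REV,morbidity,2013,100000,100000,200000
economics,REV,morbidity,2017,100000,0,100000
economics,REV,morbidity,scenario,0,0,0
economics,REV,morbidity,benefit,0,0,100000
economics,REV,morbidity,scenario_benefit,100000,100000,200000
summary,deaths_attributable,mortality,2013,12591,8481,15349
summary,deaths_attributable,mortality,2017,10274,6728,12934
summary,morbidity_attributable,morbidity,2013,37949,23349,51183
summary,morbidity_attributable,morbidity,2017,22129,13342,30465
summary,deaths_avoided,mortality,benefit,2317,1533,2842
summary,morbidity_avoided,morbidity,benefit,15822,8734,23990
summary,economic_benefit_total,all,benefit,317700000,227500000,458100000
summary,economic_benefit_mortality,mortality,benefit,312800000,207000000,383700000
summary,economic_benefit_morbidity,morbidity,benefit,44900000,20500000,74400000
summary,economic_benefit_total,all,scenario_benefit,1289500000,825800000,1673600000
summary,economic_benefit_mortality,mortality,scenario_benefit,1186800000,777600000,1460000000
summary,economic_benefit_morbidity,morbidity,scenario_benefit,102700000,48200000,213600000
summary,gdp_usd,all,2013,78700000000,,
summary,gdp_usd,all,2017,108400000000,,
summary,population,all,2013,7000000,,
summary,population,all,2017,7300000,,
summary,pm25_city_mean,all,2013,110,,
summary,pm25_city_mean,all,2017,63,,
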
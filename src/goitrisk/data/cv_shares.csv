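age_group,basis,perchlorate_water_conc,perchlorate_food_conc,nitrate_water_conc,nitrate_food_conc,thiocyanate_water_conc,thiocyanate_food_conc,water_EF,food_EF
1-3 months,serum,2,3,17,49,0,14,4,11
2-3 years,serum,3,5,13,52,0,15,4,8
6-11 years,serum,3,5,14,55,0,13,3,7
18-21 years,serum,3,4,15,56,0,12,3,7
>21 years,serum,2,4,15,57,0,12,3,7
pregnant women,serum,2,4,15,58,0,11,3,7
1-3 months,halflife,2,3,8,19,0,53,4,11
2-3 years,halflife,3,5,7,18,0,55,4,8
6-11 years,halflife,3,5,7,22,0,53,3,7
18-21 years,halflife,3,4,6,20,0,57,3,7
>21 years,halflife,2,4,6,20,0,58,3,7
pregnant women,halflife,2,4,9,23,0,52,3,7
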
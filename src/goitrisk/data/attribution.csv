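age_group,basis,approach,perchlorate,nitrate,thiocyanate
1-3 months,serum,A3,0.25,28.20,3.10
2-3 years,serum,A3,0.40,46.50,3.13
6-11 years,serum,A3,0.35,47.30,2.30
18-21 years,serum,A3,0.21,29.10,1.07
>21 years,serum,A3,0.24,28.90,1.26
pregnant women,serum,A3,0.29,38.40,2.10
1-3 months,serum,A4,0.00,0.42,0.08
2-3 years,serum,A4,0.01,0.81,0.25
6-11 years,serum,A4,0.01,0.89,0.20
18-21 years,serum,A4,0.00,0.24,0.06
>21 years,serum,A4,0.00,0.20,0.05
pregnant women,serum,A4,0.00,0.39,0.11
1-3 months,serum,A4b,0.22,26.78,3.10
2-3 years,serum,A4b,0.38,43.60,2.22
6-11 years,serum,A4b,0.31,43.67,2.22
18-21 years,serum,A4b,0.18,26.90,1.12
>21 years,serum,A4b,0.18,26.90,1.12
pregnant women,serum,A4b,0.24,35.10,2.06
1-3 months,halflife,A3,0.25,9.70,22.00
2-3 years,halflife,A3,0.40,9.60,40.00
6-11 years,halflife,A3,0.35,11.50,38.10
18-21 years,halflife,A3,0.21,9.20,20.80
>21 years,halflife,A3,0.24,9.20,20.80
pregnant women,halflife,A3,0.29,9.40,30.40
1-3 months,halflife,A4,0.00,1.50,3.60
2-3 years,halflife,A4,0.01,3.19,7.80
6-11 years,halflife,A4,0.01,3.19,7.80
18-21 years,halflife,A4,0.00,0.28,0.82
>21 years,halflife,A4,0.00,0.32,0.78
pregnant women,halflife,A4,0.00,1.80,3.60
1-3 months,halflife,A4b,0.22,9.30,21.08
2-3 years,halflife,A4b,0.38,9.60,37.22
6-11 years,halflife,A4b,0.31,10.10,36.79
18-21 years,halflife,A4b,0.18,8.85,19.07
>21 years,halflife,A4b,0.18,8.85,19.07
pregnant women,halflife,A4b,0.24,8.20,27.66
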
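age_group,basis,A3,A4,A4b
1-3 months,serum,31.6,0.5,30.1
2-3 years,serum,50.0,1.1,46.2
6-11 years,serum,50.0,1.1,46.2
18-21 years,serum,30.4,0.3,28.2
>21 years,serum,30.4,0.3,28.2
pregnant women,serum,40.8,0.5,37.4
1-3 months,halflife,32.0,5.1,30.6
2-3 years,halflife,50.0,11.0,47.2
6-11 years,halflife,50.0,11.0,47.2
18-21 years,halflife,30.2,1.1,28.1
>21 years,halflife,30.2,1.1,28.1
pregnant women,halflife,40.1,5.4,36.1
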
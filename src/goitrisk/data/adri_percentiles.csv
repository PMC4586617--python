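age_group,basis,p1,p5,p10,p30,p50,p70,p90,p95,p99
1-3 months,serum,3.2,3.5,4.7,8.2,11.2,15.2,19.9,23.4,25.7
2-3 years,serum,3.8,4.2,5.6,9.8,13.5,18.3,23.9,28.1,30.9
6-11 years,serum,3.8,4.2,5.6,9.8,13.5,18.3,23.9,28.1,30.9
18-21 years,serum,2.9,3.2,4.2,7.4,10.1,13.7,17.9,21.1,23.2
>21 years,serum,2.9,3.2,4.2,7.4,10.1,13.7,17.9,21.1,23.2
pregnant women,serum,3.5,3.9,5.1,9.0,12.4,16.7,21.9,25.7,28.3
1-3 months,halflife,5.4,6.0,8.0,13.9,19.1,25.8,33.8,39.8,43.7
2-3 years,halflife,6.5,7.2,9.5,16.7,22.9,31.0,40.6,47.7,52.5
6-11 years,halflife,6.5,7.2,9.5,16.7,22.9,31.0,40.6,47.7,52.5
18-21 years,halflife,4.9,5.4,7.2,12.5,17.2,23.3,30.4,35.8,39.4
>21 years,halflife,4.9,5.4,7.2,12.5,17.2,23.3,30.4,35.8,39.4
pregnant women,halflife,6.0,6.6,8.7,15.3,21.0,28.4,37.2,43.7,48.1
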
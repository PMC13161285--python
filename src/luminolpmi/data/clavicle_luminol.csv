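sample_id,pmi_years,ipeak_au,exposure_s,correction_factor,age_at_death,sex,pmi_approximate
1,7.40,9142.70,15,,64,F,0
2,10.24,2207.65,15,,96,M,0
3,11.00,4437.25,15,,80,F,0
4,12.48,5617.40,15,,98,F,0
5,13.28,7928.28,15,,55,M,0
6,14.05,2506.60,15,,92,F,0
7,15.22,2123.01,15,,69,M,0
8,16.00,1359.88,22.5,,60,M,0
9,17.00,1530.92,22.5,,99,F,0
10,19.70,1308.67,22.5,,61,F,0
11,20.00,1053.97,22.5,,97,F,0
12,21.66,563.04,31.67,,60,M,0
13,22.70,704.52,31.67,,90,F,0
14,23.20,369.25,41.25,,90,F,0
15,24.35,394.93,41.25,,85,F,0
16,26.26,505.56,41.25,,43,M,0
17,27.00,608.53,41.25,,,unknown,0
18,34.00,277.93,41.25,,,M,0
19,38.00,252.70,51,,,F,0
20,40.00,228.36,51,,60,F,0
21,42.00,240.08,51,,,M,0
22,46.00,230.32,51,,,unknown,0
23,53.00,211.20,51,,65,M,0
24,500.00,218.68,51,,,F,1
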
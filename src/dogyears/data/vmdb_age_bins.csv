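label,lo_years,hi_years,midpoint_years
0-2 weeks,0,0.0385,0.25
2 weeks-2 months,0.0385,0.1667,0.25
2-6 months,0.1667,0.5,0.25
6 months-1 year,0.5,1,0.75
1-2 years,1,2,1.5
2-4 years,2,4,3
4-7 years,4,7,5.5
7-10 years,7,10,8.5
10-15 years,10,15,12.5
over 15 years,15,,17.5
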
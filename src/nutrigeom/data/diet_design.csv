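diet_id,protein_pct,carb_pct,fat_pct
1,7,33,60
2,7,78,15
3,14,56,30
4,14,26,60
5,21,64,15
6,21,34,45
7,30,40,30
8,35,20,45
9,42,43,15
10,50,20,30
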
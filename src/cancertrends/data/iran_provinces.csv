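id,name,hasc,population_share
1,Alborz,AL,0.034
2,Ardebil,AR,0.016
3,Kermanshah,BK,0.024
4,Bushehr,BS,0.015
5,Chahar Mahall and Bakhtiari,CM,0.012
6,East Azarbaijan,EA,0.049
7,Esfahan,ES,0.064
8,Fars,FA,0.061
9,Gilan,GI,0.032
10,Golestan,GO,0.023
11,Hamadan,HD,0.022
12,Hormozgan,HG,0.022
13,Ilam,IL,0.007
14,Kohgiluyeh and Buyer Ahmad,KB,0.009
15,Kordestan,KD,0.020
16,Kerman,KE,0.039
17,South Khorasan,KJ,0.010
18,North Khorasan,KS,0.011
19,Razavi Khorasan,KV,0.080
20,Khuzestan,KZ,0.059
21,Lorestan,LO,0.022
22,Markazi,MK,0.018
23,Mazandaran,MN,0.041
24,Qom,QM,0.016
25,Qazvin,QZ,0.016
26,Sistan and Baluchestan,SB,0.035
27,Semnan,SM,0.009
28,Tehran,TE,0.166
29,West Azarbaijan,WA,0.041
30,Yazd,YA,0.014
31,Zanjan,ZA,0.013
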
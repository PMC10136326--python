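patient_id,n_seizures,seizure_types,localization,lateralization,ictal_tachycardia
1,6,FIA:6,Temp:6,R:1;bi:5,yes
2,9,FIA:9,Fronto-temp:9,R:9,yes
3,2,FIA:2,Temp:2,R:2,yes
4,8,FIA:8,Temp:8,R:8,yes
5,3,FIA:3,Temp:3,L:3,no
6,2,FIA:2,Temp:2,L:2,yes
7,17,NC:17,NC:17,NC:17,yes
8,2,FIA:2,Temp:2,R:2,intermediate
9,2,FA:2,NC:2,NC:2,no
10,2,FIA:2,Fronto-par:2,R:1;bi:1,yes
11,5,FIA:5,Temp:5,L:5,intermediate
12,6,FIA:6,Temp:6,L:6,intermediate
13,5,FIA:5,Temp:3;NC:2,R:3;NC:2,intermediate
14,2,FIA:2,Temp:2,L:2,yes
15,2,FA:1;FIA:1,Temp:1;NC:1,R:1;NC:1,no
16,2,FA:2,Temp:1;NC:1,R:1;NC:1,yes
17,3,NC:3,NC:3,NC:3,intermediate
18,6,FA:6,NC:6,NC:6,no
19,3,FIA:3,Temp:3,L:3,yes
20,5,FIA:5,Temp:5,L:3;R:2,intermediate
21,15,FIA:15,Front:15,NC:15,yes
22,3,FIA:3,Temp:3,R:3,intermediate
23,7,FIA:7,Temp:7,L:7,no
24,5,FIA:5,Temp:5,L:5,yes
25,4,FIA:4,Temp:4,L:4,yes
26,22,FA:14;FIA:8,Temp:12;Fronto-temp:10,L:3;R:19,intermediate
27,9,FIA:9,Temp:9,L:4;R:3;bi:2,no
28,3,FA:2;F-BTC:1,Temp:1;Par:2,R:3,yes
29,2,FIA:2,Temp:2,R:2,yes
30,3,FIA:3,Fronto-temp:3,L:3,yes
31,2,FIA:2,Occipito-temp:2,L:2,intermediate
32,6,FIA:6,Temp:6,R:6,intermediate
33,8,FIA:8,Temp:1;Occipito-temp:7,R:8,yes
34,5,FIA:5,Fronto-temp:5,L:5,intermediate
35,5,FIA:5,Temp:5,L:5,yes
36,6,FIA:6,Temp:6,R:6,yes
37,5,FIA:5,Temp:5,R:5,yes
38,2,FIA:2,Temp:2,L:2,intermediate
39,2,FIA:2,Temp:2,bi:2,intermediate
40,5,FIA:5,Temp:5,R:5,yes
41,2,FIA:2,Temp:2,L:2,yes
42,8,FIA:8,Temp:8,L:3;R:1;bi:4,yes
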
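run_id,temperature_C,pH,agitation_rpm,tryptone_g_per_100mL,raffinose_g_per_100mL,k2hpo4_g_per_100mL,activity_U_per_mL,predicted_U_per_mL,partition
1,34,6.5,160,0.5,2,0.75,2.80,2.5,train
2,34,6.5,160,0.5,3,1.25,4.70,4.78,train
3,34,6.5,160,1.5,2,1.25,5.10,5.00,train
4,34,6.5,160,1.5,3,0.75,5.40,5.26,test
5,34,6.5,180,0.5,2,1.25,5.70,5.79,train
6,34,6.5,180,0.5,3,0.75,5.80,5.75,train
7,34,6.5,180,1.5,2,0.75,5.90,6.12,train
8,34,6.5,180,1.5,3,1.25,6.60,6.69,train
9,34,7.5,160,0.5,2,1.25,4.80,4.78,train
10,34,7.5,160,0.5,3,0.75,4.60,4.54,train
11,34,7.5,160,1.5,2,0.75,5.20,4.96,train
12,34,7.5,160,1.5,3,1.25,5.80,5.88,train
13,34,7.5,180,0.5,2,0.75,3.60,3.45,test
14,34,7.5,180,0.5,3,1.25,5.70,5.92,train
15,34,7.5,180,1.5,2,1.25,6.50,6.54,train
16,34,7.5,180,1.5,3,0.75,5.30,5.30,test
17,38,6.5,160,0.5,2,1.25,5.30,5.26,train
18,38,6.5,160,0.5,3,0.75,6.50,6.42,train
19,38,6.5,160,1.5,2,0.75,5.80,5.54,train
20,38,6.5,160,1.5,3,1.25,4.70,4.81,train
21,38,6.5,180,0.5,2,0.75,5.40,5.28,train
22,38,6.5,180,0.5,3,1.25,5.90,6.10,train
23,38,6.5,180,1.5,2,1.25,5.40,5.42,test
24,38,6.5,180,1.5,3,0.75,5.60,5.58,train
25,38,7.5,160,0.5,2,0.75,5.20,5.07,train
26,38,7.5,160,0.5,3,1.25,6.50,6.24,train
27,38,7.5,160,1.5,2,1.25,5.60,5.61,train
28,38,7.5,160,1.5,3,0.75,5.70,5.57,train
29,38,7.5,180,0.5,2,1.25,4.80,4.90,test
30,38,7.5,180,0.5,3,0.75,4.50,4.56,train
31,38,7.5,180,1.5,2,0.75,4.20,4.08,train
32,38,7.5,180,1.5,3,1.25,3.30,3.55,test
33,32,7,170,1,2.5,1,5.10,5.11,train
34,40,7,170,1,2.5,1,5.10,5.20,train
35,36,6,170,1,2.5,1,5.70,5.74,train
36,36,8,170,1,2.5,1,5.00,5.07,test
37,36,7,150,1,2.5,1,5.60,6.23,train
38,36,7,190,1,2.5,1,7.10,6.58,train
39,36,7,170,0,2.5,1,5.80,5.92,train
40,36,7,170,2,2.5,1,6.50,6.49,train
41,36,7,170,1,1.5,1,5.50,5.89,test
42,36,7,170,1,3.5,1,7.00,6.72,train
43,36,7,170,1,2.5,0.5,5.00,5.65,train
44,36,7,170,1,2.5,1.5,7.10,6.56,train
45,36,7,170,1,2.5,1,7.50,7.32,train
46,36,7,170,1,2.5,1,7.20,7.32,test
47,36,7,170,1,2.5,1,7.40,7.32,train
48,36,7,170,1,2.5,1,7.30,7.32,train
49,36,7,170,1,2.5,1,7.40,7.32,test
50,36,7,170,1,2.5,1,7.40,7.32,train
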
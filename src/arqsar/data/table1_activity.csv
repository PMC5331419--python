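compound_id,pic50_exp,pic50_pred,split
1,6.04,5.91,pred_a
2,6.14,6.15,pred_a
3,5.70,5.81,pred_a
4,6.77,6.88,train
5,6.18,6.23,train
6,6.52,6.71,pred_a
7,5.24,6.76,train
8,6.07,5.95,train
9,6.60,6.53,train
10,6.38,6.27,train
11,6.04,6.06,train
12,6.48,6.48,pred_a
13,6.28,5.80,train
14,5.54,5.47,train
15,6.47,6.17,train
16,5.47,5.81,train
17,5.74,5.51,pred_a
18,5.89,5.80,train
19,5.46,5.61,train
20,5.96,6.35,train
21,6.38,6.12,pred_a
22,6.38,6.07,train
23,6.72,6.64,train
24,6.52,6.46,train
25,5.80,5.84,train
26,6.14,6.30,train
27,6.52,6.46,train
28,6.31,6.48,train
29,6.35,6.18,train
30,6.32,6.06,train
31,6.03,5.80,train
32,5.74,5.60,train
33,5.20,5.50,train
34,5.18,5.24,train
35,6.70,6.59,train
36,6.28,6.59,train
37,6.02,6.38,pred_b
38,5.66,5.49,pred_b
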
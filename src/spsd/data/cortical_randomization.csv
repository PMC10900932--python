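model,f1,f2,f3,f4,f5,f6,df_cbv
1,3.5,3.5,3.5,3.5,3.5,3.5,0.996
2,3.8,3.2,4.3,2.9,2.1,4.7,1.010
3,3.7,2.6,4.6,3.4,2.6,4.1,0.948
4,3.7,3.1,3.8,4.4,1.3,4.7,0.956
5,2.4,4.1,5.0,4.9,4.2,0.4,0.971
6,3.4,2.9,4.7,1.5,3.7,4.8,0.962
7,0.2,4.9,4.7,1.9,4.7,4.6,1.000
8,3.3,3.6,3.4,1.1,4.8,4.8,0.963
9,3.8,4.1,1.0,2.9,4.6,4.6,0.981
10,2.2,4.3,4.2,4.8,2.8,2.7,0.973
11,3.6,3.7,1.5,4.0,3.3,4.8,0.998
12,3.4,3.6,4.6,3.2,1.5,4.7,0.981
13,3.0,3.2,3.6,3.5,3.9,3.6,0.993
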
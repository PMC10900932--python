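n,df_tbv_rho165,df_tbv_rho190,diff_tbv_pct,df_cbv_rho165,df_cbv_rho190,diff_cbv_pct
1,1.69,1.88,11,2.58,2.92,13
2,1.31,1.45,10,3.66,4.1,12
3,6.21,6.53,5,3.63,4.07,12
4,1.3,1.41,8,4.69,5.22,11
5,4.92,4.91,0,5.3,4.22,20
6,4.8,4.93,3,3.57,3.96,11
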
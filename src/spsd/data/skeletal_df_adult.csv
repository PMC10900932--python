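source,nuclide,mean,ci_low,ci_high,shared_pct,unshared_pct,overall_pct
TBV,Sr90,4.20,2.4,6.2,6,25,26
TBV,Sr89,2.33,1.5,3.4,7,25,26
CBV,Sr90,1.54,0.8,2.6,11,36,38
CBV,Sr89,0.74,0.4,1.3,9,37,38
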
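parameter,Atenolol,Powder Blend
Da,3.49,4.01
Dc,3.96,4.13
Ie,2.84,2.83
Ic,2.37,2.37
Icd,0.267,0.346
IH,9.35,9.33
alpha,0.94,1.27
t,0.83,1.80
HR,4.04,5.47
H,4.66,6.96
Pf,3.78,3.97
Itheta,4.50,5.50
DE,1.21,0.14
DCD,6.33,1.99
DSD,5.06,0
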
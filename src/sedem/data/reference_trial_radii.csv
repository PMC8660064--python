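parameter,Trial-1,Trial-2,Trial-5,Trial-8,Trial-9,Trial-10,Trial-11,Trial-12,Trial-13
Da,6.58,5.13,7.49,5.01,5.98,5.36,7.01,6.08,6.19
Dc,6.89,5.89,7.83,5.33,6.19,5.78,7.18,6.71,6.43
Ie,0.567,2.09,0.483,1,0.475,1.133,0.283,1.283,0.5
Ic,0.9,2.58,0.868,1.2,0.678,1.454,0.476,1.878,0.746
Icd,5.5165,6.8825,9.75,5.09,6.95,5.46,6.07,5.64,7.435
IH,9.765,9.25,9.775,9.68,9.825,9.61,9.88,9.48,9.8
alpha,5.914,5.062,5.284,5.378,5.42,5.274,5.962,5.038,5.406
t,8,7,8.5,5.5,6.5,7.5,8,8,7.5
HR,7.09,7.31,6.99,7.57,7.33,6.92,7.42,7.46,7.41
H,7.985,8.03,8.445,7.855,8.04,8.12,8.07,8.16,8.145
Pf,8.778,8.522,9.408,6.212,9.168,8.562,8.714,8.944,8.804
Itheta,7.5,5.5,7,7.5,8.5,7,7,9.5,8
DE,-5.66,-7.04,-8.92,-0.78,0.44,1.42,-6.12,-7.46,-8.24
DCD,-1.233,-1.699,-7.299,-0.3333,1.167,2.299,-5.333,-6.066,-6.599
DSD,-7.366,-9.232,-13.632,-7.233,-2.366,-0.633,-9.766,-10.3656,-13.099
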
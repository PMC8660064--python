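batch_id,Dimension,Compressibility,Flowability/Powder Flow,Lubricity/Stability,Lubricity/Dosage,Disgregability
Atenolol,3.725,1.825,3.707,4.348,4.141,4.2
Powder Blend,4.07,1.85,4.134,6.215,4.734,0.713
Trial-1,6.735,2.33,7.893,7.538,8.139,0
Trial-2,5.51,3.85,7.104,7.67,7.011,0
Trial-5,7.66,3.7,7.853,7.718,8.204,0
Trial-8,5.17,2.43,6.853,7.712,6.856,0
Trial-9,6.085,2.701,7.25,7.685,8.834,0.147
Trial-10,5.57,2.68,7.46,7.52,7.781,0.473
Trial-11,7.095,2.276,7.947,7.745,7.857,0
Trial-12,6.395,2.934,7.506,7.81,9.222,0
Trial-13,6.31,2.894,7.569,7.778,8.402,0
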
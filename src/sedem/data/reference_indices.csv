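batch_id,IP_odt,IPP_odt,IGCB,IP_classic,IPP_classic,IGC
Atenolol,0.2,3.58,3.47,0.083,3.419,3.255
Powder Blend,0.267,3.34,3.24,0.333,3.999,3.807
Trial-1,0.667,5.03,4.89,0.833,6.29,5.988
Trial-2,0.667,4.88,4.74,0.833,6.104,5.811
Trial-3,0.667,5.03,4.89,0.833,6.29,5.989
Trial-4,0.667,5.03,4.89,0.833,6.29,5.989
Trial-5,0.667,5.45,5.29,0.833,6.819,6.491
Trial-6,0.667,5.03,4.89,0.833,6.29,5.989
Trial-7,0.667,5.03,4.89,0.833,6.29,5.989
Trial-8,0.667,4.49,4.36,0.833,5.61,5.341
Trial-9,0.667,5.03,4.89,0.833,6.26,5.954
Trial-10,0.667,4.91,4.76,0.833,6.014,5.726
Trial-11,0.667,5.07,4.92,0.833,6.339,6.034
Trial-12,0.667,5.21,5.06,0.833,6.514,6.202
Trial-13,0.667,5.09,4.94,0.833,6.364,6.058
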
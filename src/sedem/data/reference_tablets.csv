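trial_id,average_weight_mg,weight_variation_pct,thickness_mm,thickness_sd,crushing_strength_kg,specific_crushing_strength,tensile_strength,friability_pct,wetting_time_s,drug_content_pct,drug_content_sd,disintegration_min,disintegration_sd,q15_pct,q15_sd
Trial-1,258.21,3.5,3.48,0.31,9.86,0.27,0.172,0.45,195,98.63,0.78,8.5,0.91,62.39,0.74
Trial-2,252.68,2.91,3.65,0.46,7.19,0.188,0.119,0.72,168,99.7,0.91,10.8,0.37,65.19,0.92
Trial-5,252.91,3.11,3.34,0.29,12.07,0.344,0.219,0.31,249,99.17,0.46,12.65,0.98,21.37,1.19
Trial-8,254.92,3.12,3.61,0.52,5.3,0.14,0.089,1.3,139,99.67,0.38,6.8,0.29,79.52,1.43
Trial-9,256.17,3.73,3.47,0.18,9.12,0.25,0.159,0.4,182,98.02,0.63,8.2,1.17,63.18,0.91
Trial-10,255.36,3.19,3.68,0.37,6.73,0.174,0.111,0.78,154,97.68,0.93,7.5,0.98,68.4,0.73
Trial-11,252.19,2.85,3.41,0.39,10.48,0.293,0.186,0.39,201,99.11,0.52,10.3,0.34,52.07,1.16
Trial-12,254.8,3.26,3.59,0.24,8.63,0.229,0.146,0.45,174,100.73,0.79,7.8,0.69,70.02,0.39
Trial-13,251.98,2.71,3.43,0.26,11.8,0.328,0.208,0.19,235,99.82,0.32,10.9,1.08,48.73,0.83
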
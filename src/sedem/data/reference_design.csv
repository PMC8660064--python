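trial_id,time_coded,granulation_time_s,binder_coded,binder_concentration_pct
Trial-1,0,45,0,10
Trial-2,1,60,-1,5
Trial-3,0,45,0,10
Trial-4,0,45,0,10
Trial-5,1,60,1,15
Trial-6,0,45,0,10
Trial-7,0,45,0,10
Trial-8,-1,30,-1,5
Trial-9,-1,30,1,15
Trial-10,0,45,-1,5
Trial-11,1,60,0,10
Trial-12,-1,30,0,10
Trial-13,0,45,1,15
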
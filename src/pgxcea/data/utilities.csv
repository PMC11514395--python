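state,age_band_lower,utility
response,40,0.871
response,50,0.842
response,60,0.823
response,70,0.79
response,80,0.736
relapse,,0.55
no_response,,0.48
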
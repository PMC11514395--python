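strategy,switch,titrate,observe,discontinue,suicide_attempt,p_suicide_death_given_attempt
PGX,0.68,0.2,0.25,0.26,0.06,0.006
SOC,0.45,0.24,0.25,0.08,0.06,0.006
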
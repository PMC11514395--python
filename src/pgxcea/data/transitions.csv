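strategy,target,probability
PGX,response,0.118
PGX,relapse_0,0.0949
PGX,relapse_1,0.0229
PGX,no_response,0.0965
PGX,suicide_death,0.1175
PGX,nonsuicide_death,0.118
SOC,response,0.117
SOC,relapse_0,0.2062
SOC,relapse_1,0.0572
SOC,no_response,0.0965
SOC,suicide_death,0.1176
SOC,nonsuicide_death,0.117
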
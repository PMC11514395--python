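strategy,gene,met_class,carrier,p_response,p_relapse_given_response,p_side_effect
PGX,CYP2D6,PM,CARRIER,0.37,0.099,0.49
PGX,CYP2D6,PM,NONCARRIER,0.37,0.099,0.49
PGX,CYP2D6,IM,CARRIER,0.37,0.099,0.49
PGX,CYP2D6,IM,NONCARRIER,0.37,0.099,0.49
PGX,CYP2D6,URM,CARRIER,0.35,0.099,0.3
PGX,CYP2D6,URM,NONCARRIER,0.35,0.099,0.3
SOC,CYP2D6,PM,CARRIER,0.37,0.233,0.9
SOC,CYP2D6,PM,NONCARRIER,0.37,0.233,0.9
SOC,CYP2D6,IM,CARRIER,0.37,0.233,0.7
SOC,CYP2D6,IM,NONCARRIER,0.37,0.233,0.7
SOC,CYP2D6,URM,CARRIER,0.35,0.233,0.3
SOC,CYP2D6,URM,NONCARRIER,0.35,0.233,0.3
PGX,CYP2C19,PM,CARRIER,0.58,0.099,0.49
PGX,CYP2C19,PM,NONCARRIER,0.58,0.099,0.49
PGX,CYP2C19,IM,CARRIER,0.48,0.099,0.49
PGX,CYP2C19,IM,NONCARRIER,0.48,0.099,0.49
PGX,CYP2C19,URM,CARRIER,0.37,0.099,0.49
PGX,CYP2C19,URM,NONCARRIER,0.37,0.099,0.49
PGX,CYP2C19,RM,CARRIER,0.37,0.099,0.49
PGX,CYP2C19,RM,NONCARRIER,0.37,0.099,0.49
SOC,CYP2C19,PM,CARRIER,0.48,0.23,0.55
SOC,CYP2C19,PM,NONCARRIER,0.48,0.23,0.55
SOC,CYP2C19,IM,CARRIER,0.37,0.23,0.51
SOC,CYP2C19,IM,NONCARRIER,0.37,0.23,0.51
SOC,CYP2C19,URM,CARRIER,0.37,0.23,0.49
SOC,CYP2C19,URM,NONCARRIER,0.37,0.23,0.49
SOC,CYP2C19,RM,CARRIER,0.37,0.23,0.9
SOC,CYP2C19,RM,NONCARRIER,0.37,0.23,0.49
PGX,CYP2D6,NORMAL,NONCARRIER,0.37,0.099,0.3
SOC,CYP2D6,NORMAL,NONCARRIER,0.37,0.233,0.3
PGX,CYP2C19,NORMAL,NONCARRIER,0.37,0.099,0.49
SOC,CYP2C19,NORMAL,NONCARRIER,0.37,0.23,0.49
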
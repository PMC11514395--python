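gene,met_class,strategy,first_line,discontinuation,increased_dose
CYP2D6,PM,SOC,25,6,47
CYP2D6,IM,SOC,25,6,47
CYP2D6,URM,SOC,25,6,47
CYP2D6,PM,PGX,12,6,25
CYP2D6,IM,PGX,12,6,25
CYP2D6,URM,PGX,24,6,47
CYP2D6,NORMAL,SOC,25,6,47
CYP2D6,NORMAL,PGX,25,6,47
CYP2C19,PM,SOC,76,38,152
CYP2C19,IM,SOC,76,38,152
CYP2C19,URM,SOC,76,38,152
CYP2C19,RM,SOC,76,38,152
CYP2C19,PM,PGX,38,19,108
CYP2C19,IM,PGX,38,19,108
CYP2C19,URM,PGX,76,38,152
CYP2C19,RM,PGX,76,38,152
CYP2C19,NORMAL,SOC,76,38,152
CYP2C19,NORMAL,PGX,76,38,152
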
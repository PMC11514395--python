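gene,met_class,prevalence
CYP2D6,PM,0.0189
CYP2D6,IM,0.2328
CYP2D6,URM,0.0855
CYP2C19,PM,0.0187
CYP2C19,IM,0.198
CYP2C19,URM,0.0653
CYP2C19,RM,0.2984
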
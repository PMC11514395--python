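side_effect,cost
sexual_dysfunction,208
hyponatremia,129
arrhythmia,389
serotonin_syndrome,103
insomnia,12
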
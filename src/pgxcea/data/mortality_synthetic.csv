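midpoint_age,annual_rate
47,0.001834
52,0.002828
57,0.004362
62,0.006727
67,0.010375
72,0.016
77,0.024675
82,0.038055
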
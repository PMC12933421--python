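# Default calibration targets: pooled evacuation-compliance rate per framing
# (fractions, derived from the published per-condition counts fixture).
control: 0.009009009009009009
fear: 0.009009009009009009
efficacy: 0.012012012012012012
norm: 0.009009009009009009
fear_efficacy: 0.12312312312312312
fear_efficacy_norm: 0.15361445783132531
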
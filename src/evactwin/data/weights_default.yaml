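# Calibrated decision-rule parameters (grid search against the
# published per-framing evacuation rates; see docs/methods.md).
alpha: 0.2
beta: 0.005
gamma: 0.005
delta: 0.4
tau: 0.5
theta_threat: 0.58
theta_efficacy: 0.6
theta_threat_low: 0.0
intercept: 0.11248547669836474
logistic_scale: 8.0
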
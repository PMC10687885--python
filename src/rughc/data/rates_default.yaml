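# Synthetic hourly billing rates ($/h) by provider discipline.
# Only the ratio to the PSW rate matters downstream (standardized weights).
RPN: 55.0
RN: 75.0
OT: 90.0
PT: 90.0
SLP: 95.0
SW: 80.0
RD: 85.0
PTA: 50.0
PSW: 30.0
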
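# HX34 human melanoma: radiosensitivity parameters with posterior SDs.
name: HX34
alpha0: 0.263
alpha0_sd: 0.016
beta0: 0.047
beta0_sd: 0.005
repair_rate: 8.857
repair_rate_sd: 2.175
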
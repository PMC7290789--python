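# M8 human melanoma (primary cutaneous): radiosensitivity parameters.
name: M8
alpha0: 0.612
alpha0_sd: 0.130
beta0: 0.066
beta0_sd: 0.020
repair_rate: 8.769
repair_rate_sd: 2.128
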
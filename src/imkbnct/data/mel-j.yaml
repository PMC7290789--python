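# Mel-J human melanoma (lung metastasis): radiosensitivity parameters.
name: Mel-J
alpha0: 0.002
alpha0_sd: 0.047
beta0: 0.050
beta0_sd: 0.009
repair_rate: 8.916
repair_rate_sd: 2.126
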
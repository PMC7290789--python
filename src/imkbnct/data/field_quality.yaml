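# Reference field qualities: saturation-corrected dose-mean lineal energy y*
# (keV/um) and dose rate (Gy/min) for the calibration irradiation conditions.
# The BNCT entry is the total field at the stated 10B concentration.
photon:
  y_star: 2.26
  dose_rate_gy_min: 1.25
neutron_only:
  y_star: 41.36
  dose_rate_gy_min: 1.0
bnct:
  y_star: 68.50
  dose_rate_gy_min: 3.75
  ppm: 10.0
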
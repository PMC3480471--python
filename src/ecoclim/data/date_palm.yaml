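# Climate-response parameter set for date palm (Phoenix dactylifera).
# Temperatures in deg C, soil moisture as fraction of storage capacity,
# stress rates as non-negative magnitudes per week.
name: date_palm
dv0: 14.0
dv1: 20.0
dv2: 39.0
dv3: 46.0
sm0: 0.007
sm1: 0.013
sm2: 0.81
sm3: 0.9
ttcs: 4.0
thcs_rate: 0.01
tths: 46.0
thhs_rate: 0.9
smws: 0.9
hws_rate: 0.022
smds: 0.0
hds_rate: 0.0
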
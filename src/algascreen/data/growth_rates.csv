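strain,growth_rate_per_day,generation_time_h
Sp1.41,1.14,14.6
Sp1.43,0.74,21.1
Sp1.44,0.75,22.2
Sp1.46,0.69,24.0
Sp1.50,1.15,14.5
Sp1.52,0.97,17.2
Sp11.30,0.51,32.6
Sp12.07,0.55,30.2
Sp12.21,1.04,16.1
Sp12.36,0.90,18.6
Sp13.17,0.99,17.7
Sp14.35,0.96,17.41
Sp16.26,0.90,18.6
Sp16.34,1.10,15.1
SpU.9,0.59,28.1
Sp17.013,0.92,18.1
Sp17.022,0.65,25.6
Sp17.25,0.98,17.0
Sp17.38,1.12,14.9
Sp19.010,0.64,26.0
Sp19.011,1.24,13.5
Sp19.015,0.72,23.1
Sp19.15,1.22,13.7
Sp19.40,1.10,15.1
Sp21.01,0.69,24.0
Sp21.02,0.80,20.7
Sp21.12,0.40,41.8
Sp21.14,0.75,22.1
Sp21.20,0.42,39.8
Sp21.37,1.10,15.1
Sp21.23,1.07,15.6
Sp23.13,0.55,30.3
Sp24.1,0.55,30.3
Sp24.05,0.50,33.2
LO47,0.74,22.5
LO48,1.00,16.7
LO49,1.08,22.2
LO51,0.58,29.1
WW3,0.63,25.3
WW5,0.58,28.7
WW8,0.80,20.7
WW27,0.77,21.7
WW39,0.66,25.4
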
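strain,cetane_number,iodine_value,degree_of_unsaturation,lcsf,saponification_value,cfpp_printed
Sp1.41,59.4,51.9,57.7,4.44,207,-3
Sp1.43,61.0,45.0,50,5.12,209,0
Sp1.44,53.7,74.3,66.9,4.9,207,-1
Sp1.46,58.0,56.3,62.5,4.01,210,-4
Sp1.50,18.9,207,120,2.37,215,-9
Sp1.52,55.4,67.0,60.4,4.51,209,-2
Sp12.07,44.6,108,76.7,4.11,211,-4
Sp12.21,57.4,59.7,56.6,4.1,207,-4
Sp12.36,55.3,68.7,68.6,3.45,206,-6
Sp14.35,60.3,48.3,53.7,4.69,208,-2
Sp16.26,59.1,53.7,59.8,4.02,206,-4
Sp16.34,45.6,110,104,0.55,200,-15
SpU9,65.6,13.3,37.3,8.26,241,9
Sp17.013,36.3,139,85.7,4.16,214,-3
Sp17.022,66.0,22.7,46.1,6.44,214,4
Sp17.25,61.3,42.9,47.6,6.02,210,2
Sp19.010,55.0,68.0,60.5,4.4,210,-3
Sp19.011,54.7,68.0,57.7,4.59,212,-2
Sp19.15,56.4,63.2,59.8,4.43,208,-3
Sp19.40,68.8,10.7,11.9,8.81,216,11
Sp21.02,25.3,186,118,3.51,206,-5
Sp21.12,58.1,56.6,56.6,4.71,208,-2
Sp21.14,55.0,68.5,62,5.15,208,0
Sp21.20,53.9,71.9,60,5.76,210,2
Sp21.37,60.7,46.5,51.7,4.83,208,-1
Sp23.13,69.1,9.60,10.6,8.94,216,12
Sp24.05,47.7,94.8,69,4.18,213,-3
LO47,56.1,61.1,42,7.24,215,6
LO48,53.9,73.9,71.3,3.44,206,-6
LO49,52.6,78.6,66.2,5.15,207,0
LO51,67.8,14.5,48.8,6.88,217,5
WW3,53.9,73.5,73.1,2.67,207,-8
WW39,49.5,93.0,90.6,1.45,203,-12
WW5,31.0,162,35.2,2.01,210,-10
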
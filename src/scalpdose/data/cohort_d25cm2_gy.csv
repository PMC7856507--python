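patient,ptv_cc,sc1,sc2,sc3,sc4,sc5
A,168.19,33.1,37.9,36.8,35.1,35.4
B,242.66,36.8,41.4,43.9,40.7,39.4
C,361.77,46.2,49.5,50.3,48.1,48.0
D,365.68,42.8,46.0,46.7,44.5,44.4
E,190.45,32.6,36.3,36.7,35.3,35.2
F,556.36,52.8,55.3,57.3,55.3,54.6
G,107.51,28.8,31.7,32.2,31.4,31.0
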
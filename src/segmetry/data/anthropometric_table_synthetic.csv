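segment,mass_fraction,density_kgm3,length_fraction
head,0.0694,1110,0.130
shoulders,0.0400,1040,0.047
thorax,0.1250,920,0.150
abdomen,0.1600,1010,0.081
pelvis,0.1100,1020,0.078
arm,0.0271,1070,0.172
forearm,0.0162,1130,0.157
hand,0.0061,1160,0.108
thigh,0.1416,1050,0.245
shank,0.0433,1090,0.246
foot,0.0137,1100,0.152
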
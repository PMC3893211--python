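compound,0.125,0.25,0.5,1,2.5,5,10
Imatinib,100,100,100,100,100,100,100
Dasatinib,100,100,100,100,100,100,100
Parthenolide,100,100,100,100,100,100,0
TDZD-8,100,100,100,100,100,100,100
Arsenic trioxide,100,100,100,100,100,100,100
Niclosamide,100,100,100,0,0,0,0
Salinomycin,100,100,100,0,0,0,0
Thioridazine,100,100,100,100,100,0,0
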
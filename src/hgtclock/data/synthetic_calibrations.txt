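3
Cyanobacteria_1 Cyanobacteria_2 2450 -1
Cyanobacteria_1 Cyanobacteria_2 -1 1200
GSB_1 GSB_2 -1 1640
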
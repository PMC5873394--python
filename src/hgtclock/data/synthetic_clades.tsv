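# Synthetic demo clade table for the bundled stand-in species tree
# (synthetic_truth.nwk). name<TAB>crown|stem<TAB>comma-separated leaf labels.
Root	crown	Sericytochromatia_1,Melainabacteria_1,Melainabacteria_2,Cyanobacteria_Gloeobacter,Cyanobacteria_1,Cyanobacteria_2,Chloroflexi_1,Chloroflexi_2,GNS_1,GNS_2,Alphaproteobacteria_1,Bacteroidetes_1,Ignavibacteria_1,GSB_1,GSB_2
Cyanobacteria	stem	Cyanobacteria_Gloeobacter,Cyanobacteria_1,Cyanobacteria_2
Cyanobacteria	crown	Cyanobacteria_Gloeobacter,Cyanobacteria_1,Cyanobacteria_2
CyanobacteriaNoGloeobacter	crown	Cyanobacteria_1,Cyanobacteria_2
GNS	stem	GNS_1,GNS_2
GNS	crown	GNS_1,GNS_2
GSB	stem	GSB_1,GSB_2
GSB	crown	GSB_1,GSB_2
Chloroflexi	crown	Chloroflexi_1,Chloroflexi_2,GNS_1,GNS_2
CyanobacteriaMelainabacteria	crown	Melainabacteria_1,Melainabacteria_2,Cyanobacteria_Gloeobacter,Cyanobacteria_1,Cyanobacteria_2
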
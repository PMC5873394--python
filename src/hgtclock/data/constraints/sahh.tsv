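# SahH (S-adenosyl-L-homocysteine hydrolase) index HGT:
# donor within Chloroflexi -> recipient common ancestor of
# Cyanobacteria and Melainabacteria. Crown-vs-crown is the weakest
# safe reading of a transfer "from within" the donor clade.
SahH	Chloroflexi	crown	CyanobacteriaMelainabacteria	crown
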
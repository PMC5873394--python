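# BchH (Mg-chelatase subunit) index HGT:
# donor within GNS (green non-sulfur bacteria) -> recipient stem GSB
# (green sulfur bacteria); a transfer into the stem predates the crown,
# so the recipient node is the GSB crown.
BchH	GNS	crown	GSB	crown
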
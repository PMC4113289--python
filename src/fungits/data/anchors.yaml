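# Conserved flanking motifs delimiting the ITS2: the 3' end of 5.8S and the
# 5' start of LSU. Treated as data; replace for other marker designs.
motifs_5p:
  - AACGCAGCGAAATGCGATACGTAGTG
motifs_3p:
  - TTGACCTCAAATCAGGTAGGACTACC
max_mismatches: 1
search_window_5p: 80
search_window_3p: 80
min_its2_len: 30
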
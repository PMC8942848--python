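# Default transmembrane-segment table for the class D1 receptor dimer.
# Ranges are inclusive author residue numbers, applied identically to both
# protomers of the symmetric dimer.  Anchors pin the generic-numbering offset
# of each helix (residue number -> "NxMM").

[segments]
"N-term" = [5, 48]
H1 = [49, 72]
ICL1 = [73, 75]
H2 = [76, 103]
ECL1 = [104, 109]
H3 = [110, 153]
ICL2 = [154, 160]
H4 = [161, 188]
ECL2 = [189, 200]
H5 = [201, 238]
ICL3 = [239, 241]
H6 = [242, 267]
ECL3 = [268, 277]
H7 = [278, 303]

[anchors]
53 = "1x43"
80 = "2x42"
128 = "3x29"
184 = "4x64"
201 = "5x25"
243 = "6x35"
290 = "7x50"
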
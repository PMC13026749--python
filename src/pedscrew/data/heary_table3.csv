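# Cross-tabulation of Heary grades for the same screws:
# rows = grading from the computed pedicle wall distance (dpw),
# columns = reference grading from intraoperative CBCT images.
# "/" marks breach directions with no corresponding grade in the scheme.
# The printed margins of this table are internally inconsistent with the
# cells (row "/" total 9 vs cell sum 5; grand total 240 vs 236; columns III
# and V); cells and printed margins are both preserved verbatim, and the
# loader flags the mismatch.
grade,I,II,III,IV,V,/,Total
I,202,1,0,0,0,0,203
II,2,4,0,0,0,0,6
III,0,0,1,0,0,0,1
IV,4,0,0,17,0,0,21
V,0,0,0,0,0,0,0
/,0,0,0,0,0,5,9
Total,208,5,0,17,1,5,240
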
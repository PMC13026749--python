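# Cross-tabulation of Gertzbein grades for 236 analyzable screws:
# rows = grading from the computed pedicle wall distance (dpw),
# columns = reference grading from intraoperative CBCT images.
# "/" marks breach directions with no corresponding grade in the scheme.
# The Total row/column reproduce the margins as printed in the source table.
grade,0,1,2,3,4,/,Total
0,202,0,0,0,1,0,203
1,4,10,2,0,0,0,16
2,0,0,5,0,0,0,5
3,0,0,0,0,0,0,0
4,2,0,0,0,5,0,7
/,0,0,0,0,0,5,5
Total,208,10,7,0,6,5,236
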
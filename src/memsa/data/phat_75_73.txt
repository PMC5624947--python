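# PHAT(75/73)-style transmembrane substitution matrix.
# Format: first non-comment line = residue alphabet; following lines =
# full square of integer scores in that order.
A R N D C Q E G H I L K M F P S T W Y V
  3  -2  -1  -2   0  -1  -2   1  -2   0   0  -2   0  -2  -1   1   0  -3  -2   0
 -2   7  -1  -2  -4   2   0  -3   1  -4  -4   3  -4  -4  -3  -2  -2  -4  -3  -4
 -1  -1   5   3  -4   1   1   0   1  -3  -3   0  -3  -4  -3   1   0  -5  -3  -3
 -2  -2   3   7  -5   1   3  -1   0  -4  -4   0  -4  -5  -3   0  -1  -6  -4  -4
  0  -4  -4  -5   8  -4  -5  -3  -4   0   0  -5   0   0  -4   0  -1  -3  -2   0
 -1   2   1   1  -4   6   3  -3   1  -3  -3   2  -3  -4  -3   0  -1  -4  -3  -3
 -2   0   1   3  -5   3   6  -3   0  -4  -4   1  -4  -5  -3  -1  -1  -5  -4  -4
  1  -3   0  -1  -3  -3  -3   6  -3  -3  -3  -3  -3  -3  -2   0  -2  -4  -4  -3
 -2   1   1   0  -4   1   0  -3   8  -3  -3   0  -3  -2  -3  -1  -2  -2   2  -3
  0  -4  -3  -4   0  -3  -4  -3  -3   3   2  -4   1   0  -4  -1   0  -1  -1   2
  0  -4  -3  -4   0  -3  -4  -3  -3   2   3  -4   1   0  -4  -1   0  -1  -1   2
 -2   3   0   0  -5   2   1  -3   0  -4  -4   6  -4  -4  -3  -1  -1  -5  -3  -4
  0  -4  -3  -4   0  -3  -4  -3  -3   1   1  -4   4   0  -4  -1   0  -1  -1   1
 -2  -4  -4  -5   0  -4  -5  -3  -2   0   0  -4   0   4  -4  -2  -1   1   3   0
 -1  -3  -3  -3  -4  -3  -3  -2  -3  -4  -4  -3  -4  -4   8  -1  -2  -5  -4  -4
  1  -2   1   0   0   0  -1   0  -1  -1  -1  -1  -1  -2  -1   4   2  -4  -2  -1
  0  -2   0  -1  -1  -1  -1  -2  -2   0   0  -1   0  -1  -2   2   4  -4  -2   0
 -3  -4  -5  -6  -3  -4  -5  -4  -2  -1  -1  -5  -1   1  -5  -4  -4   9   2  -1
 -2  -3  -3  -4  -2  -3  -4  -4   2  -1  -1  -3  -1   3  -4  -2  -2   2   7  -1
  0  -4  -3  -4   0  -3  -4  -3  -3   2   2  -4   1   0  -4  -1   0  -1  -1   3
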
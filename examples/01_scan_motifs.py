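"""Score a TRANSFAC motif against DNase-accessible sequences.

Parses a small TRANSFAC record, converts the counts to log2-odds weights
against a uniform background, and scans two sequences on both strands. The
printed score is the best-matching window; a sequence containing the motif
consensus reaches the matrix's maximum attainable score.
"""

from dhstf import parse_transfac, scan_max_score, to_scoring_matrix

TRANSFAC_TEXT = """\
AC  M00001
XX
NA  DEMO_TF
XX
P0      A      C      G      T
01  12  1  1  1
02   1 12  1  1
03   1  1 12  1
04   1  1  1 12
05  12  1  1  1
XX
//
"""

(pwm,) = parse_transfac(TRANSFAC_TEXT)
sm = to_scoring_matrix(pwm, background=(0.25, 0.25, 0.25, 0.25), pseudocount=1.0)

print(f"motif {pwm.id} ({pwm.factor_name}), consensus {pwm.consensus}, "
      f"max attainable score {sm.max_score:.3f} bits")

with_site = "TTTTGG" + "ACGTA" + "CCCTTT"          # consensus embedded
without_site = "TTTTGGTTGGTTGGTTT"                  # background only
for label, seq in [("with consensus", with_site), ("background", without_site)]:
    score = scan_max_score(sm, seq)
    print(f"  {label:15s} best window score = {score:7.3f}")

# The first sequence attains the maximum (a perfect consensus match on one
# strand); the second stays far below it, which is what separates candidate
# binding sites from background in the affinity matrix.
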
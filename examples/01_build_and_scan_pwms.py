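"""Parse a TRANSFAC frequency table, build a log-odds PWM, scan a sequence.

The PWM weight of base b at column i is ln((c_bi + q*p_b) / ((N_i + q)*p_b))
with pseudocount q = 1 and background p; a window's score is the sum of the
weights of its bases, and a reverse-strand match is reported at the
forward-strand start of the covered interval.
"""

from crmscan import (SequenceRecord, build_pwm, estimate_background,
                     parse_transfac_matrices, scan_sequence)

TRANSFAC_TEXT = """\
AC  M_DEMO
XX
NA  DemoFactor
XX
P0      A      C      G      T
01      1      0     18      1
02     18      1      1      0
03      1     18      1      0
04     18      0      1      1
05      0     18      2      0
06      1     17      0      2
07      0      1      1     18
08      2      0     18      0
09      1      1      0     18
10      0     18      1      1
XX
//
"""

(matrix,) = parse_transfac_matrices(TRANSFAC_TEXT)
print(f"parsed {matrix.factor_id} ({matrix.factor_name}), "
      f"{len(matrix)} columns, consensus-like word GACACCTGTC")

# background from the sequences we are about to scan
sequence = ("TTATAGCGGACAGTTACCAT" + "GACACCTGTC"  # consensus at 20, '+'
            + "CATTTTGGAGACGAT" + "GACAGGTGTC"     # revcomp at 45, '-'
            + "GTTTACATGAAAGGCAATCC")
record = SequenceRecord("demo_promoter", sequence, anchor_offset=0)
background = estimate_background([record.sequence])
pwm = build_pwm(matrix, background)
print(f"max achievable score: {pwm.max_score:.3f}")

hits = scan_sequence(record, pwm, threshold=0.75 * pwm.max_score)
for h in hits:
    print(f"hit at start {h.start:3d} strand {h.strand} score {h.score:.3f}")
print("-> the '+' hit is the planted consensus word; the '-' hit is its "
      "reverse complement, reported at its forward-strand start.")
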
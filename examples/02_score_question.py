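"""Score one answer to one scoring question, with its confidence range.

A question combining criteria with normalized weights 0.65 (hazard),
0.19 (transmission), and 0.27 (outcome) gets weight w_q = 0.37 (their
mean).  An expert answers value 2 of a maximum 3 with medium confidence
(half-width C = 1).
"""

from cszprio import question_score, question_weight, score_bounds

w_q = question_weight(0.65, 0.19, 0.27)
print(f"question weight w_q = {w_q:.2f}")

z = question_score(w_q, V=2, M=3)
z_low, z_high = score_bounds(w_q, V=2, C=1, M=3)
print(f"initial score   Z = w_q * V/M       = {z:.4f}  (~{z:.2f})")
print(f"confidence range  [{z_low:.4f}, {z_high:.4f}]  (~[{z_low:.2f}, {z_high:.2f}])")

# The initial score credits the question's weight in proportion to the
# ordinal answer; the range shifts the answer down/up by the confidence
# half-width (clamped to the answer scale), so a low-confidence answer
# contributes a wide score interval to the disease total.
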
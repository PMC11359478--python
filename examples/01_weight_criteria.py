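"""Derive crisp and fuzzy criterion weights from expert pairwise judgments.

Builds the packaged four-hazard example comparison matrix, checks its
consistency, and prints the full weight table: crisp geometric-mean
weights, Buckley triangular fuzzy weights, centroid-defuzzified values,
and normalized defuzzified weights.
"""

from cszprio import consistency, example_hazard_matrix, geometric_mean_weights
from cszprio.fixtures import EXAMPLE_HAZARD_LABELS
from cszprio.fuzzy import weight_table

matrix = example_hazard_matrix()
report = consistency(matrix, geometric_mean_weights(matrix))
print(f"consistency ratio: {report.cr:.3f} "
      f"({'acceptable' if report.acceptable else 'REJECTED'}; gate is CR < 0.10)")

table = weight_table(matrix, EXAMPLE_HAZARD_LABELS)
cols = ["label", "weight_2dp", "fuzzy_l_2dp", "fuzzy_m_2dp", "fuzzy_u_2dp",
        "defuzzified_2dp", "normalized_defuzzified_2dp"]
print(table[cols].to_string(index=False))

# The crisp weight is the normalized row geometric mean of the judgments.
# The fuzzy triple (l, m, u) spreads each weight over the judgment
# uncertainty: its mode m equals the crisp weight, and a wide l..u range
# flags criteria whose relative importance the judgments pin down poorly.
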
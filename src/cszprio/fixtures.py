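"""Packaged example inputs.

The four-hazard example matrix is a reconstruction: the published
demonstration shows the hazards (warming; flooding, storms and cyclones;
drought; sea level rise) and the weight table they produce, but not the
underlying judgments.  The judgment set below is the unique assignment on
the odd Saaty scale whose geometric-mean weights round to the published
crisp weights (0.10, 0.65, 0.19, 0.06) and whose ±1 fuzzification
reproduces every published fuzzy-weight component at two decimals.
"""

from __future__ import annotations

from .ahp import PairwiseComparisonMatrix, matrix_from_judgments

__all__ = [
    "EXAMPLE_HAZARD_IDS",
    "EXAMPLE_HAZARD_LABELS",
    "EXAMPLE_HAZARD_JUDGMENTS",
    "example_hazard_matrix",
]

EXAMPLE_HAZARD_IDS = ("warming", "flooding", "drought", "sea_level")

EXAMPLE_HAZARD_LABELS = {
    "warming": "Warming",
    "flooding": "Flooding, storms, and cyclones",
    "drought": "Drought",
    "sea_level": "Sea level rise",
}

#: One judgment per unordered hazard pair (criterion_a, criterion_b, intensity).
EXAMPLE_HAZARD_JUDGMENTS = (
    ("flooding", "warming", 7.0),
    ("drought", "warming", 3.0),
    ("warming", "sea_level", 3.0),
    ("flooding", "drought", 5.0),
    ("flooding", "sea_level", 7.0),
    ("drought", "sea_level", 3.0),
)


def example_hazard_matrix() -> PairwiseComparisonMatrix:
    """The reconstructed 4x4 example climate-hazard comparison matrix."""
    return matrix_from_judgments(EXAMPLE_HAZARD_JUDGMENTS, EXAMPLE_HAZARD_IDS, set_id="hazard")
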
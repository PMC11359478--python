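# cszprio — fuzzy-AHP prioritization of climate-sensitive zoonoses

`cszprio` is the computational engine behind workshop-based expert
prioritization of zoonotic diseases whose transmission responds to climate
hazards. National One Health panels (human, animal, and environmental
health experts) compare prioritization criteria pairwise, answer ordinal
scoring questions for each candidate disease, and attach a confidence
level to every answer; the package turns that elicitation data into a
ranked priority list with uncertainty ranges. It is aimed at
epidemiologists and analysts who run or post-process such workshops and
want a scriptable, reproducible alternative to spreadsheet pipelines.

## The method

**Criterion weighting (fuzzy AHP).** For each of three criterion sets —
climate hazards, biological transmission mechanisms, health outcomes —
every expert fills a reciprocal pairwise-comparison matrix $A = (a_{ij})$
on Saaty's nine-point scale ($a_{ij} \in \{1/9, \dots, 9\}$, elicited as
linguistic phrases from *extremely less important* to *extremely more
important*). Crisp weights are the normalized row geometric means
$w_i \propto (\prod_j a_{ij})^{1/n}$, and each matrix must pass Saaty's
consistency gate $CR = CI/RI < 0.10$ with
$CI = (\lambda_{\max} - n)/(n-1)$. To carry judgment uncertainty into the
weights, entries are fuzzified to triangular fuzzy numbers ($x \mapsto
(x-1, x, x+1)$, saturated at the scale ends) and propagated through
Buckley's fuzzy geometric mean, giving fuzzy weights
$\tilde w_i = (l_i, m_i, u_i)$ whose modes equal the crisp weights; these
are defuzzified by the centroid $(l+m+u)/3$ and renormalized. Group
weights combine matrices across experts by the element-wise geometric
mean.

**Disease scoring.** Each scoring question $q$ combines one criterion
from each set and carries weight $w_q$, the mean of the three normalized
criterion weights. An answer of ordinal value $V_{q,d}$ (maximum $M_q$)
with confidence half-width $C_{q,d}$ (high/medium/low → 0/1/2) scores

$$Z_{q,d} = w_q \frac{V_{q,d}}{M_q}, \qquad
Z_{\mathrm{low/high},q,d} = w_q \frac{V_{q,d} \mp C_{q,d}}{M_q}$$

with the shifted value clamped to $[0, M_q]$. Disease totals sum over
participants and questions, and are normalized by $P \sum_q w_q$ so a
disease every expert maxes out scores exactly 1. Diseases are ranked by
normalized score (ties: lower estimate, then id).

A seeded synthetic-workshop generator (`cszprio.synthetic`) emulates the
whole elicitation — near-consistent judgment matrices from Dirichlet
weight draws, ordinal answers driven by latent per-disease climate
sensitivities — so the full pipeline is testable without real data.

## Worked example

```python
from cszprio import (consistency, example_hazard_matrix,
                     geometric_mean_weights, question_score, score_bounds)
from cszprio.fuzzy import weight_table

m = example_hazard_matrix()          # packaged 4-hazard example judgments
print(f"CR = {consistency(m).cr:.3f}")
print(weight_table(m)[["criterion", "weight_2dp", "fuzzy_l_2dp",
                       "fuzzy_m_2dp", "fuzzy_u_2dp",
                       "defuzzified_2dp", "normalized_defuzzified_2dp"]])
print(question_score(0.37, V=2, M=3), score_bounds(0.37, V=2, C=1, M=3))
```

prints

```
CR = 0.084
   criterion  weight_2dp  fuzzy_l_2dp  fuzzy_m_2dp  fuzzy_u_2dp  defuzzified_2dp  normalized_defuzzified_2dp
0    warming        0.10         0.07         0.10         0.15             0.11                        0.10
1   flooding        0.65         0.49         0.65         0.86             0.67                        0.65
2    drought        0.19         0.13         0.19         0.27             0.20                        0.19
3  sea_level        0.06         0.04         0.06         0.09             0.06                        0.06
0.24666666666666667 (0.12333333333333334, 0.36999999999999994)
```

The matrix passes the CR < 0.10 gate; flooding dominates the hazard set
with crisp weight 0.65 and fuzzy weight (0.49, 0.65, 0.86) — a wide
interval signals that the judgments pin its importance down loosely. A
question of weight 0.37 answered 2-of-3 at medium confidence contributes
0.25 to the disease's total, with confidence range 0.12–0.37.

Longer narrative walkthroughs live in `examples/` (criterion weighting,
question scoring, a full synthetic workshop with rank-recovery check).

## Command line

`cszprio simulate | validate | weights | score | rank` mirror the
workshop pipeline as batch steps: generate or validate inputs, derive
per-participant and group weight reports (participants failing the
CR gate are rejected with the offending ratio), and write the ranked
priority list with plot-ready uncertainty data. Every command writes a
run manifest (input digests, options, seed, package version).

```sh
cszprio simulate --out ws --seed 1
cszprio weights --config ws/config.yaml --judgments ws/judgments.csv --out ws/weights
cszprio rank --config ws/config.yaml --responses ws/responses.csv \
             --weights-dir ws/weights --out ws/ranked
```

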
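# Methods

This note records the model, the numerical conventions, and the design
choices behind `cszprio`, in the order the pipeline runs them.

## Elicitation model

A workshop configuration consists of three ordered criterion sets —
climate hazards, biological transmission mechanisms, and health
outcomes — plus scoring questions, diseases, and participants. Each
question references exactly one criterion from each set and carries an
ordered list of multinomial, ordinal answer options. Option values are
consecutive integers starting at 0 or 1; the convention here starts
"no change" options at 0 and counts up by 1, so an answer of value 2 out
of a maximum of 3 contributes the fraction 2/3 of the question's weight.
Pairwise judgments are elicited on the nine-phrase linguistic scale
(*extremely less important* … *extremely more important*) mapped
bijectively onto the odd Saaty intensities {1/9, 1/7, 1/5, 1/3, 1, 3, 5,
7, 9}. Even intermediate intensities (2, 4, 6, 8 and reciprocals) are
accepted on numeric input for interoperability with other AHP tools but
are never produced by the linguistic scale.

Confidence labels map to integer half-widths on the answer scale:
high → 0, medium → 1, low → 2. Medium = 1 is the anchoring convention of
the scoring equations; the 0/2 values for high/low are the package
default, chosen so that higher confidence always yields a tighter score
range (the mapping is monotone by validation and configurable per
workshop in the `confidence_values` section).

## Crisp AHP

Weights default to the normalized row geometric mean,
`w_i ∝ (Π_j a_ij)^(1/n)`. The principal right eigenvector (hand-rolled
power iteration, L1-normalized, default tolerance 1e-12, 10 000 iteration
budget) is provided as an option; both are exact on cardinally consistent
matrices. The geometric mean is the default because it is the basis of
the fuzzy pipeline and reproduces the packaged example's published-style
weight table exactly; the two methods agree within 0.01 per component on
that example but can differ by slightly more than 0.01 on other
gate-passing matrices of order ≥ 5, so no blanket agreement bound is
asserted.

Consistency uses Saaty's row-ratio estimate
`λ_max = mean_i (A w)_i / w_i` computed from the supplied weight vector,
so CR is well defined for either weighting method; an eigen-decomposition
`λ_max` (LAPACK) is exposed separately for cross-checks and the two agree
to ~1e-3 on near-consistent matrices. `CI = (λ_max − n)/(n − 1)`,
`CR = CI/RI` with Saaty's random indices (0, 0, 0.58, 0.90, 1.12, 1.24,
1.32, 1.41, 1.45, 1.49 for n = 1..10, extended to n = 15 with the
commonly published continuation 1.51, 1.54, 1.56, 1.57, 1.59; the table
is an argument and can be swapped). Orders 1–2 are consistent by
construction (CR = 0). The CR < 0.10 gate is a flag at library level —
callers can still compute with an inconsistent matrix — but the CLI
refuses to accept a participant matrix that fails it, mirroring how an
interactive elicitation interface would force revision.

Group aggregation is the element-wise geometric mean, the only
reciprocity-preserving aggregation of judgment ratios; it is computed in
log space and antisymmetrized there so the result is reciprocal to
machine precision.

## Fuzzy weighting

Crisp intensities are fuzzified with a ±1 triangular spread saturated at
the scale ends: 1 → (1,1,1), x ∈ {2..8} → (x−1, x, x+1), 9 → (8,9,9),
and reciprocals map to fuzzy reciprocals (1/u, 1/m, 1/l). The ±1 spread
is the package default because it reproduces the reference example's
fuzzy weight table end to end; the (8,9,9) saturation is a choice the
example never exercises. TFN products and powers are componentwise
(the standard interval approximation), and Buckley's construction pairs
bounds conservatively in the final division:
`w̃_i = (l_ri/Σu, m_ri/Σm, u_ri/Σl)` from row fuzzy geometric means r_i.
Consequences used as invariants: modes equal the crisp geometric-mean
weights exactly (hence sum to 1), l ≤ m ≤ u throughout, and replacing the
fuzzification by the crisp embedding x → (x,x,x) collapses the fuzzy
weights to the crisp ones.

Defuzzification is the centroid `(l+m+u)/3`; normalized defuzzified
weights divide by the sum. Alternative operators (weighted mode,
α-cuts) are out of scope. For groups, each participant's matrix is
fuzzified first, the fuzzy matrices are combined componentwise by the
geometric mean, and Buckley is applied to the result — the symmetric
extension of the crisp group path; defuzzification happens after
aggregation. Display rounding is 2 decimals, half away from zero, with
full precision retained internally.

## Scoring and ranking

Question weight w_q is the arithmetic mean of the three normalized
criterion weights the question references (taken from the
normalized-defuzzified column of the group tables). Answer V with
confidence half-width C on a question of maximum M scores
`Z = w_q V/M` with bounds `w_q max(V−C, 0)/M` and `w_q min(V+C, M)/M`.
The clamp keeps every per-question score in [0, w_q]; it never triggers
in the interior worked example (V=2, C=1, M=3 → 0.25 in 0.12–0.37).

Disease totals sum Z, Z_low, Z_high over all participants and questions.
Complete answering is required by default: a missing
(participant, disease, question) triple is an error, and an explicit
`impute_missing` option scores absences as V = 0 with low confidence
(recorded in the run manifest when invoked via the CLI). Normalized
scores divide the raw sums by `P · Σ_q w_q` (P = number of
participants), the maximum attainable total, so normalized scores live
in [0, 1], reach 1 iff every response is maximal, and 0 iff every
response is zero. Ranking is by normalized score descending, ties broken
by the lower estimate descending and then disease id, producing gapless
1-based ranks independent of input order.

## Synthetic workshop generator

The generator fixes the study conditions the rest of the test suite runs
under: 10 participants (panels of 6–15 are the intended operating
range), 10 questions, 25 diseases, 4 criteria per set, and 4 answer
options per question — the scale of the illustrative scenarios the
method is presented with. Judgments: each participant's true weight
vector is a Dirichlet(1) draw; consistent ratios w_i/w_j get
multiplicative log-normal noise (default σ = 0.1 on the log scale, a
mild perturbation that keeps most draws inside the CR gate) and are
snapped to the nearest odd Saaty value in log space (ratios are
multiplicative, so distance is measured on logs; the 7/9 boundary is at
√63). Matrices failing CR < 0.10 are redrawn, up to 1000 retries, so
generated judgments always pass the gate. Answers: each disease has a
latent sensitivity s_d ~ Uniform(0,1) (overridable); an answer adds
logistic noise (default scale 0.5) to logit(s_d) and rounds the resulting
propensity onto the question's value range — a discretized logistic link,
chosen for being simple and monotone in s_d. Confidence labels are
i.i.d. with P(low, medium, high) = (0.2, 0.5, 0.3), a
medium-heavy split plausible for a mixed expert panel. All randomness
flows from one integer seed through separate child streams for
questions, matrices, and responses; identical configurations give
byte-identical output files.

What the generator does *not* emulate: correlated expert opinion,
sector-specific bias, question-specific answer difficulty, or
informative confidence (confidence is independent of answer accuracy).
Passing tests therefore show that the pipeline recovers structure under
idealized independent noise, not that real panels are this well behaved.
One resolution limit matters for interpreting recovery tests: with
answer maximum M, latent sensitivities closer than 1/M collide onto the
same ordinal value, so zero-noise rank recovery is exact only for
sensitivities the answer scale can resolve; recovery tests use one
answer level per disease where exactness is the correct expectation, and
Spearman correlation ~0.97–1.0 otherwise.

## Numerical conventions and degenerate inputs

Reciprocity is validated to 1e-9 (absolute, on a_ij·a_ji); weight vectors
must sum to 1 within 1e-9. Intensity parsing accepts decimals,
'1/7'-style fractions (preserved on write), and linguistic phrases,
case-insensitively. A single-criterion set degenerates cleanly: weight
1.0, fuzzy weight (1,1,1). Power iteration starts uniform, which cannot
be orthogonal to the Perron vector of a positive matrix. Test problem
sizes (4–10 participants, ≤ 10 questions, ≤ 25 diseases) keep the whole
suite in a few seconds; they match the method's intended workshop scale,
which is inherently desk-sized.

## Known limitations

- No incomplete-matrix imputation and no alternative consistency indices
  (geometric consistency index, Koczkodaj); inconsistent matrices must
  be revised, not repaired.
- No fuzzy extent analysis (Chang) or general fuzzy-set algebra; TFNs
  and the operations above are the whole fuzzy surface.
- No statistical test of rank separation between adjacent diseases; the
  reported intervals are elicitation-confidence ranges, not sampling
  confidence intervals.
- The final deliberation step of a real workshop (consensus validation
  of the list) is human and out of scope.
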
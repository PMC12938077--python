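# Methods

## Problem and model

An n-way junction is a loop of a nested RNA secondary structure closed on
all sides by n ≥ 2 stems (maximal runs of stacked canonical base pairs;
internal loops and bulges are the n = 2 case). The package predicts which
cyclically adjacent stem pairs stack coaxially. The sample unit is the
*pseudo two-way junction*: an adjacent stem pair (H1, H2) with the unpaired
loop `L0` that connects them directly, the two flanking loops `L1`/`L2` on
the far arc, and the count `N = n − 2` of stems standing between them. A
single random-forest classifier scores all pairs regardless of junction
order; the junction-level configuration is then the maximum-weight matching
of the above-threshold pair probabilities on the junction's cycle graph.
The matching constraint encodes the physics: a helix end can stack on at
most one partner.

Assumptions: structures are fully nested (pseudoknotted input is rejected,
because the loop bookkeeping that defines L0/L1/L2 would silently corrupt
otherwise); junctions are loops closed by stems on every side, so stems
meeting only at the exterior loop are not decomposed (their stacking is
governed additionally by dangling ends the model does not describe);
stacking between non-adjacent stems is out of scope.

## Coordinates and decomposition conventions

Indices are 0-based internally; serialized output uses 1-based inclusive
ranges. Stems within a junction are ordered by their 5′-most residue, the
closing stem first; pair names (H1–H2, …) follow that order. For a pair
taken from an n-way junction, `loop0` is the junction-loop segment between
H1 and H2 along the direct arc, and `loop1`/`loop2` are the far-arc
segments flanking H1 and H2. For a true two-way junction `loop0` is the
5′-side loop and `loop1 = loop2` is the 3′-side loop. No minimum stem
length is imposed (1-bp stems pass through; filtering is a curation
concern).

## Thermodynamics

Helix free energies use the Watson–Crick–Franklin nearest-neighbor model at
37 °C: ΔG° = init + AU/GU-end penalties + symmetry correction + Σ stack
terms. Parameters ship as a versioned plain-text file
(`data/turner2004_dg37.txt`), Turner 2004 rule set: initiation 4.09,
AU/GU-end 0.45, self-complementary correction 0.43 kcal/mol, and the 36
canonical nearest-neighbor steps (Watson–Crick entries at the published
0.01 kcal/mol precision; GU-wobble entries at 0.1 kcal/mol precision). A
1-bp stem has both helix ends on the same pair, so an AU/GU pair there is
penalized twice — a documented degenerate case without physical relevance.

The coaxial stacking energy between adjacent stems is piecewise in the
connecting-loop length L0, with empirical constants a = 9.3, b = 0,
c = −0.6 kcal/mol and a 2.1 kcal/mol terminal-mismatch penalty:

| branch      | value                              |
|-------------|------------------------------------|
| L0 = 0      | flush-stack table at the interface step |
| L0 = 1      | mismatch-stack table + 2.1         |
| 2 ≤ L0 ≤ 6  | a + b·L0 + 2c                      |
| L0 > 6      | a + 6b + 1.1·ln(L0/6) + 2c         |

The function is continuous at L0 = 6 and strictly increasing beyond —
stacking propensity falls sharply with loop length. The interface step for
the table branches is the nearest-neighbor step formed by the two
junction-proximal closing pairs, read 5′→3′ on the continuous strand (the
standard flush-coax convention). The flush table is assigned the
continuous-backbone helix-stack values (the classic flush-stack
approximation); the mismatch-mediated base table likewise defaults to the
interface-step stack value, with the mismatch penalty added separately.
Both tables are independent sections of the parameter file, so measured
stack(1) values can be dropped in without code changes. Ambiguity codes are
rejected rather than guessed.

## Features and similarity

The 12-vector is (L0, L1, L2, A_L0, A_L1, A_L2, L_H1, L_H2, N, dG_H1,
dG_H2, dG_coax), serialized in exactly that order. The consecutive-adenine
statistic is the length of the longest A-run in the loop (A-runs, not total
A-count, are what matter for loop stacking chemistry); the total-count
alternative is available behind a switch without being endorsed. Features
enter the forest raw — tree splits are scale-invariant — but the cosine
feature-similarity score Fs used to relate a query pair to training samples
z-scores both vectors with training-set statistics first, because raw
mixed-unit cosines are dominated by the energy terms.

## Classifier

Reference hyperparameters: 703 trees, max depth 43, min split 5, min leaf
1, feature-sampling ratio 0.23, positive class weight 4.8 (classes are
imbalanced roughly 6:1 toward stacking). Retraining recomputes the decision
threshold as the first upward crossing of the Gaussian KDEs of the
out-of-fold predicted probabilities of the two classes (Silverman's
0.9·min(σ, IQR/1.34)·n^(−1/5) bandwidth with a 0.01 floor for degenerate
samples, 512-point grid on [0, 1], linear interpolation at the sign change,
0.5 fallback with a warning when the densities never cross); the shipped
reference threshold is 0.42 and can be pinned. Note that on heavily
imbalanced training sets the KDE crossing can sit far above 0.5 — with a
6:1 synthetic set it lands near 0.95 — which is the expected behavior of
the crossing rule, not a defect; pin the threshold when comparability
matters. Hyperparameter search is a seeded Gaussian-process (Matern ν=2.5)
expected-improvement loop: five random initializations, ten guided
iterations, each configuration scored by stratified 10-fold CV. The CV
objective defaults to AUC (robust to the imbalance; recorded in model
metadata). Small finite search spaces are evaluated exhaustively. Feature
importances are split-based: Gini from the trained forest, information gain
from a companion entropy-criterion forest fitted on the retained training
data. Rows with missing features are rejected, not imputed — all 12
features are always computable from valid input.

## Reconstruction

Edges with probability strictly above the threshold are retained (a pair at
exactly the threshold is not). The maximum-weight matching on the cycle is
computed by exact dynamic programming — condition on the wrap-around edge,
solve two path recurrences f(k) = max(f(k−1), f(k−2) + w_k) — in O(n), and
cross-checked against brute-force enumeration. Ties between equal-weight
matchings resolve to fewer edges, then the lexicographically smallest pair
set, so outputs are deterministic. An order-2 junction degenerates to one
candidate edge (binary outcome). Raw probabilities are summed without
renormalization. Configuration counts are the cycle-matching numbers
2, 4, 7, 11, 18, … (Lucas recurrence) for orders 2, 3, 4, 5, 6, ….

## Metrics

For junction orders below five the headline metric is exact-match
configuration accuracy (one spurious or missing stack makes the junction
wrong); pairwise accuracy PA — the fraction of the junction's cyclically
adjacent pairs whose stacked/unstacked status is correct — is reported for
all orders and is the headline metric from order five up. Multi-junction PA
is macro-averaged (per junction, then averaged); pooled averaging over
pairs is available as an option. Binary metrics (accuracy, precision,
recall, F1, Cohen's kappa, rank-based AUC) come from the standard confusion
matrix; AUC on single-class input is reported as undefined rather than 0.5.

## Curation

Structure-level redundancy is removed by global Needleman–Wunsch alignment
of dot-bracket strings (+2 match, −1 mismatch, −2 gap; deterministic
traceback diagonal > up > left), similarity = identical aligned positions /
alignment length (shorter-sequence denominator available); pairs above 0.90
similarity are linked and single-linkage groups collapse to the
lexicographically first id — a chain A~B~C collapses even when A and C are
dissimilar, which is the intended single-linkage behavior. Splits are
per-order at fraction 0.85, seeded; orders with at most 3 members route
wholly to the test split so rare topologies test generalization. Sequence-
identity clustering and 3D-coordinate redundancy filtering are external
preprocessing steps outside this package's input format.

## Synthetic data: what it emulates and what it does not

The generator emits records realizing one junction each: a closing stem
enclosing order−1 hairpin stems. Defaults, chosen once as the study
conditions: 600 junctions; order mix 0.95/0.015/0.015/0.01/0.005/0.005 for
orders 2–7; stems 2–8 bp sampled as complementary duplexes with a 10% GU
fraction (so every energy-table branch is exercised); junction-loop lengths
from a geometric distribution truncated to 0–12 nt (mean ≈ 1.9 — real
junction connecting loops are short, and a thin upper tail keeps the
planted decision boundary out of the bulk); hairpin loops 3–7 nt.

Truth labels follow logit P(stack) = α − 1.5·L0 − 0.5·ΔG°37(H1−H2) per
pair, Bernoulli-sampled, then projected to a valid matching by greedily
dropping the lower-odds member of any conflict. The intercept α is
calibrated by bisection (against fixed uniform draws, hence deterministic)
to a 6:1 stacked:unstacked pair ratio. Two consequences are worth stating
plainly. First, a 6:1 ratio is only reachable when two-way junctions
dominate: an n-way junction can stack at most ⌊n/2⌋ of its n pairs, so an
order mix resembling raw junction surveys (~83% two-way) caps the ratio
near 3:1 — hence the 95% two-way default. Second, under the 6:1 target most
negative labels are conflict-capped pairs inside multiway junctions rather
than long-loop pairs; these negatives are flagged exactly by the topology
feature N, so in trained forests N competes with L0/dG_coax for top split
importance and can rank first depending on the random realization. The
importance ordering among those three features is therefore not a stable
property of this generator at 6:1 balance, even though held-out AUC stays
high (~0.97).

What passing tests on this data do show: the decomposition, features,
energies, training, thresholding, matching, and metrics interoperate and
recover a planted monotone loop-length/energy rule. What they do not show:
performance on real junctions — the generator has no tertiary contacts,
ligands, ions, non-canonical pairs, pseudoknots, or the sequence biases of
crystallized RNAs, and its truths derive from the same feature family the
classifier consumes.

## Problem sizes

The default test and acceptance runs use ~1750 synthetic junctions (~2050
pairs) for classifier recovery, 10-fold CV with the full 703-tree reference
forest, 1000 random weighted cycles for the matching oracle, and
 a few hundred junctions for end-to-end reconstruction checks.

## Known limitations

Temperature and ionic conditions are not modeled (the parameter tables are
ΔG°37); exterior-loop and non-adjacent stacking are out of scope; the
mismatch-mediated coax table is a stack-value approximation pending
measured values; junction family types are not predicted.
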
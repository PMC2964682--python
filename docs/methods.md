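# Methods notes

## Model and assumptions

The pipeline treats drug-target discovery as a link-prediction problem on
reactions rather than proteins. Its assumptions, stage by stage:

**Expression states.** Gene-to-reaction associations are stored flat (a set
of genes per reaction) because the state rule only quantifies over that set:
a reaction is highly expressed when at least one gene is high, lowly
expressed only when *all* observed genes are low, undetermined otherwise
(including any LOW/UNDETERMINED mixture, and reactions whose genes are all
absent from the expression table). Boolean AND/OR gene-rule structure is
deliberately not modelled; collapsing complexes into a flat set errs toward
calling a reaction highly expressed, which only relaxes the LP reward, never
the hard constraints. Genes with missing expression are dropped at load
rather than imputed.

There is no canonical definition of "highly expressed" for a normalized
array panel, so the threshold rule is configurable and prominent: the
default calls values strictly below the per-cell-line 25% quantile LOW and
strictly above the 75% quantile HIGH (a quartile analogue of tertile-based
activity schemes); absolute cutoffs are available via
`classify_genes(..., method="absolute")`.

**Flux LP.** The activity model maximizes Σ y over the relaxed indicators
subject to steady state S·v = 0, box bounds, and the big-M style rows that
make y⁺ = 1 force v ≥ ε (R_H, forward), y⁻ = 1 force v ≤ −ε (R_H, backward)
and y⁺ = 1 force v = 0 (R_L). Two deliberate choices:

* *No y⁺ + y⁻ ≤ 1 coupling.* The integer model needs none (both cannot be 1
  simultaneously when ε > 0), and the relaxation is kept as the plain
  continuous image of that model. Consequently both indicators can be
  fractional at once; e.g. on a 3-reaction chain with bounds [0, 10] and one
  highly expressed reaction the optimum is y⁺ = 1, y⁻ = 9/11 (objective
  20/11), with v = 1 along the chain forced uniquely. Tests pin this value.
* *Stabilization.* LP optima are degenerate in v, and reaction profiles must
  be reproducible, so by default a second pass minimizes Σ|v| (split-variable
  LP) subject to the activity objective held at its optimum (within 1e−9).
  This selects a sparse, minimal-total-flux representative deterministically;
  scipy's HiGHS solver is itself deterministic for a fixed problem.

Solver tolerances: primal feasibility 1e−9; reported solutions are checked
against S·v = 0 at 1e−6 and box bounds at 1e−9. Infeasible or unbounded
models are reported as such, never silently zeroed. The stoichiometric
matrix is held dense; at genome scale (~3k × 4k) this costs ~100 MB, which
is acceptable for the intended problem sizes but is the first thing to
change for substantially larger reconstructions.

**Profiles and similarity.** The flux threshold ε = 1 (arbitrary flux
units, the same ε as the LP) defines activity: |v| ≥ ε is active, the open
band (−ε, ε) inactive. Reactions inactive in every cell line have no
direction in profile space and are removed before cosine similarity;
feeding a zero-norm profile to `flux_similarity` is an error, not a silent
zero. Cosine similarity is clipped to [−1, 1] and symmetrized against
floating-point asymmetry.

**Sequence similarity.** Smith–Waterman local alignment (biopython's
`PairwiseAligner`) with BLOSUM62, gap open 10, gap extend 1 by default —
a conventional protein-alignment configuration, made explicit because the
choice materially affects raw scores. Normalization is by the geometric
mean of self-alignment scores, s_TS(s,t) = SW(s,t)/√(SW(s,s)·SW(t,t)):
symmetric, scale-free, exactly 1 on identity, and 0 only when no positive
local alignment exists. A simple match/mismatch matrix mode exists so tests
can check scores against a hand-filled DP table. Reaction structure
similarity defaults to the `max` aggregation over enzyme pairs, which
performs best for prediction among max/avg/min.

**DRN statistics.** β is the fraction of drug-sharing reaction pairs that
also share an enzyme, β(t) = |{p ∈ Γ_RER ∩ Γ_RDR : s(p) > t}| /
|{p ∈ Γ_RDR : s(p) > t}|; the complementary fraction 1 − β is the share of
pairs interacting with the same drug through *different* enzymes. All
cutoffs are strict (> t), pairs are unordered with distinct members, and an
empty denominator raises an explicit undefined-statistic error rather than
returning 0 — a 0 would be indistinguishable from "no overlap".

**Kernel KNN.** Association score = similarity-weighted mean of the k
nearest training labels, normalized by the sum of neighbor similarities.
Ties at rank k break toward the ascending reaction id (reproducibility);
negative cosine similarities participate in ranking as-is, and a
non-positive denominator yields score 0. Cross-validation folds partition
*reactions* (a held-out reaction is scored for all drugs at once), and each
repeat reports one AUC pooled over all (drug, held-out reaction) pairs.
AUC is the Mann–Whitney rank statistic with ties counted ½.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| ε | 1 (flux units) | activity threshold in the LP and the profile filter |
| q_low / q_high | 0.25 / 0.75 | per-cell-line expression quantile cutoffs |
| λ | 0.2 | weight of flux vs structure similarity in s_R |
| k | 20 | kernel KNN neighborhood size (5 on toy instances, see below) |
| score cutoff | 0.35 | reporting threshold for predicted pairs |
| folds × repeats | 10 × 50 | cross-validation design |
| gap open / extend | 10 / 1 | affine gap penalties under BLOSUM62 |

## The synthetic generator

One latent grouping — pathway modules — induces every signal the pipeline
exploits. Each module is an independent linear chain with exchange inflow
and outflow (so a nonzero steady-state flux is always available), one gene
and one enzyme per interior reaction. Modules switch on/off per cell line
(Bernoulli ½, adjusted so each module is on somewhere and off somewhere);
on-module genes draw Normal(8, 0.8) and off-module genes Normal(2, 0.8) on
a log2-microarray-like scale. Drugs home on modules round-robin and target
each home-module enzyme with probability p_within = 0.9 (otherwise a random
outside enzyme). Enzyme sequences form one family per module (150 residues,
5% per-residue substitutions from a shared ancestor). Default study size:
4 modules × 5 reactions, 20 cell lines, 8 drugs; at that size k = 5 is the
natural neighborhood (one module's worth of reactions minus the held-out
one), and single-repeat 10-fold CV over 10 seeds keeps the full-pipeline
checks fast.

What the toys do *not* emulate — and hence what passing tests do not show
about real data: branched/cyclic network topology and shared metabolites
across modules; reactions catalyzed by multiple enzymes or enzyme isoforms
shared across reactions (toy Γ_RER is empty, so β and P_E are degenerate at
0 on generated instances; their logic is exercised by constructed pair
sets); dosage-dependent partial expression; reversible fluxes (toy bounds
are [0, 10], so cosine similarity on toys never goes negative); and the
extreme sparsity of real drug-target maps.

The permutation null shuffles interaction labels across all
(drug, reaction) entries. A per-reaction column permutation would preserve
each drug's label count, and at toy sample sizes the without-replacement
coupling between a reaction's own label and its neighbors' labels biases the
pooled AUC visibly below ½ even with no signal; the global shuffle matches
the exchangeability assumption of the pooled statistic and sits at ≈ 0.5.

## Degenerate inputs and tie-breaking

* Quantile thresholds on a constant column: nothing is strictly beyond
  either quantile, so everything is UNDETERMINED.
* `filter_active` may return an empty matrix; `flux_similarity` on it is a
  0 × 0 matrix, and downstream prediction raises on an empty training set.
* AUC and the t-test refuse single-class / zero-variance inputs explicitly.
* Neighbor ties and nearest-profile ties resolve by ascending reaction id.

## Known limitations

* Gene rules are flattened; AND-complexes are treated as OR.
* The LP activity objective weights all reactions equally; no confidence
  weighting of expression calls.
* Dense stoichiometric storage (see above).
* Structure similarity requires sequences for every enzyme of every scored
  reaction; there is no partial-coverage fallback.
* Scores are vote fractions, not calibrated probabilities; the 0.35 cutoff
  is an operating point, not a significance level.
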
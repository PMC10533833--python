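# Methods

## The model

Each questionnaire wave is modelled as a pairwise Markov random field
(MRF) over mixed node families: gaussian nodes for age, HIV risk
perception and the 30 PrEP/VLS belief items (1–7 agreement scales), and
binary nodes for PrEP use, VLS use and steady partner. The conditional
distributions are

* gaussian node j:  x_j | rest ~ N(τ_j + Σ_k w_jk x_k, σ_j²),
* binary node j:   P(x_j = 1 | rest) = logistic(τ_j + Σ_k w_jk x_k),

with a symmetric, zero-diagonal interaction matrix W. With unit
conditional SDs the gaussian-block precision is Θ = I − W, so
gaussian–gaussian weights equal the partial correlations of the implied
joint normal — this is what makes closed-form oracles possible for every
downstream estimate.

## Synthetic cohort generator

`sample_panel` emulates an open prospective cohort:

* **Attendance.** Each of the 632 participants draws a visit count from
  the cohort's distribution (54, 130, 189, 259)/632 for 1–4 visits
  (1917 expected rows) and attends that many waves chosen uniformly
  without replacement — attendance is non-monotone, not drop-out shaped.
* **Within-person correlation.** Per-participant, per-node random
  intercepts ~ N(0, 0.5²) are added to every threshold (logit scale for
  binary nodes), giving positive ICC across waves.
* **Sampling.** One draw per participant-wave by Gibbs sampling with a
  fixed scan order and 200 burn-in sweeps (all participants advance in
  lockstep; rows are independent chains). Belief values are clipped to
  their 1–7 range afterwards; the clipping is a mild distortion of the
  MRF (point masses at the bounds) accepted for realism.
* **CAS and condom use.** Drawn per wave from logistic models on PrEP
  and VLS: cas ~ logistic(−0.5 + PrEP + VLS) (≈ 45–50% prevalence, so the
  sensitivity stage has a usable subset) and condom ~
  logistic(0.6 − 0.8·PrEP − 0.5·VLS) (≈ 60%, declining as PrEP rises).

### Default study conditions and calibration

`make_default_study_networks` builds four generating networks: belief
chains (weight 0.22) within the PrEP- and VLS-belief blocks, a
self-efficacy pair, social-norm links, and behaviour–belief edges.
Temporal structure: wave 1 carries extra PrEP–affordability,
PrEP–efficacy and efficacy–affordability edges that vanish from wave 2
onward (the planted structure change), and the PrEP–VLS coupling jumps
at wave 4. Two calibrations tie the generator to the study's reported
conditions rather than to round numbers:

1. **Cross-family couplings.** Behaviour–belief weights are raw
   conditional log-odds per scale unit (0.35–0.6). They are chosen so
   that the *estimated* standardized mixed-model edge weights land in
   the 0.2–0.4 range of the reported direct correlates: a raw
   cross-family weight w yields an estimated weight near
   √(w·sd_belief · w·sd_binary) ≈ 0.4·w at these prevalences, and raw
   weights of 0.3 would sit below the EBIC detection threshold at
   n ≈ 500, leaving the behaviour nodes spuriously isolated.
2. **Binary thresholds.** Solving logistic(τ + w'μ) = p_target ignores
   the variance of the linear predictor and inflates low-prevalence
   nodes. Thresholds therefore use the logit-normal moment
   approximation E[logistic(η)] ≈ logistic(m/√(1 + πs²/8)) with s² the
   predictor variance contributed by gaussian/binary neighbours and the
   random intercept. Realized PrEP uptake tracks the target trajectory
   10→22→25→31% at roughly 14→27→29→35%; the residual gap is the
   remaining mean-field error and is accepted.

Gaussian thresholds solve τ = (I − W)μ exactly given the neighbour
means (beliefs centred near 4, risk perception near 1.9, age a
standardized gaussian node — the scaling of age before estimation is not
otherwise constrained, so the generator standardizes it).

## Network estimation

**Mixed graphical model.** One L1-penalized regression per node (linear
for gaussian, logistic for binary responses) on all other nodes, all
predictors standardized — including binary ones, a convention that puts
cross-family weights on a comparable scale. Per node, λ is selected on a
50-point log-spaced grid from λ_max down to 0.01·λ_max by
EBIC_γ = −2·loglik + k·log n + 2γk·log(p−1), γ = 0.25. An edge is kept
under the AND rule (both directions nonzero; OR available), with weight
sign·√(b_ij·b_ji). The geometric-mean combination was chosen over the
arithmetic mean because for gaussian pairs it equals the partial
correlation exactly (b_ij = −θ_ij/θ_ii, b_ji = −θ_ij/θ_jj), which keeps
gaussian–gaussian weights in [−1, 1] and makes the unregularized limit
reproduce sample partial correlations to solver precision. Edges whose
two directions disagree in sign are dropped and recorded
(`sign_conflicts`): downstream strength and comparison statistics need
signed reals.

**EBIC graphical lasso.** The sample correlation matrix enters the
graphical lasso (diagonal unpenalized) over a 100-point log-spaced path
from λ_max = max|S_offdiag|; selection by
EBIC = −n(log det Θ − tr(SΘ)) + E log n + 4γE log p with γ = 0.5 and E
the nonzero off-diagonal precision count. The path stops early once
EBIC has moved past its minimum for 10 consecutive lambdas (it is
quasi-convex along the path in practice). Edges are partial
correlations −θ_ij/√(θ_ii θ_jj). Note that a single global penalty
admits tiny spurious entries (|ρ| ≲ 0.02) at large n — shrinkage-bias
relief on true edges outpaces the EBIC cost of incidental ones — so
support recovery is assessed by magnitude, not by exact sparsity.

**Inner solvers.** Both estimators reduce to thousands of small L1
problems inside permutation/bootstrap loops, so the inner loops are
numba-compiled Gram-based solvers (`prevnet._solvers`): a warm-started
cyclic coordinate-descent lasso path, and the blockwise (Friedman)
graphical lasso whose column updates reuse the same lasso kernel, warm
started across the lambda path. Solutions are cross-checked in the test
suite against `sklearn.linear_model.lasso_path` (agreement ~1e-6) and
`sklearn.covariance.graphical_lasso` (agreement to solver tolerance; at
lambdas where sklearn's dual gap oscillates our solution attains a lower
objective). Logistic nodewise fits use sklearn's liblinear with a large
`intercept_scaling` so the intercept is effectively unpenalized, and the
same EBIC early-stopping rule (patience 8).

## Bootstrap accuracy and stability

Edge intervals are percentile 2.5/97.5 quantiles over B participant
resamples with replacement (B ≥ 100 enforced; percentile rather than
normal-approximation intervals because the sampling distributions of
penalized edge weights are asymmetric, with mass at zero). Resamples
reuse a shared lambda grid spanning the full sample's per-node path
bounds for speed (full reselection via flag). Resamples with a constant
column are skipped and counted; >5% skips raises a warning. Two edges
are "distinct" iff the bootstrap interval of their difference excludes
zero. Case-dropping stability subsamples without replacement at drop
fractions 0.1–0.7 (smallest retained subset ≥ 50 rows), correlates
subset strength with full-sample strength (Pearson), and reports the CS
coefficient: the largest fraction whose correlation is ≥ 0.7 in ≥ 95%
of subsamples. Note the correlation is only informative when true
strengths are heterogeneous; on near-regular graphs it is noise.

## Consensus communities

Walktrap (walk length 4) runs on absolute edge weights — random-walk
transition probabilities require non-negative weights; sign structure is
reported separately. Because walktrap is deterministic on a fixed graph,
"iterated 1000 times with 90% co-membership" is interpreted as bootstrap
resampling: per iteration the participants are resampled, the network
re-estimated, walktrap run, and pairwise co-membership accumulated;
consensus clusters are connected components of the pairs above the 0.9
threshold, unattached nodes becoming singletons. An iteration whose
network is empty counts as an all-singleton partition.

## Network comparison test

Groups are compared on their EBIC-glasso networks over continuous nodes
only (binary nodes are excluded from comparison statistics). Three
statistics: |Δ global strength|, max|Δ edge| (structure), and per-edge
|Δ| with Holm correction across all node pairs (uncorrected p also
emitted). The null re-splits the pooled rows into the original group
sizes and re-estimates both networks per permutation; p-values use the
+1 convention (1 + #{perm ≥ obs})/(perm + 1), hence lie in (0, 1].
Implementation details that matter:

* the lambda grid is computed once from the pooled correlation matrix,
  so all permutations are scored against the same path;
* pooled rows are sorted canonically before permuting and the smaller
  group size is always drawn first, making every statistic and p-value
  exactly invariant to swapping the group labels;
* waves share participants, but the permutation scheme treats groups as
  independent — the scheme this test supports. The overlap is detected
  and warned about; a paired scheme is out of scope.

The pairwise schedule runs exactly (T1,T4), (T1,T2), (T2,T3), (T3,T4).
The hybrid report annotates Holm-significant NCT edges with the weight
difference from the mixed networks, flags edges absent from both mixed
networks, and keeps sub-display-cut (0.15) rows in machine output only.

## GEE trends

Wave index 1–4 enters as a numeric covariate (equal spacing, even though
the calendar gap between the first two waves is a year — the effect is
"per subsequent time point"); clusters are participants; the working
correlation defaults to exchangeable with independence as a cross-check
(identical point estimates to pooled regression); inference is robust
Wald. Binary outcomes report exp(coefficient) with an exp-transformed
95% interval. The multivariable sensitivity model regresses PrEP (or
VLS) on wave plus all other roster nodes and flags |coefficient| > 10 as
possible separation. Fewer than two clusters with repeated observations
is a warning, not an error: GEE then reduces to ordinary regression.

## Scale construction and tables

Cronbach's α = k/(k−1)(1 − Σ item variances / variance of row sums) with
(n−1) variances; Pearson r for two items. Composites above 0.7 replace
their items with the row mean; failing composites keep the raw items and
are flagged (an extension for robustness — the gate is expected to pass
on well-behaved data). Uptake percentages are displayed
half-away-from-zero rounded but stored unrounded. A participant absent
from a wave contributes nothing to that wave's N. The condom-use
denominator is all participants in the wave (the alternative —
restricting to those with casual partners — is noted as a possible
source of small display discrepancies).

## Problem sizes used by the shipped runs

The acceptance script simulates the full 632-participant, 35-node study
and uses: B = 200 bootstrap resamples (wave 4), 50 stability subsamples
per drop fraction (wave 1), 200 community iterations (wave 4), 500 NCT
permutations on an 11-node continuous sub-roster containing the planted
change, and 500 permutations for the CAS sensitivity test; it completes
in about two minutes. The statistical acceptance tests use 250
replicates × 200 permutations for NCT calibration, 100 outer replicates
at B = 300 for bootstrap coverage, 50 seeds for parameter recovery and
200 replicates for GEE recovery. These sizes are the package's choices
for a desk-scale reference run; all thresholds (coverage bands,
calibration bands, recovery tolerances) are independent of them.

## What passing tests do and do not show

The generator reproduces the features the analysis is sensitive to —
mixed node families, within-person correlation, non-monotone attendance,
wave-specific structure — but not questionnaire response styles, item
wording effects, ordinal discreteness of Likert responses (beliefs are
truncated gaussians here), measurement error beyond the MRF, or
selection bias in attendance (attendance is independent of node values).
Recovery and calibration results on this synthetic cohort therefore
validate the estimators and tests, not the substantive conclusions one
would draw from any real cohort. Other known limitations: the NCT
ignores participant overlap between waves (documented above); binary
nodes with more than two levels and moderation effects are out of
scope; betweenness/closeness centralities are deliberately not computed
(strength only); and printed real-data edge weights are matched only in
regime, since the estimation hyperparameters (γ, rule, lambda grid) of
the original analysis are unknown.
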
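# prevnet

Temporal attitude-network analysis of biomedical HIV-prevention uptake.

`prevnet` implements, end-to-end and on fully synthetic data, the analysis
pipeline of a longitudinal questionnaire study among HIV-negative men who
have sex with men (MSM): how uptake of two biomedical prevention strategies
— pre-exposure prophylaxis (PrEP) and viral load sorting (VLS) — relates to
a network of beliefs, social norms and demographics across four 6-monthly
waves, and how that network changes over time. It is aimed at researchers
who analyse attitude/behaviour panels with psychometric network methods and
want a tested, reproducible reference implementation with known ground
truth.

## What it computes

For each wave the variables (2 binary behaviours, steady partner, age, HIV
risk perception and 30 belief items on 1–7 scales) are modelled as a
pairwise Markov random field. The pipeline provides:

* **Synthetic cohorts** (`prevnet.synthetic`) — Gibbs-sampled multi-wave
  panels from known per-wave mixed MRFs, with non-monotone attendance
  drawn from the cohort's printed visit-count distribution, participant
  random intercepts for within-person correlation, and a planted
  structure change between waves 1 and 2.
* **Scale construction** (`prevnet.scales`) — multi-item measures are
  combined into row means when internal consistency exceeds 0.7
  (Pearson r for two items, Cronbach's α for more); per-wave uptake and
  belief descriptive tables.
* **Trend models** (`prevnet.trends`) — logistic/linear GEE with
  exchangeable working correlation and robust (sandwich) inference; the
  reported effect is the odds ratio (or slope) per subsequent wave.
* **Network estimation** (`prevnet.estimation`) — a mixed graphical model
  via nodewise L1-penalized regressions with per-node EBIC (γ = 0.25)
  lambda selection and AND-rule symmetrization, where the edge weight is
  the signed geometric mean of the two nodewise coefficients (exactly the
  partial correlation for gaussian pairs); and an EBIC-regularized
  graphical lasso (γ = 0.5) over the continuous nodes returning partial
  correlations. Both are scikit-learn-style estimators
  (`MixedGraphicalModel`, `EBICGraphLasso`).
* **Accuracy & stability** (`prevnet.accuracy`) — participant-bootstrap
  percentile intervals per edge, edge-difference tests, and case-dropping
  stability of strength centrality with the CS coefficient.
* **Descriptives** (`prevnet.descriptives`) — strength (Σ|w| per node),
  global strength, average shortest path length over 1/|w| distances, and
  bootstrap-iterated walktrap consensus communities (co-membership > 90%).
* **Network comparison** (`prevnet.comparison`) — the permutation network
  comparison test (NCT) of global-strength invariance, structure
  invariance (max edge difference) and Holm-corrected edge-wise
  differences on the continuous-variable networks, with the hybrid report
  that annotates significant edges with mixed-network magnitudes.
* **Pipeline & CLI** (`prevnet.pipeline`, `prevnet` command) — the whole
  study in order behind a YAML config, with per-stage seeds, a manifest,
  and the condomless-anal-sex (CAS) sensitivity analysis.

## Worked example

```python
from prevnet import (make_default_roster, make_default_study_networks,
                     sample_panel, estimate_mgm, fit_gee_trend)
from prevnet.descriptives import strength, global_strength

roster = make_default_roster()                  # 35 nodes, 3 binary
networks = make_default_study_networks(roster)  # 4 waves, change at T1->T2
panel = sample_panel(networks, n_participants=632, seed=1)

r = fit_gee_trend(panel, "PrEP", family="binomial")
print(f"PrEP trend OR {r.effect:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})")

net4 = estimate_mgm(panel.wave_data(4), roster)
cent = strength(net4).set_index("node")["strength"]
print(f"T4 global strength {global_strength(net4):.2f}, "
      f"PrEP strength {cent['PrEP']:.2f} (rank {int(cent.rank(ascending=False)['PrEP'])})")
```

prints (seed 1):

```
PrEP trend OR 1.43 (1.31-1.56)
T4 global strength 8.27, PrEP strength 1.56 (rank 1)
```

PrEP uptake in this synthetic cohort rises from ~14% to ~33% across the
four waves (OR ≈ 1.4 per wave), and by the final wave the PrEP node has
the highest strength centrality in the network — the same qualitative
story the pipeline is designed to detect: uptake grows, and the behaviour
becomes increasingly embedded in the belief network.

The same run from the shell:

```bash
prevnet run-all --seed 1 --out study_output
```

writes the panel, descriptive tables, trend CSVs, per-wave edge lists and
GraphML networks, bootstrap and stability summaries, community JSONs, the
NCT schedule and the CAS sensitivity bundle, plus `manifest.json` with
per-stage seeds and timings.

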
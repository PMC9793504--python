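# caretraj

Sequence analysis of longitudinal healthcare-utilization trajectories in
ageing cohorts.

Epidemiologists studying how older adults use health services over many
years face a pattern-recognition problem: each person contributes several
parallel categorical time series (physician visits, emergency care,
hospitalizations, home care, nursing-home stays), punctuated by missed
questionnaires, incapacity and death. `caretraj` implements the full
analysis chain used to derive a *typology* of such trajectories:

1. **Multichannel optimal matching (OM).** The dissimilarity between two
   individuals is the minimum total cost of transforming one state sequence
   into the other by substitutions and insertions/deletions (indels),
   computed in a single dynamic programme over vector states:

   ```
   D[i,j] = min( D[i-1,j-1] + S(x_i, y_j),  D[i-1,j] + Γ,  D[i,j-1] + Γ )
   S(x, y) = Σ_c w_c · s_c(x[c], y[c]),     Γ = Σ_c w_c · γ_c
   ```

   Substitution costs are ordinal per channel, `s_c(a,b) = 2|pos(a) −
   pos(b)| / K_c`, and the indel is half the maximum substitution
   (`γ_c = 1`), weighing timing and sequencing equally.  Missingness is
   modelled explicitly: death sits one ordinal unit beyond the highest
   utilization level (the furthest state from "no use"), incapacity is
   cost-equivalent to the highest level, and random nonresponse is
   equidistant (at `γ_c`) from every other state.

2. **Clustering on the dissimilarity matrix.** Agglomerative clustering
   with complete linkage (Ward and PAM available for comparison), scored by
   the average silhouette width `s(i) = (b_i − a_i)/max(a_i, b_i)`.  The
   cluster count is the largest k in range for which every cluster keeps at
   least ~1% of the sample (25 of 2271).

3. **Cluster characterization.** Chi-squared tests (ANOVA for age) screen
   baseline covariates; significant ones enter a multinomial logistic
   regression against the largest cluster, pruned by backward stepwise
   selection under `AIC = −2ℓ + 2p`.  Odds ratios `exp(β)` carry Wald 95%
   CIs, and quasi-separated cells (a category empty in some cluster) are
   flagged non-estimable instead of reported as divergent numbers.

Because the underlying panel data are not publicly deposited, the package
ships a **seeded synthetic-cohort generator** whose six latent archetypes
reproduce the published typology — constant low utilization (83.3%),
increasing utilization (4.9%), late health deterioration (4.4%), ambulatory
care to nursing home (1.5%), early fatal event (3.8%) and high ambulatory
care (2.1%) — together with the study's attrition (2271 of 3053 retained
under the ≥6-observations rule) and its 5.9% nonresponse share.  Every
stage of the pipeline is tested end to end against this generator.

## Worked example

```python
import pandas as pd
import caretraj as ct

cohort, latent = ct.generate_cohort(ct.default_config(), seed=1)
kept, retained, _ = ct.filter_min_observations(cohort)       # >= 6 known waves
dm   = ct.pairwise_distance_matrix(kept, ct.build_cost_model(kept.specs))
tree = ct.agglomerate(dm, "complete")
sol  = ct.select_solution(tree, dm)                          # k by the size rule
print(sol.k, sol.sizes)
```

prints

```
6 [1885  102   99   93   44   37]
```

i.e. the automatic selection lands on six clusters.  Matching each cluster
to its majority latent archetype (`ct.match_clusters_to_archetypes`) gives

```
cluster 1: LHU    83.41%  (n=1885)
cluster 2: IHU     4.51%  (n=102)
cluster 3: EFE     4.38%  (n=99)
cluster 4: LHD     4.12%  (n=93)
cluster 5: HAC     1.95%  (n=44)
cluster 6: AC2NH   1.64%  (n=37)
```

— the published prevalences recovered to within about a percentage point
by a fully unsupervised pipeline.  The scripts under `examples/` walk
through each capability (simulation, cost model and OM distances,
clustering and model selection, characterization, plotting); a `caretraj`
command-line tool (`simulate | distmat | cluster | characterize | plot |
run`) wraps the same functions for shell use.

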
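# Methods

## Data model

A cohort is a set of individuals observed over T = 11 annual waves on five
health-service channels: ambulatory care (4 ordinal levels: none / low /
medium / high), emergency care (none / one / multiple), hospitalization
(none / one / multiple), professional home care (none / temporary /
regular) and nursing home (none / temporary / permanent).  Position 0 of
every channel alphabet means "no utilization"; the published figures never
state the questionnaire's count-to-category cutoffs, so the level labels
are configurable and carry no numeric meaning inside the pipeline — only
their ordinal positions matter.

Three overlay states apply to all channels of a person-wave at once:
random nonresponse (NR), incapacitated (too unwell to participate) and
dead.  Death is absorbing.  The study-inclusion rule retains individuals
with at least `min_obs = 6` *known* waves, where a wave is known if it
carries a channel level, incapacity or death — a confirmed death is an
observation about the person, a nonresponse is not.  This definition is a
deliberate choice: an early-death trajectory class can only exist in the
analysis sample if death waves count as observed.

## Dissimilarity

Per channel, substitution costs are ordinal, `s_c(a, b) = 2·|pos(a) −
pos(b)| / K_c`, normalising the maximum substitution to 2 on every channel
so that the half-max indel rule gives `γ_c = 1` everywhere.  Under equal
normalised indels, weighting channels "proportionally to their indel"
reduces to equal weights, which is what the default uses (`w_c = 1`,
configurable).  The overlay states are embedded in the same ordinal
geometry:

* DEAD at extended position `K_c` — one unit beyond the highest level, the
  minimal encoding of "furthest from no utilization" that keeps the matrix
  a metric;
* INCAPACITATED at position `K_c − 1`, i.e. cost-equivalent to the highest
  utilization level;
* NR at exactly `γ_c` from every other state — "equidistant" pins only the
  common value, and `γ_c` (half the maximum) is the unique equidistant
  value that preserves the triangle inequality against the DEAD↔none pair.

The multichannel distance runs one dynamic programme on vector states with
pooled substitution `S = Σ_c w_c s_c` and pooled indel `Γ = Σ_c w_c γ_c`
(local interdependence).  Because edit scripts compose, the OM distance
inherits the metric property from the substitution matrix; the test suite
verifies the triangle inequality exhaustively on 300 individuals.  The DP
supports unequal lengths even though all sequences here have length 11.

The pairwise driver encodes each distinct multichannel state once (a few
hundred distinct states in practice), precomputes the pooled substitution
table, and runs a numba-compiled loop over unordered pairs: the full
2271×2271 matrix takes a few seconds on one CPU.

## Clustering and model selection

Agglomerative clustering with complete linkage is the primary procedure
(scipy's Lance–Williams implementation); Ward on the non-Euclidean OM
matrix is available but heuristic, and PAM (build + swap k-medoids,
implemented in-package since no installed library offers it on a
precomputed dissimilarity) serves as the partitioning alternative.
Partitions are renumbered by decreasing size, so cluster 1 is always the
largest and serves as the reference downstream.

Average silhouette width uses the standard `(b − a)/max(a, b)` with
singleton clusters scored 0 (the common convention).  Cluster-count
selection operationalises the published "all clusters contain at least ~1%
of the participants (≥ 25)" rule as: compute the ASW for every k in 2..10
(logged for inspection), return the **largest** k whose partition keeps all
sizes ≥ ⌈0.011·n⌉.  Because hierarchical partitions are nested, the
minimum cluster size is non-increasing in k, which makes this rule
well-defined; if no k qualifies the code falls back to k = 2 with a
warning, and the user can always fix k explicitly.

## Characterization

Bivariate screening uses Pearson chi-squared tests without continuity
correction (the cluster dimension has six categories; the correction only
exists for 2×2 tables) and one-way ANOVA for age.  Covariates with p <
0.05 enter a multinomial logistic regression with the largest cluster as
the reference outcome, fitted by Newton iterations (gradient tolerance
1e-8, 200 iterations, statsmodels MNLogit) with an L-BFGS fallback when
the Hessian is singular.  Dummy coding uses the first declared category as
reference.  Backward stepwise selection removes whole covariates (all
dummies at once), dropping at each step the covariate whose removal yields
the lowest AIC, and stops when no removal improves the criterion — which
guarantees the final AIC never exceeds the initial one.

Quasi-complete separation is detected structurally before fitting: a dummy
category with no member in some cluster (or a covariate whose *reference*
category has no member in a cluster, which makes every contrast against it
diverge — the "no individuals with 0 chronic illnesses" situation) is
flagged, and the affected odds ratios are reported as non-estimable rather
than as the diverged numbers the optimizer happens to stop at.  When the
fallback fit cannot provide a covariance, standard errors come from the
pseudo-inverse of the observed information; SEs of flagged cells are
meaningless and never reported as estimates.

Missing covariate values follow the share rule: above 0.5% missing
(evaluated per covariate), a covariate gains an explicit "missing"
category; below it, the affected individuals are excluded from the model
sample.

## Synthetic cohort generator

The generator exists because the original panel microdata are available
only on request; it emulates the *structure* of the published sample well
enough that every pipeline stage is exercised under realistic conditions.

Six latent archetypes are drawn multinomially with the published cluster
prevalences (83.3 / 4.9 / 4.4 / 1.5 / 3.8 / 2.1%).  Each archetype
simulates the five channels as independent Markov chains with phase-wise
transition kernels (phases: waves 1–4, 5–8, 9–11) whose shapes follow the
published descriptions: LHU stays in the low bands with no path to the top
states; IHU escalates home care to "regular" and ambulatory care to the
top bands during phases 2–3; LHD stays low until wave 8 and then
deteriorates (utilization spike, incapacity, death hazards 0.60/0.65/0.50
in waves 9–11); AC2NH starts with high ambulatory care, hospitalizations
and home care and converges to permanent nursing-home residence; EFE dies
in waves 2–6 (hazards rising to 1 at wave 6, concentrating deaths early);
HAC holds the top ambulatory and emergency levels throughout with low home
care.  All kernel values live in `defaults.yaml`, not in code.

Attrition is two separate processes.  Permanent dropout is modelled as
enrolment-only participation — with probability 0.2562 an individual
answers only the wave-1 questionnaire and contributes nothing afterwards
(the large first-wave attrition spike typical of postal panels).  This
makes retention archetype-independent: an attriter falls below the
six-observation floor regardless of any later death, so the retained
sample's archetype mix is an unbiased draw of the prevalences.  Transient
nonresponse affects continuing participants: the number of missed
questionnaires per person is binomial, capped at 2 (chronic non-response
*is* the dropout process), placed uniformly over responsive waves 2–11.
The dropout probability and the nonresponse rate (0.0719 per eligible
wave) were calibrated once by a one-dimensional search at n = 60 000
against the two study-level figures — 74.4% retention (2271/3053) and a
5.9% nonresponse share among retained person-wave cells — and then frozen
in `defaults.yaml`.

Baseline covariates (sex, living alone, chronic illnesses, self-perceived
health, grip strength, IADL difficulties, age) are drawn conditionally
independently given the archetype, with category probabilities taken from
the published cluster-by-covariate tables, including each covariate's
missing shares; age is a uniform integer on 65–70 shifted to the
cluster-specific mean.

What the generator does **not** emulate, and hence what passing tests do
not show about real data:

* nonresponse in real panels is bursty and trailing, not scattered — one
  visible consequence is that the exact all-"none" nursing-home *sequence*
  here holds ~42% of the sample rather than >60%, even though >60% (in
  fact ~95%) of retained individuals never use a nursing home once
  nonresponse waves are ignored;
* channels evolve independently within archetype, whereas real
  hospitalizations, home care and nursing-home entry are correlated within
  person-wave;
* covariates are conditionally independent given the archetype — no
  joint covariate structure beyond the cluster conditioning;
* utilization levels are ordinal bands with no count-level semantics;
* the between-archetype separation is cleaner than real cohorts, where
  boundaries blur — recovery metrics (ARI ≈ 0.97–1.0) are an upper bound
  on what identical code would achieve on field data.

## Numerical choices and degenerate inputs

* OM DP is O(|a|·|b|) with two rolling rows; empty sequences cost
  `Γ·length` of the other.
* Tie-breaking in agglomeration follows scipy's deterministic merge order;
  PAM breaks exact cost ties with an infinitesimal seeded jitter, making
  it deterministic given (matrix, seed).
* A distance matrix must be symmetric, nonnegative, zero-diagonal — this
  is validated at construction, not assumed.
* Silhouette requires ≥ 2 clusters; singletons score 0.
* Problem sizes in the test suite: the brute-force OM oracle runs ~10⁴
  random pairs of length ≤ 4 over a 4-state alphabet; the metric check
  uses 300 individuals; clustering recovery uses an 800-individual
  subsample; the typology recovery and calibration checks run the full
  n_raw = 3053 cohort.

## Known limitations

* Only OM is implemented; alternative sequence dissimilarities (Hamming,
  LCS, OMspell) are out of scope.
* Ward linkage on an OM matrix lacks the Euclidean embedding its variance
  interpretation assumes; treat it as a comparison heuristic.
* The stepwise search is greedy backward elimination, not best-subset; the
  selected covariate set can depend on the entry set.
* No survey weighting, multiple imputation, or bootstrap cluster-stability
  analysis.
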
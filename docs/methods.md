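# Methods

This note documents the statistical models, defaults, and design
choices behind `dietnet`, and what the synthetic-data experiments do
and do not demonstrate.

## Synthetic cohort generator

The generator (`dietnet.cohort`) emulates the *structure* of a
health-screening cohort table, not any particular population's joint
distribution. Its pieces:

* **Food intakes.** The 16 food-group intakes are `exp` of a
  multivariate normal on the log scale. The generator's precision
  matrix is the planted GGM ground truth; this makes the downstream
  log-transform step exactly Gaussian, guarantees positive intakes, and
  gives analytic partial correlations ρᵢⱼ = −ωᵢⱼ/√(ωᵢᵢωⱼⱼ). The default
  truth plants five strong edges (partial correlations 0.30–0.60, the
  magnitudes screening cohorts report for their strongest food pairs)
  plus a weak ring backbone (0.12) so the network is connected, as
  observed food networks are. Log-scale medians follow typical
  East-Asian FFQ intake levels (e.g. ~560 g/day cereals, ~305 g/day
  vegetables) with marginal log-SD ≈ 0.5.
* **Demographics.** The ten categorical variables are sampled from a
  pairwise categorical Markov random field by Gibbs sampling — n
  parallel chains, 500 burn-in sweeps plus 10 thinning sweeps, a fixed
  and documented mixing budget. Planted pairwise potentials encode the
  dependencies large screening cohorts show (sex–smoking strongest,
  age–employment, marital–income, sex–employment, education–income);
  all other pairs are conditionally independent, which is the
  categorical ground-truth edge set.
* **Comorbidity markers.** Blood pressure, total cholesterol, fasting
  glucose, and GFR categories are drawn from multinomial logits on
  age/sex/lifestyle with moderate coefficients (0.2–2.2 on the
  log-odds scale, age effects dominating, matching the ordering of
  reported adjusted odds ratios). Raw clinical measures are then
  back-filled uniformly inside the drawn category's numeric window
  (with treatment/self-report flags qualifying half of the
  hypertension/diabetes rows), so the classification rules can be
  exercised and must reproduce the planted categories exactly.
* **Energy and missingness.** Energy is a fixed positive linear
  combination of intakes (coarse kcal/g densities, oils 9.0 down to
  vegetables 0.3) plus N(0, 120²) noise, centering the cohort near
  1,900 kcal/day with a small tail outside the 500–4,000 plausibility
  window so the filter has work to do. Missing cells are
  missing-completely-at-random per cell (default 1%), with sentinel
  `NA` on disk; all downstream analyses are complete-case.

What this does **not** emulate: item-level FFQ structure, nutrient
composition, realistic marginal shapes beyond log-normality,
informative missingness, or any dependence of intakes on demographics.
A passing recovery test therefore shows the estimators work under the
model class they assume — not that real cohort networks are recovered.

## GGM estimation

Intakes are transformed log(x+1) (the +1 g pseudo-count keeps zero
intakes finite and is unit-stable) and standardized per column, making
the λ grid scale-free; partial correlations are invariant to this.
The graphical lasso is solved over 50 log-spaced λ values from λ_max
(the smallest λ that empties the graph, i.e. the largest absolute
off-diagonal sample covariance) down to 0.01·λ_max. Model selection
minimizes EBIC(λ) = −2ℓ(Ω̂) + E·log n + 4γE·log p with E the number of
nonzero off-diagonal pairs and γ = 0.5. Off-diagonal partial
correlations with |ρ| ≤ 1e-6 are treated as numerical zeros. Tiny
negative duality gaps reported by the solver at the dense end of the
path are ignored as numerical noise; non-finite estimates raise.

## Dietary score

Eigenvector centrality needs a nonnegative matrix, so weights are the
leading eigenvector of |ρ| with zeroed diagonal — negative partial
correlations enter by magnitude. The vector is normalized to unit
Euclidean length; any fixed normalization only rescales scores, and
tertile membership is invariant. On a disconnected network the Perron
vector concentrates on the principal component and nodes outside it
receive weight 0 (documented behavior, not an error). Scores use raw
g/day intakes, not logs. Tertile cutpoints are linear-interpolation
empirical quantiles at 33.33%/66.67%; values tied with a cutpoint fall
into the lower group. Fewer than three distinct scores is a degenerate
input and raises.

## Mixed graphical model

Each node is regressed on all others: continuous nodes by lasso
(response standardized), categorical nodes by ℓ1-penalized multinomial
logistic regression on an over-complete 0/1 indicator coding (one
column per level, levels treated symmetrically; indicators are left
unstandardized so coefficients share a meaningful scale after the
continuous columns are standardized). Per node the λ path has 30
log-spaced values from that node's λ_max (KKT entry point) to
0.01·λ_max, and EBIC selects the fit with df = nonzero coefficients
and a 2γ·df·log P model-space term. At λ_max itself the solution is
the analytic intercept-only model; it is used directly rather than
solved numerically, since the coordinate-wise solver oscillates on the
KKT boundary there.

Edges aggregate every coefficient linking two nodes from both
nodewise fits; under the AND rule both directions must contribute at
least one nonzero coefficient. The edge weight is the mean absolute
value of all collected cross-coefficients — a scale-stable summary
after standardization. Signs are defined only for
continuous–continuous pairs with agreeing directions; pairs involving
a categorical node have no canonical sign and are recorded as 0.
Only pairwise (k = 2) interactions are modeled. The multinomial solver
uses a fixed internal shuffling seed so identical inputs give
byte-identical networks.

## Centrality

Association weights convert to lengths d = 1/w. Closeness is
1/Σd(i,j) over reachable nodes; on a disconnected graph the sum runs
over the reachable set only, isolated nodes get 0, and a warning marks
the result as hard to interpret (closeness loses meaning when a node —
e.g. an independent BMI group — is cut off). Betweenness uses the
standard fractional tie-splitting convention (each unordered pair
counted once, tied shortest paths sharing equally); this is the single
emitted variant. Brute-force simple-path enumeration on graphs of up
to 6 nodes serves as the test oracle for all three indices.

## Stability

The accuracy bootstrap literally resamples 80% of the sample *with*
replacement per replicate (`resample_frac` exposes the standard
full-n bootstrap as well). Edge CIs are 2.5%/97.5% replicate
quantiles, widened where necessary to contain the replicate mean: for
edges selected in only a handful of replicates the distribution is a
point mass at zero plus outliers, and the raw 97.5% quantile can fall
below the mean. Difference tests flag pairs whose bootstrap difference
interval excludes zero and are deliberately unadjusted for
multiplicity (noted in the report). Case-dropping stability subsamples
*without* replacement at each drop fraction; the CS coefficient is the
largest fraction at which the subsample/full-sample centrality
correlation is ≥ 0.7 in ≥ 95% of subsamples, found by scanning the
whole grid rather than assuming monotonicity. Subsamples with a
degenerate (constant) statistic are excluded from the tally with a
warning; a network with no reproducible structure therefore yields
CS = 0.

## Association analysis

Marker rules follow clinical guideline cutoffs with two gaps closed
explicitly: blood-pressure precedence is hypertension (DBP ≥ 90 or
SBP ≥ 140 or treatment/self-report) > elevated (80 ≤ DBP < 90 or
120 ≤ SBP < 140) > normal, and cholesterol intervals are half-open
([4.66, 5.19), [5.19, 6.22)) so every value maps to exactly one
category. Glucose is analyzed as two groups (normal versus combined
prediabetes + diabetes). Treatment/self-report flags dominate numeric
thresholds. The energy filter retains the boundary values 500 and
4000 kcal (exclusion is strict).

Odds ratios come from one multinomial logistic model per marker with
all predictors entered jointly (mutual adjustment), reference-coded
indicators, Wald 95% CIs exp(β̂ ± 1.96·SE), and Wald p-values. Rank
deficiency is reported naming the collinear columns before fitting;
Newton is retried with BFGS on thin outcome categories, and persistent
non-convergence (possible separation) raises naming the suspect
predictors.

## Pipeline

One run seed fans out to named per-stage substreams
(SeedSequence([seed, crc32(stage)])), so stages are independently
reproducible and a rerun with the same configuration is
byte-identical, as the manifest's artifact hashes verify. Exclusions
happen once, before modeling.

## Problem sizes used in validation

Recovery experiments use n = 2000 with 20 replicates (16-node GGM with
5 planted edges; 12-node mixed network with 8 planted edges), the λ→0
oracle check uses n = 4000 at p = 4, stability checks use a 5-node
chain at n = 1200 (50 subsamples per drop fraction) and pure noise at
n = 600, and the centrality oracle enumerates all simple paths on 50
random graphs of ≤ 6 nodes. These sizes keep each experiment's Monte
Carlo error comfortably inside the asserted margins.

## Known limitations

* The synthetic demographics are sampled from the same model family
  the MGM assumes; recovery results do not speak to model
  misspecification.
* Continuous–categorical edge signs are not defined; analyses that
  need signed mixed edges must inspect the nodewise coefficient blocks.
* The bootstrap difference tests are unadjusted; with many edges some
  flags are expected by chance.
* Closeness on disconnected graphs depends on the reachable-set
  convention; compare values only between graphs with the same
  component structure.
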
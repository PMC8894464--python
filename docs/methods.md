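# Methods

`ccmnet` reconstructs directed causal networks among phytoplankton species
richness (BD), community biomass (EF, chlorophyll-a proxy), nitrate,
phosphate and water temperature from monthly monitoring series, quantifies
feedback-loop weights, and relates module strengths to environmental
gradients across sites. This note documents the model assumptions, the
tunable parameters, the synthetic benchmark systems, and the numerical and
design choices that were genuinely open.

## 1. Preprocessing

Raw samples are averaged into calendar-month bins; months between the first
and last sample with no observations stay missing — they are never
interpolated, because interpolation fabricates dynamics that state-space
methods would read as signal. Each monthly series is then stationarized:

1. remove the long-term linear trend (OLS residuals against the month
   index),
2. deseasonalize: `D(t) = (O(t) − μ_month) / σ_month` with the sample (n−1)
   standard deviation,
3. rescale to zero mean and unit sample variance.

In the composed `preprocess` step the trend and the twelve monthly means
are estimated **jointly** (one least-squares fit on an intercept-free
month-indicator basis plus centered time), after which residuals are scaled
by their month's standard deviation and z-scored. Estimating the two
sequentially leaves a leakage term — a 12-periodic signal is not exactly
orthogonal to time on a finite record, so the trend fit steals a small slope
(~1e-4 per month at 40 years, amplitude 1) whose within-month variation
survives deseasonalization. Joint estimation makes the output exactly
invariant (machine precision) to adding any affine function of time plus any
fixed 12-periodic signal, which is the operational definition of the two
steps. The standalone `detrend_linear` operation remains plain OLS on time.

Degenerate cases: a calendar month with zero variance maps to anomaly 0
(vanishing-variance limit, logged); a represented month with fewer than two
observations, or a constant series, is a validation error.

## 2. Cross-mapping engine

The effect series X is unfolded into delay vectors
(x(t), x(t−τ), …, x(t−(E−1)τ)) with τ = 1 month throughout. Vectors
touching a missing month are dropped. To estimate the cause Y at lag k, the
vector at time t estimates Y(t−k): its E+1 nearest library neighbours by
Euclidean distance are combined with simplex weights
w_i = exp(−d_i/d_min), normalized; skill ρ is the Pearson correlation of the
estimates against observations over all usable points. Exact zero-distance
neighbour sets split weight equally (continuous limit); distance ties break
toward the earliest time index; a prediction point never uses itself
(configurable Theiler exclusion window, default 0 excludes only the
identical time point).

Convergence is measured on a skill curve ρ(L): library sizes on an evenly
spaced integer grid from L0 = E to Lmax = the number of usable embedded
vectors, with `n_subsamples` random library subsets per size (drawn without
replacement) and the full library once at Lmax. The curve's replicate
skills, grid, and effective sample size are retained for audit.

## 3. Per-link protocol

For each ordered pair (cause Y, effect X):

1. **Embedding dimension.** E ∈ [2, 20] scored by the univariate simplex
   one-step self-forecast of X; the selected E is the smallest whose skill
   lies within half a standard error of the maximum. The parsimony band
   matters for series whose skill-vs-E profile is flat (linear-stochastic or
   very noisy data): a plain argmax then lands on an arbitrary large E where
   delay windows add variance without signal, while sharply peaked profiles
   (chaotic dynamics) are unaffected. An alternative criterion — maximizing
   the full-library hindcast cross-map of X(t) onto Y(t−1) — is available as
   `e_selection="hindcast"`. It is not the default because the hindcast
   statistic is (up to the lag scan) the same statistic whose convergence is
   subsequently tested; maximizing it over 19 candidate dimensions transfers
   a winner's curse of roughly +0.1 into ρ(Lmax) and triples the
   false-positive rate on decoupled benchmark pairs (measured: ~33% vs ~10%
   at fixed E; see §6). Self-prediction selects E from the effect series
   alone and contributes no such bias, which realizes the stated purpose of
   a hindcast-style selection — avoiding overfit when the two series are
   unrelated.
2. **Lag.** k ∈ {0, 1, 2, 3} months maximizing full-library skill of
   X(t+k) cross-mapping Y(t); ties → smallest k. For a one-step-forced
   system the selected lag concentrates at the embedding window's edge
   (k ≈ E−1).
3. **Convergence.** Two criteria, both required at α = 0.05: a one-sided
   Kendall τ test for an increasing trend in the (L, mean ρ(L)) pairs, and
   Fisher's Δρ Z test comparing ρ(Lmax) against ρ(L0) after the atanh
   transform, Z = Δz / sqrt(2/(n_eff − 3)). The effective sample size is
   the Pyper–Peterman autocorrelation-adjusted count of prediction points,
   1/n_eff = (1 + 2·Σ_k r_A(k)·r_B(k))/n, taking the more conservative of
   two estimates — one from the cross-map estimates against the
   observations, one from the reconstructed state coordinate against the
   observations (the estimates are a smoother of the target series, so
   their measured autocorrelation alone understates the dependence).
   Serially correlated series carry fewer independent observations than
   their raw count; the unadjusted test flags independent AR(1) pairs at up
   to ~45% (measured), while n_eff restores near-nominal rates. For
   serially independent series n_eff equals the raw count.
4. **Strength.** LS = max(ρ(Lmax), 0). Negative skill carries no causal
   information, and loop weights need non-negative members; the raw ρ is
   retained. Significance = both convergence criteria pass (the
   conservative conjunction) and the pair is not a self-link.
5. **Uncertainty.** Bootstrap SE: the library of embedded points is
   resampled with replacement (size preserved, prediction set fixed),
   ρ(Lmax) recomputed per replicate, SE = sd over 500 replicates.

## 4. Networks, standardization, loops

All 20 ordered pairs among the five variables are quantified per site.
Because cross-map skill has site-specific ceilings (length, noise), linkage
strengths are standardized within each site: SLS = LS / max(LS), maximum
over all 20 links, significant or not — so SLS ∈ [0, 1] and every site has
one link at 1. Loop weight is the geometric mean of member SLS (after
Neutel): pairwise loops sqrt(SLS_AB·SLS_BA), triangles the cube root of the
three members. The four triangles are Type I (BD→EF→nutrient→BD) and
Type II (EF→BD→nutrient→EF), each with NO3 (-N) or PO4 (-P). A loop is
significant when every member link is. Temperature is exogenous — it forces
the biota but is not fed back on — so links into it are quantified only as
false-positive diagnostics and never enter loops or recovery scores.

## 5. Cross-system layer

One row per site: response blocks are the four module families (links into
EF, links into BD, pairwise loop weights, triangular loop weights);
predictors are depth, area and long-term means of richness, temperature,
PO4, NO3 and biomass, log10-transformed where they span orders of magnitude
(depth, area, nutrients, biomass) and standardized. RDA = PCA of the fitted
values of the multivariate regression of centered responses on standardized
predictors; explained variance is the fitted-to-total sum-of-squares ratio
(equal to OLS R² for a single response). Significance by permuting predictor
rows (default 10,000 permutations, +1-corrected p). Paired site-wise
comparisons use sign-flip permutation tests on mean differences; group
comparisons use Kruskal–Wallis; correlations are Pearson with permutation
p-values; stepwise regression is bidirectional AIC on standardized
predictors with the overall F on (k, n−k−1) degrees of freedom. These
analyses describe where modules prevail; they are not causal claims.

## 6. Synthetic benchmark systems

The study's raw monitoring data are not publicly archived, so the package
ships generators whose causal structure is known by construction.

**Coupled logistic pair.** x(t+1) = x(t)(r_x − r_x x − β_xy y(t)) and
symmetrically for y; the benchmark default is unidirectional forcing
β_yx = 0.1 (X forces Y), r = (3.8, 3.5), process noise sd 0.005, clipped to
(1e-6, 1−1e-6). The small process noise matters: in the noise-free map the
driver's trajectory deterministically imprints on the responder
(generalized synchrony), giving the *reverse* direction genuine cross-map
skill of ~0.12 and a near-100% false-detection rate; 0.005 noise breaks the
synchrony while leaving forward detection at 100%. Larger noise
(≥0.02) re-inflates reverse skill because driver noise is itself causal
signal transmitted to the responder.

**Mock lake ecosystem.** Monthly-step skeleton on normalized (0,1) scales:
temperature = 0.5 + 0.25·sin(2πm/12) + AR(1) anomaly (φ = 0.6, sd 0.12),
exogenous; richness and biomass are chaotic logistic maps (r = 3.7, 3.6)
coupled to each other, to the nutrients and to the temperature deviation;
nutrients follow n(t+1) = n + λ(1−n) − n·(uptake) with constant loading
(λ = 0.30, 0.25) and depletion by biomass (and, for nitrate, by richness
and temperature). The ground-truth network is the nonzero off-diagonal
coupling pattern: 12 edges, including the Type I cycle
richness→biomass→no3→richness by construction. Process noise 0.02.

**Observation layer.** Adds per-variable linear trends (a few 1e-4 per
month), a small measurement-level seasonal component, i.i.d. Gaussian noise
(0.02), and masks exactly round(f·n) months at random (default f = 0.03) —
precisely the artefacts preprocessing removes.

What the generator does **not** emulate: irregular within-month sampling,
measurement error heteroscedasticity, regime shifts, species-level
composition, and real nutrient stoichiometry. Passing recovery tests shows
the pipeline detects interactions embedded in nonlinear dynamics under
monitoring-like degradation; it does not validate CCM's assumptions on any
particular real system. Two caveats are inherent to the method and visible
in the benchmarks: indirect chains (both nutrients share biomass as a
driver) can be flagged as direct links, and strong unidirectional forcing
without noise produces synchrony that defeats directionality.

## 7. Problem sizes and defaults

| parameter | default | note |
|---|---|---|
| τ (embedding lag) | 1 month | the series' native scale |
| E range | 2–20 | searched per ordered pair |
| k grid | 0–3 months | phytoplankton response scale |
| n_L (library grid) | 20 | acceptance/benchmark runs use 12 |
| n_subsamples | 100 | acceptance/benchmark runs use 25 |
| α | 0.05 | both convergence criteria |
| n_boot | 500 | bootstrap SE replicates |
| n_perm | 10,000 | all permutation tests |
| Theiler window | 0 | raise for strongly autocorrelated data |
| min overlap | 30 months | per-link precondition |

Benchmark and recovery experiments in the test-suite and acceptance script
run at n = 400–480 months with 30 seeds, n_L = 12 and 25 subsamples — curve
resolution beyond that changes the convergence decisions negligibly while
the runtime scales linearly in n_L × n_subsamples.

## 8. Known limitations

- CCM cannot attribute signs to interactions; loop weights are magnitudes.
- Cross-map skill conflates direct and indirect influence; precision against
  a sparse ground truth is bounded by transitive detections.
- The Fisher and Kendall criteria test convergence, not effect size; with
  very long series arbitrarily weak couplings become "significant".
- Analyses run at the consensus monthly scale only; sub-monthly causality is
  invisible by construction.
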
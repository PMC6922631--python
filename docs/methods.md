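# Methods

`topoprofile` estimates how the spatial pattern of neurodegeneration relates
to the topology of the structural connectome. It does so in two stages: a
longitudinal progression model turns short-term volumetric follow-up into
per-region rates of pathology accrual on a common latent timeline, and a
constrained linear decomposition expresses those rates as a sparse
non-negative combination of graph-topology descriptors — the *topological
profile* of a cohort or an individual.

## Data model and preprocessing

Inputs are (a) a long-format table of regional gray-matter volumes with
subject id, age at visit, group label and nuisance covariates, (b) one or
more weighted structural adjacency matrices over a lateralized atlas
(82 regions by default), and (c) region metadata (hemisphere, left/right
pairing, barycenter coordinates in mm).

Preprocessing follows standard volumetric practice:

1. **Nuisance adjustment.** Each region's volume is regressed on total
   intracranial volume, sex and age (age optional, e.g. for an ageing cohort
   where it is the effect of interest). Coefficients are estimated on the
   control subset by default and residuals applied to everyone, so the
   disease effect itself is not regressed away; fitting on all subjects is
   available as an option.
2. **Bilateral averaging.** After dropping unwanted regions, each left/right
   pair is replaced by the mean of its members (82 → 41 regions by default).
3. **Z-scoring against controls**, oriented so that *larger z means more
   atrophy*: z = (control mean − x)/control sd. This makes "the region with
   the highest z" literally the most atrophied region and makes disease
   trajectories increase over time. Re-applying the z-score operation to an
   already-oriented cohort re-standardizes without flipping sign again, so
   standardization is idempotent on its own control subset.

Visits with missing covariates are dropped with a logged warning.

## Network metrics and the design matrix

Nine per-region vulnerability templates are computed on the cohort-average
connectome (element-wise mean of subject matrices, symmetrized, zero
diagonal, globally max-scaled to [0, 1] — global rather than per-row scaling
preserves relative connection strengths):

| descriptor | metrics | mechanism proxied |
|---|---|---|
| centrality | betweenness, closeness, weighted degree, clustering | nodal stress at hubs |
| segregation | inverse degree, inverse clustering | trophic failure of isolated regions |
| network proximity | weighted shortest-path distance to epicenter | trans-neuronal spread |
| cortical proximity | Euclidean distance to epicenter | diffusive spread |
| constant progression | column of ones | uniform loss |

Numerical conventions:

- Path-based metrics (betweenness, closeness, shortest paths) run on travel
  lengths 1/weight over positive-weight edges, the standard conversion for
  streamline-weighted networks; zero weight means no edge. Closeness is
  (n−1)/Σd; betweenness is unnormalized (the min-max step absorbs scale).
- Clustering is the weighted geometric-mean (Onnela) form.
- Inverse metrics are guarded: an isolated node (or zero clustering) takes
  the column maximum of the inverse metric after computation, with a
  warning; if a graph has no triangles at all the inverse-clustering column
  degenerates to zeros.
- All metrics are computed on the full lateralized graph first and averaged
  across hemisphere pairs afterwards, so asymmetric connectivity information
  enters the metric values before symmetrization.
- The **epicenter** is operational: per subject, the bilateral region with
  the highest z at the last follow-up; the cohort epicenter is the modal
  subject epicenter (ties break to the lowest region index, with a
  warning). On the lateralized graph the epicenter is the pair of member
  nodes; distances to it are multi-source minima.
- Distance-type columns are inverted as v = 1 − minmax(d): the mechanisms
  they proxy make regions *closer* to the epicenter *more* vulnerable, so
  vulnerability must decrease with distance. A raw-distance mode exists for
  sensitivity analyses. Nodes unreachable from the epicenter get proximity
  0 (maximal distance), with a warning.
- Every non-constant column is min-max scaled to span [0, 1] exactly; a
  constant column of ones is appended. Rank deficiency of the resulting
  matrix is flagged.

The metrics within a descriptor are deliberately correlated (they probe one
mechanism); consequences for identifiability are discussed below.

## Progression model

Each subject j observes region v at ages t through a per-subject time shift
d_j mapping to a latent disease time τ = t − d_j:

    z_vjk = f_v(t_jk − d_j) + b_jv + ε,   ε ~ N(0, σ_v²)

with a population trajectory f_v (fixed effect), per-subject scalar offsets
b_jv with shared variance (random effect), and region-specific observation
noise. Identifiability of the latent timeline comes from monotonicity: in
atrophy orientation, trajectories never decrease.

The fixed effect is a Gaussian-process regression in weight space whose
derivative is a non-negative combination of M radial-basis bumps:

    f_v'(τ) = Σ_m w_vm φ_m(τ),  w_vm ≥ 0,
    f_v(τ)  = c_v + Σ_m w_vm Φ_m(τ)

where Φ_m is the analytic antiderivative of the Gaussian bump (a scaled
normal CDF), so monotonicity holds by construction and the derivative is
available in closed form rather than by finite differences.

**Fitting** alternates, trajectories first:

1. per region, bound-constrained ridge least squares for (c_v, w_v) via
   `scipy.optimize.lsq_linear` (ridge λ = 1e-4 on the weights only);
2. per subject, a 1-D grid search plus parabolic refinement for d_j over
   [−2l, 2l], where l is the kernel length-scale. Each candidate shift is
   scored jointly with its own optimal shrunken offsets — scoring against
   offsets frozen at the previous shift lets the random intercepts absorb
   the shift signal and anchors subjects at their old positions.

Shifts are anchored to mean zero each iteration (the soft ±2l bound alone
leaves a translation degeneracy). Iteration stops when the penalized
residual sum of squares changes by less than 1e-4 relative, with a cap of
40 outer iterations; the objective typically plateaus for ~20 iterations
while shifts disentangle, then drops sharply — hence the generous cap. A
non-converged fit returns the best iterate with `converged=False`.

**Tunable parameters** (defaults): kernel length-scale l = span of centered
ages / 4 (years); M = 25 basis bumps spanning the observed shifted-age range
with width 2.0 × spacing; τ grid of 200 points over [min − 2l, max + 2l];
S = 100 posterior derivative draws. Basis bumps are restricted to the
observed data span: bumps far outside it have near-constant antiderivatives
over the data, are collinear with the intercept, and produce spurious
edge slopes. The basis width trades smoothing bias in the maximal rate
(wider = more bias) against noise-driven wiggles that trap the shift search
(narrower = worse shift recovery); 2.0 × spacing keeps the logistic
closed-form check within 0.01–0.03 of truth while shift recovery stays
above 0.99 rank correlation at realistic noise.

**Uncertainty** is a Laplace approximation at the optimum: per region, a
Gaussian over the active weights (and intercept) with covariance
σ_v²(AᵀA + λI)⁻¹, sampled S times with negative weight draws clipped at
zero; all downstream uncertainty (rate credible intervals, profile credible
intervals) propagates these draws.

**Rates.** The cohort rate is Y_v = max over the grid of f_v'(τ) — finite
because the trajectories are smooth and the shifts bounded — with
uncertainty from the per-draw maxima. Individual rates evaluate f_v' at the
subject's anchored mean age τ̃_j = mean(visit ages) − d_j, clipped at zero;
anchors outside the grid evaluate at the nearest end with a warning.

## Topological profile

With Y min-max scaled to [0, 1] (a degenerate constant positive Y maps to
ones — pure level information is exactly what the constant descriptor
encodes) and Σ the design matrix, the profile solves

    β = argmin_{β ≥ 0} ||Y − Σβ||²

by ISRA multiplicative updates β ← β ⊙ (ΣᵀY) ⊘ (ΣᵀΣβ) from a uniform
positive start (1/9), which under Gaussian noise is the EM solution of the
non-negativity-constrained likelihood. The residual sum of squares is
non-increasing at every step and is asserted so. Convergence is declared
when the relative change of all *numerically live* coordinates falls below
1e-8 (cap 50 000 iterations): coordinates converging to the zero boundary
decay geometrically, so their relative change per iteration is constant and
would otherwise keep the criterion from ever firing; coordinates below
1e-13 are treated as zero. On random full-rank designs the solution agrees
with active-set NNLS to better than 1e-4 (L∞); on the strongly collinear
columns of a real design the crawl along the near-degenerate ridge is
slower, and agreement to 1e-4 needs roughly 200k–500k iterations — at the
default cap the residual weight discrepancy (~3e-3) is far below the 0.01
reporting precision of the weights.

Derived quantities:

- **Sparsification**: weights strictly below 0.10 are zeroed (all nine
  entries, including the constant). Entries exactly at 0.10 survive.
- **Descriptor sums**: sums of surviving weights per descriptor; the
  percentage view renormalizes survivors to 100% and rounds to the nearest
  5%. (Renormalize-then-round is a lossy convention: a descriptor at 21.7%
  of the surviving weight reports as 20%.)
- **Variance explained**: R² = 1 − RSS/TSS with TSS about the mean of Y.
  Under this centered definition a constant-only fit explains exactly
  nothing (its best prediction is the mean); an uncentered option
  (TSS = ΣY²) is exposed, under which the constant model is credited with
  the mean level. Single-descriptor R² refits ISRA on that descriptor's
  columns alone, without the constant.
- **AIC** = 2N + V ln(RSS/V). N counts 5 for the full profile (one weight
  per descriptor, plus epicenter choice, minus normalization), 1 for a
  single plain metric, 2 for an epicenter-based metric (shortest path,
  spatial distance). An exact fit returns −∞ with a flag.
- **Credible intervals**: ISRA refitted on each of the S posterior rate
  draws; the spread (sd) is the credible half-width.
- **Bootstrap**: subjects resampled with replacement, progression and
  profile refitted per replicate (B = 100 by default); failed replicates
  are dropped and counted.
- **Permutation test**: the null permutes the region order of Y relative to
  Σ — preserving the marginal rate distribution while destroying the
  alignment with topology — and refits; p = (1 + #{β_perm ≥ β_obs})/(1+B),
  Bonferroni-corrected across the 8 non-constant metrics; a zero observed
  weight has p = 1 by construction. Null refits use a looser tolerance
  (1e-5, cap 5 000 iterations); they only feed exceedance counts, which are
  insensitive at that precision.
- **Late-stage profile**: the same machinery applied to the per-region mean
  of patients' last-visit z-scores instead of rates — the end-stage-only
  baseline the longitudinal approach improves upon.

## Cohort space

Profiles live in the 5-D space of descriptor sums (sparsified sums by
default; raw sums are an option). Individuals are assigned to the nearest
cohort profile by Euclidean distance; ties resolve to the subject's own
cohort when tied, else the lowest cohort index, with a warning. An
individual nearer another cohort's profile is an *outlier*. Confusion
matrices report row percentages (true cohort × assigned cohort). With three
cohorts, barycentric coordinates use normalized inverse distances
((1/d_i)/Σ(1/d_k)); a zero distance maps to the corner, two zero distances
are an error. Distances to the own-cohort profile can be correlated
(Pearson) with clinical features.

## Synthetic data generator

The generator composes the same forward model the estimator inverts, so
every stage is testable without any restricted data:

- **Connectome**: V/2 barycenters uniform in one hemisphere box, mirrored;
  edge probability `density` (0.3), weights = exp(−d/40 mm) modulated by
  hemisphere-symmetric log-normal heterogeneity (σ = 2 before the two
  symmetrizing averages). The heterogeneity emulates the broad
  streamline-count spread of tractography networks; without it, every
  metric is a monotone function of spatial position and the design columns
  collapse into near-duplicates (network distance vs spatial distance
  correlate at 0.97 instead of the ~0.8 typical with heterogeneity).
  Disconnected draws are retried up to 10 times.
- **Cohort**: rates Y* = Σ β_true. By default β_true is rescaled so the
  noiseless rate field spans [0, 1] exactly (the excess shift lands on the
  constant weight, clipped at zero); the min-max step of the estimator is
  then the identity and the recorded `beta_true` is itself the estimation
  target. The NNLS solution of the noiseless scaled problem is also stored
  as `beta_identifiable` — under min-max normalization it is the exactly
  identifiable parameter when the clip was active. Each region follows a
  logistic with maximal slope equal to its rate (max slope Ak/4 in closed
  form, which makes the rate extraction analytically checkable); subjects
  get shifts ~ N(0, 2² years), entry points uniform over ±5 years of
  disease time, 4 annual visits, per-subject-region offsets of sd 0.05 and
  observation noise of sd 0.05 z-units — a short-interval volumetric cohort
  of the size and noise level typical for single-site imaging studies; the
  default cohort size is 50 subjects.
- **Volume wrapping** re-expresses a z-score cohort as raw volumes with a
  TIV effect and a flat control group, optionally expanded to lateralized
  columns, to exercise the preprocessing chain end to end.

What the generator does *not* emulate: measurement-noise heterogeneity
across regions, subject-specific connectomes, epicenter heterogeneity
within a cohort, non-logistic (e.g. biphasic) trajectories, and informative
dropout. Passing tests therefore demonstrate correctness of the estimation
machinery under the stated generative assumptions, not robustness to the
full range of real-data pathologies.

## Validation experiments and problem sizes

The validation battery (`topoprofile.experiments`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) uses problem sizes
chosen to give stable Monte-Carlo estimates in minutes on one CPU:

- reference-profile worked examples (sparsify → group → percentages);
- ISRA vs NNLS on 200 random 41×9 instances (max L∞ gap, expected < 1e-4);
- weight recovery from cohort rates: 50 replicate cohorts of 50 subjects,
  rate noise 0.05 per subject, canonical two-mechanism truth (0.4
  betweenness + 0.6 network proximity before normalization); the cohort
  rate vector is the subject mean. Reported as mean L∞ error vs the
  generating weights. Per-subject noise is the stated study condition; the
  error on the averaged rates is then dominated by design conditioning,
  not noise. (With 0.05 noise applied directly to the 41 cohort rates, no
  estimator can resolve individual weights of collinear columns to 0.05 —
  the NNLS oracle's error equals ISRA's in that regime.)
- end-to-end recovery through the progression fit (one 50-subject cohort);
- the logistic closed form (unit logistic → maximal rate 0.25) and
  latent-shift recovery (Spearman vs truth at noise 0.1, 50 subjects);
- model selection: fraction of 100 two-mechanism replicates where the full
  profile has lower AIC than the best single metric;
- classification: three cohorts of 40 individuals with distinct benchmark
  profiles; the package's confusion matrix against a brute-force
  nearest-centroid oracle on the same coordinates (individual profile fits
  use tolerance 1e-7 — coordinates are stable at that precision and the
  oracle comparison is unaffected).

## Known limitations

- Per-subject time *shifts* only; no time rescaling (progression speed) —
  fast and slow progressors at the same stage are not distinguished.
- Random effects are scalar per subject-region intercepts, not smooth
  subject-level deviations; only f′ and the shifts feed the profile, so
  richer random effects would mainly sharpen uncertainty.
- The Laplace posterior on clipped non-negative weights underestimates
  uncertainty near the zero boundary.
- Within-descriptor metric collinearity caps per-metric identifiability on
  real designs; descriptor sums are considerably more stable than
  individual weights, and bootstrap/credible intervals should be read
  per-metric with that in mind.
- Euclidean inter-barycenter distance stands in for along-surface cortical
  distance; a user-supplied distance matrix is accepted wherever the
  spatial matrix is used.
- The CLI covers simulate / preprocess / fit-progression / fit-profile /
  individuals; stage reports are written as CSV/JSON artifacts by the fit
  commands rather than by a separate report command.
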
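# Methods

## Model

Data are an n × p matrix; rows (observations, e.g. genes) are clustered,
columns (variables, e.g. samples) carry a known clustering into q groups
encoded as a binary row-stochastic p × q loadings matrix Λ (or one Λ_g
per component). Each mixture component g ∈ {1..G} is a factor-analysis
model x = μ_g + Λ_g u + ε with u ~ N(0, I_q) and ε ~ N(0, Ψ_g), Ψ_g
diagonal, so the marginal component covariance is Σ_g = Λ_g Λ_g′ + Ψ_g.
Because each row of Λ_g has a single 1, Λ_g Λ_g′ is a 0/1 block matrix
and Σ_g is block diagonal: within a variable cluster every pair of
variables shares unit covariance from the common factor; across clusters
covariance is exactly zero. The biclusters are the G × q cells formed by
crossing the estimated observation clusters with the supplied variable
clusters — non-overlapping and exhaustive in both directions.

Eight family members arise from three binary constraints — Λ_g = Λ,
Ψ_g = Ψ, and Ψ_g = ψ_g I — named by a three-letter C/U code in that
order (CUU = shared Λ, per-component non-isotropic Ψ_g). Covariance
parameter counts are 1 (·CC), p (·CU), G (·UC) and Gp (·UU); Λ is
supervised input and contributes no free parameters. The total count
used by the information criteria is (G−1) + Gp + the covariance count.

## Estimation

A two-cycle AECM algorithm. Cycle 1 takes (x, z) as complete data:
the E-step computes responsibilities ẑ_ig ∝ π_g φ(x_i | μ_g, Σ_g)
(log-sum-exp, so extreme observations never produce NaN), and the
CM-step sets π_g = n_g/n, μ_g = Σ_i ẑ_ig x_i / n_g with n_g = Σ_i ẑ_ig.
Cycle 2 takes (x, z, u) as complete data: responsibilities are refreshed
under the new (π, μ), the factor moments are formed once —

    β_g = Λ_g′ Σ_g⁻¹,
    S_g = (1/n_g) Σ_i ẑ_ig (x_i − μ_g)(x_i − μ_g)′,
    Θ_g = I_q − β_g Λ_g + β_g S_g β_g′,

— and the CM-step maximizes the expected complete-data objective in Ψ.
The per-component diagonal residual is

    d_g = diag{ S_g − 2 Λ_g β_g S_g + Λ_g Θ_g Λ_g′ },

and the eight members reduce to four aggregations of d_g: keep it
(?UU), average its diagonal (?UC → ψ_g = tr{·}/p), weight across
components by n_g/n (?CU), or both (?CC). The non-?UU forms follow from
setting the same score function to zero under each constraint; the test
suite verifies each update increases the objective it maximizes and
that the fully constrained update equals the n_g-weighted average of
the per-component traces.

All densities, β_g and log-determinants go through the Woodbury
identity (Ψ + ΛΛ′)⁻¹ = Ψ⁻¹ − Ψ⁻¹Λ M⁻¹ Λ′Ψ⁻¹ and |Ψ + ΛΛ′| = |Ψ||M|
with M = I_q + Λ′Ψ⁻¹Λ, so only diagonal and q × q systems are solved —
O(npq) per component per iteration, and numerically safe when p ≫ n.

### Convergence

Aitken acceleration on the log-likelihood sequence: with
a(t) = (l(t+1) − l(t)) / (l(t) − l(t−1)), the asymptote estimate is
l∞ = l(t) + (l(t+1) − l(t)) / (1 − a(t)), and the run stops when
0 ≤ l∞ − l(t) < ε with ε = 0.1. A flat sequence counts as converged;
a(t) ≥ 1 or a vanishing denominator means "continue". Before three
log-likelihood values exist, a plain |Δl| < ε test is used. The
iteration cap is 1000; a capped run is returned flagged unconverged.

### Initialization and degeneracy

Each of the n_starts = 20 random starts draws a hard uniform-multinomial
partition of the observations into G groups, takes (π, μ) from it, and
initializes Ψ from the pooled per-variable sample variances (their mean,
for isotropic models). A start whose initial groups have fewer than
q + 1 members is redrawn (up to 5 times). During iterations, any
component whose effective size n_g drops below q + 1 aborts the start
(S_g would be unusable); a cell where all starts abort is reported as a
failed fit, not an exception. Every noise variance is floored at 1e−6
to prevent the unbounded-likelihood degeneracy of mixtures of factor
analyzers. The best converged log-likelihood across starts wins. All
randomness flows from one seed through NumPy `SeedSequence` spawning,
one substream per start, so every fit is reproducible bit for bit.

## Model selection

Maximization convention throughout: BIC = 2l − m log n,
AIC = 2l − 2m, ICL = BIC + 2 Σ_i log ẑ_{i,MAP(i)} (the hard MAP-indicator
entropy form, so ICL ≤ BIC with equality for hard assignments). Largest
value wins; ties break toward smaller G, then fewer parameters. For
per-component-Λ models the number of supplied Λ_g matrices pins G, so
the G range applies only to shared-Λ models.

## Synthetic data

The generator draws from the generative model itself, through the
factor representation (so true factor scores are retained). Study shape:
G ∈ {2,3,4} balanced components, n = 100·G, p = 8 variables in q = 2
balanced clusters. Four regimes set (mean separation d, noise scale s):

| regime             |  d  |  s  |
|--------------------|-----|-----|
| low_var_good_sep   | 6.0 | 0.5 |
| mid_var_good_sep   | 6.0 | 2.0 |
| high_var_good_sep  | 6.0 | 6.0 |
| high_var_close     | 2.5 | 6.0 |

Component means sit at d·g with a per-variable-cluster offset of up to
d/2, making all G·q bicluster means distinct. Noise variances are
s times a fixed per-variable profile in [0.6, 1.4] (diagonal models)
times a per-component profile in [0.75, 1.25] (unconstrained-Ψ models);
isotropic/shared constraints collapse the corresponding profile. For
per-component-Λ data the block boundaries are rotated by g positions so
the G partitions genuinely differ. Both d and s are overridable per
design.

These regimes are an *emulation* of the qualitative study conditions
(low/mid/high noise with good separation, high noise with close
clusters), not a replication of any specific parameter table: they
reproduce the perfect fixed-G recovery ceiling in the well-separated
regimes and substantial confusion in the close-cluster regime. The
generator produces exactly model-consistent, balanced Gaussian data; it
does not emulate microarray-realistic features (probe effects, batch
structure, heavy tails, unbalanced clusters), so passing tests
demonstrate correctness of the estimator under its own assumptions, not
robustness to real expression data. One consequence worth stating: with
data exactly from the model and the true Λ supplied, BIC selects the
true G in essentially every well-separated replicate at these sizes, so
the overfitting this class of algorithms shows on messier data appears
here only in the close-cluster regime — and when it does, the test
suite checks it takes the benign "refinement" form (estimated clusters
split true clusters rather than mixing them).

## Problem sizes

Replicate studies in the tests and the acceptance script use 20
datasets × 20 random starts per fit (the package's standard desk-scale
study; single fits on n = 200–400, p = 8 take well under a second).
The BIC-selection study spans G = 2..10 for the two shared-Λ models
CUU and CUC, the pair most relevant in applications and the default of
`osgabi fit`.

## Known limitations

- Λ must be supplied; nothing estimates it (by design).
- Missing values are rejected, not imputed.
- Per-observation z-score normalization is offered (`--normalize`);
  sample-wise scaling, if wanted, must be done upstream.
- The ICL here uses the hard MAP-indicator entropy convention; soft
  entropy variants would differ slightly for overlapping components.
- With very small components (n_g < q + 1) a start is abandoned rather
  than regularized; heavily overlapping data at large G can therefore
  report failed cells, which the criterion table records.
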
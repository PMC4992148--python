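# Methods

`befstress` implements an analysis pipeline for a classic question in
biodiversity–ecosystem-function (BEF) research: when an environmental
stressor (here, the herbicide atrazine acting on marine diatom
microcosms) changes the relationship between species richness and
community productivity, is that change driven by stress effects on the
*per-capita strength of species interactions* (as the stress gradient
hypothesis predicts), or simply by interspecific differences in *stress
tolerance* acting through unchanged interactions?  The pipeline
answers this with two complementary tools — an additive partition of
biodiversity effects, and a mechanistic community model fitted under
nested scenarios of interaction change — and is exercisable end to end
on synthetic data with known ground truth.

## Study design emulated

The design is a full factorial of community assemblage × stress level ×
replicate.  Eight diatom species are assembled into 39 communities over
richness levels {1, 2, 3, 4, 8} (8 monocultures, 10 random assemblages
at each intermediate level, the full community), exposed to three
atrazine concentrations (0, 25, 250 µg l⁻¹) in triplicate — 351
experimental units.  Species are inoculated at equal shares of a total
biovolume density of 10⁷ (biovolume units per litre) and observed at
days 7, 14, 21 and 28.

## Tripartite partition of biodiversity effects

For a mixture of n species with monoculture yields Mᵢ (same day and
stress level), observed mixture yields Yᵢ and expected relative yields
RY_E,ᵢ = 1/n (equal inoculation), define RY_O,ᵢ = Yᵢ/Mᵢ and
RYT_O = Σ RY_O,ᵢ.  The net biodiversity effect

    ΔY = Σᵢ Yᵢ − Σᵢ RY_E,ᵢ Mᵢ

splits additively into

    dominance                = n · cov(M, RY_O/RYT_O − RY_E)
    trait-dependent compl.   = n · cov(M, RY_O − RY_O/RYT_O)
    trait-independent compl. = n · mean(RY_O − RY_E) · mean(M)

with the **population** (divide-by-n) covariance.  This choice is what
makes the three components sum to ΔY exactly (machine precision; the
test suite checks 10⁻⁹ relative on 1,000 random instances): with the
sample covariance the identity fails by a factor n/(n−1) on the
covariance terms.  Monoculture and mixture yields are replicate means;
stress-induced changes are componentwise stressed-minus-control
differences at matched assemblage and day.  A monoculture that
collapsed below one biovolume unit is floored there and the community
flagged rather than dropped.

## Community model

Dynamics follow a generalized Lotka–Volterra model with
stress-dependent demographic rates,

    dNᵢ/dt = μᵢ(c) · Nᵢ · (1 − Σⱼ A_ij(c) · Nⱼ),

with A_ii(c) = 1/Kᵢ(c) and dimensionless relative coefficients
α_ij(c) = A_ij(c)·Kᵢ(c).  Stress dependence is a two-level lookup
(control and 250 µg l⁻¹; the 25 µg l⁻¹ treatment reuses control
parameters, the two being statistically indistinguishable in the
underlying experiment).  Weekly medium renewal is not modelled (cell
loss through renewal was negligible), nor is an explicit mortality
term: a completely inhibited species (μ = 0) holds its density.

Integration: the public `simulate` uses LSODA with rtol 10⁻⁸ /
atol 10⁻² and an extinction floor of 1 biovolume unit (inoculated
species are clipped there; absent species stay at zero).  The
estimation inner loop instead uses a numba fixed-step RK4 integrator
with dt = 0.1 d, whose global error (~10⁻⁴ relative for growth rates
up to ~1.5 d⁻¹) is far below observation noise; the two integrators
are cross-checked against each other and against the logistic closed
form in the test suite.

## Scenarios of stress effects on interactions

Five nested constraint sets on how interactions may differ between the
stress levels, each encoded as a bijection between a bounded free
vector and the full two-level parameter set:

| scenario | constraint | free parameters |
|---|---|---|
| S1 | no interspecific interactions (A_ij = 0) | 4n |
| S2 | inter = intraspecific strength (α_ij = 1) | 4n |
| S3 | inter/intra ratio stress-invariant (shared α_ij) | 4n + n(n−1) |
| S4 | absolute strength stress-invariant (shared A_ij) | 4n + n(n−1) |
| S5 | interactions free per level | 4n + 2n(n−1) |

The 4n block is μ and K per species per level, bounded within 10% of
the per-species monoculture estimates (obtained by least-squares
logistic fits on log densities, with the known inoculation density);
growth-rate upper bounds are relaxed to 0.15 d⁻¹ when the monoculture
estimate is below 0.1 d⁻¹.  Relative coefficients are bounded in
[0, 200]; for S4/S5 the bound is applied in A-space as
200 / max_c K̂ᵢ(c) (when K sits at its upper bound the realised α can
exceed 200 by ≤10%, accepted because the bound itself derives from
estimates).  The lower bound 0 excludes facilitation in all scenarios.
Under S3 the per-capita interaction A_ij(c) = α_ij/Kᵢ(c) strengthens
when stress lowers Kᵢ, by construction.  S4's feasible set is a subset
of S5's, so at matched budget the optimal S5 objective cannot exceed
S4's when S5 is warm-started from S4's optimum — a property the tests
exploit.

## Objective and estimation

Fit quality for one community is the time- and abundance-weighted mean
absolute percentage error,

    S = Σ_t w_t [Σᵢ p_it |N_it,o − N_it,e| / N_it,o] / Σ_t w_t,

with p_it the observed relative abundance (species span orders of
magnitude in biovolume, so errors must be scaled per species, and the
abundance weighting keeps the community total well predicted).  Day
weights down-weight the noisier early samples; the default is
w = {7: 0.5, 14: 0.5, 21: 1, 28: 1}, configurable, and no result here
depends on the particular positive non-decreasing choice.  The overall
objective is the unweighted mean of S over all fit units (mixtures and
monocultures at both fitted stress levels); parameters are shared
across communities, so the fit is joint.

Parameter sets whose trajectories blow up (any density above 10³ ×
the maximum observed total), extinguish more than one species, or
exceed 100% MAPE score `penalty_base + d(β, β₀)` with penalty_base = 10
and d the Euclidean distance from the restart's start in
bound-normalized coordinates — the optimizer is steered back when it
wanders into irrelevant regions.  An additional soft cut-off adds the
normalised excess to S whenever a species' mean interaction effect
(mean over days and recipients of α_ij·Nⱼ(t)) exceeds 1,000 × the mean
species abundance of the community, disfavouring implausibly strong
effects of rare species.

Estimation runs repeated generalized simulated annealing
(`scipy.optimize.dual_annealing`) in bound-normalized coordinates —
essential, since the free vector mixes ~1 d⁻¹ rates with ~10⁸
capacities.  Each restart begins from a random *feasible*
(non-penalized) start, obtained by rejection sampling with the
interaction block geometrically shrunk over attempts (uniform draws
over the full α bound are almost surely penalized).  A bounded
L-BFGS-B polish consumes the remainder of each restart's evaluation
budget: the objective is smooth away from the penalty region, where
annealing alone converges slowly.  Defaults are 100 restarts ×
2·10⁴ evaluations; the packaged experiments use 10 restarts × 1.5·10⁴.

Uncertainty is the 2.5/97.5 percentile envelope of the restart optima,
computed over *converged* restarts (objective within 1.5× of the best).
At reduced budgets a minority of restarts stall far from the optimum;
their scatter reflects optimizer failure, not parameter uncertainty,
and including them corrupts the envelope badly enough to invert
scenario comparisons.

## Monte-Carlo evaluation and scenario comparison

Per scenario, parameter vectors are sampled uniformly within the
percentile envelope (1,000 runs by default; 100 in the packaged
experiments), every mixed community is re-simulated for 28 days from
its inoculation densities at both fitted levels, and two metrics are
computed per run: (i) the negative Gaussian log-likelihood of the
observed day-28 proportional function loss, (control − stressed)/control
on total biovolume, with per-community σ propagated from replicate
spread (floor 0.01) — the exact likelihood form is configurable and
only orderings are relied on; (ii) the mean Bray–Curtis similarity,
1 − Σ|x−y|/Σ(x+y), between observed and predicted relative
compositions over mixed communities × days × levels.  Runs use a
common seed stream, so per-run metrics are paired across scenarios and
compared by Wilcoxon signed-rank tests with Bonferroni correction over
the scenario pairs.

## Regression stages

Three mixed-model stages (statsmodels MixedLM, random intercept per
assemblage): log₁₀ total biovolume on LDiv (log₁₀ richness) × stress
treatment × day; stress-induced changes in each partition component on
LDiv × day; and changes at days 21/28 on the abundance-weighted stress
tolerance Tol (monoculture yield ratio M₂₅₀/M₀) and interaction
strength Inter (scenario-4 A₀), plus Tol × Inter, optionally with
dInter (scenario-5 A₂₅₀ − A₀).  Full models are reduced by hierarchical
backward selection on likelihood-ratio tests (α = 0.05), never dropping
a main effect while a containing interaction is retained; residual
normality is reported (Shapiro), not enforced, and the random-intercept
model's log-likelihood gain over the fixed-only fit is reported.
MixedLM has no residual correlation structure, so the continuous AR(1)
option for the temporal dependence of effect changes is not available;
the models rely on the assemblage random intercept alone, and singular
random-effect fits fall back to OLS with a flag.

## Synthetic data generator

The generator defines the study conditions for all recovery tests.
Species traits are drawn once per seed: μᵢ(0) ~ U(0.4, 1.2) d⁻¹ and
Kᵢ(0) ~ U(10⁸, 5·10⁸) (typical diatom division rates and biovolume
yields), and a single tolerance multiplier per species ~ U(0.2, 1.0)
scales both μ and K at 250 µg l⁻¹ (a multiplier of 0 emulates complete
inhibition and can be set explicitly).  Off-diagonal α ~ U(0, 0.8):
this keeps communities in the suppression-without-collapse regime the
real microcosms showed (mortality under 1% of cells) — losers decline
over the four weeks without crashing through the extinction floor,
which matters because the estimation penalty classifies parameter sets
with more than one floor-hit as infeasible, and a generating truth in
that regime would be excluded by the very method under test.
Interactions across the two levels are tied per the generating
scenario, so refitting that scenario is a well-posed recovery problem.
Observations are latent trajectory values times independent mean-one
lognormal factors (σ² = ln(1+cv²), default cv = 0.05, emulating
counting error on densities spanning orders of magnitude).

What the generator does *not* emulate: demographic stochasticity,
nutrient dynamics and medium-renewal dilution, dead-cell/frustule
counts, and day-to-day environmental fluctuation.  Passing recovery
tests therefore show the estimation machinery is correct and
well-conditioned under the model's own assumptions plus realistic
counting noise — not that the gLV model is an adequate description of
any particular real community.

## Packaged experiment sizes

The recovery experiment fits scenario 4 to data from 8 species in 8
monocultures + 10 four-species mixtures chosen as five parallel classes
of a 1-factorization of the species pool, so that all 28 species pairs
co-occur in at least one mixture and every interaction coefficient is
identifiable; noise cv 0.05, 10 restarts × 15,000 evaluations; the
ordering experiment adds an S1 fit, an S5 warm-start fit and 100 paired
Monte-Carlo runs.  These sizes keep a full desk run to a few minutes on
one core while leaving each scientific question answerable; all scale
up by arguments.

## Known limitations

- Interaction coefficients of species pairs that never co-occur in any
  fitted mixture are unidentifiable; the packaged recovery design
  avoids this by construction, but arbitrary designs do not.
- The percentile envelope is a heuristic uncertainty summary (scatter
  of annealing optima), not a posterior; it narrows with optimizer
  budget.
- The Gaussian likelihood for function loss uses the day-28 loss only;
  pooling days is a configuration choice, not implemented as default.
- Backward selection with LRTs on MixedLM uses ML fits; exact
  denominator degrees of freedom (and hence p-values) will not match
  REML-based software.
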
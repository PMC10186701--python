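# Methods

## The experiment being modelled

The pipeline targets replicated nutrient-addition trials on young trees in
which the unit of randomization is the plot. The built-in design
(`wild_apple_design`) has 12 treatment levels sharing one unfertilized
control: N-only at 10/20/40 g m⁻² yr⁻¹, P-only at 2/4/8, a fixed-N20 series
with variable P (N20P2/N20P4/N20P8), and a variable-N series with fixed P4
(N10P4/N20P4/N40P4). N20P4 belongs to both combined series but exists once
(tagged N20Px); the contrast families and series scores include it in both
by explicit level lists. Five plots per level (60 plots), four saplings per
plot, and 1–3 current-year twigs per sapling, drawn uniformly.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes — a
single latent growth factor per plot, dose-driven, with hierarchical
multiplicative noise — not the physiology of any particular site.

**Latent growth.** For a plot at doses (n, p):

    G = G0 · (1 + f_N(n)) · (1 + f_P(p)) · (1 + γ · f_N(n) · f_P(p))

with f(d) = g_max·d/(K + d) − c·d² (saturating gain, quadratic high-dose
inhibition). Defaults: G0 = 1; N response g_max = 0.40, K = 2 g m⁻² yr⁻¹,
c = 5·10⁻⁵ (a strong, nearly saturated response across 10–40 with mild
inhibition at 40); P response g_max = 0.90, K = 40, c = 0 (a weak,
slowly-rising response, ≈ +4% at P2 to +15% at P8); interaction γ = −7
(antagonism: combined addition underperforms the N-only expectation). These
values were fixed from the closed-form expectations so that the four series
order N > NxP4 > N20Px > P in expected comprehensive growth score — the
qualitative field finding the pipeline is meant to recover — with a minimum
score margin of ≈ 0.09, and so that effects of individual traits carry the
reported signs (positive stem responses, declining ratio traits).

**Raw measurements.** Only the seven measured quantities are simulated; all
derived traits are computed downstream, so trait identities hold exactly.
Each measurement is scale · G_tree^β · ν_twig, where G_tree = G_level ·
ν_plot · ν_tree and every ν is a mean-one lognormal factor. Baseline scales
(at G = 1) and exponents β:

| measurement | scale | β | | measurement | scale | β |
|---|---|---|---|---|---|---|
| L (cm) | 15 | 0.8 | | TPM (g) | 0.15 | 1.0 |
| BD (cm) | 0.30 | 0.4 | | SM (g) | 1.00 | 1.2 |
| LN (count) | 8 | 0.5 | | TLA (cm²) | 80 | 0.85 |
| TBM (g) | 1.20 | 1.05 | | | | |

The exponents make every derived trait monotone in G with |effective
exponent| ≥ 0.2: stem mass grows fastest (β = 1.2), so leafing intensity
(LN/SM, β ≈ −0.7), leaf area ratio (TLA/TM, β ≈ −0.3), LAMR (β ≈ −0.35) and
SLA (TLA/TBM, β = −0.2) all decline with growth, the direction such
experiments report for allocation ratios. Leaf number is rounded to an
integer ≥ 1 after noise; the rounding bias at a mean count of ~8 is far
below a percent and is ignored by the closed-form expectation helper.

**Noise.** Default lognormal sigmas are 0.05 (plot), 0.05 (tree), 0.10
(twig measurement, drawn independently per measurement) — modest
within-site heterogeneity plus measurement-scale scatter. Real field data
are noisier and carry structure the generator omits entirely: between-year
variation, spatial gradients, sapling mortality, and trait-specific
(non-latent-factor) biology. Passing tests therefore demonstrate that the
*machinery* recovers what was put in under the stated conditions, not that
real twig data would behave this way. Tests that need clean signal
(hub-degree recovery, series-ranking recovery) use the explicitly low-noise
setting 0.02/0.02/0.05.

**Closed forms.** For a mean-one lognormal ν with sigma s, E[ν^β] =
exp(β(β−1)s²/2), so expected level means of raw measurements are available
exactly (`expected_measurements`) and serve as the simulation oracle. Note
convergence of empirical level means to these values requires replicating
plots, not just twigs — plot/tree noise does not average out within a fixed
plot — so the recovery test scales `plots_per_level` up.

## Trait derivation and aggregation

The 17-trait catalog (4 stem: L, BD, SM, TM; 10 leaf: LA, LN, TBM, TPM,
TLA, TLM, SPM, SBM, SLM, SLA; 3 ratio: LI, LAR, LAMR) is fixed. SLA is
computed as TLA/TBM — blade-only mass, the conventional leaf-economics
definition — since per-leaf vs total quantities cancel in the ratio.
Replication unit is the plot: traits are derived per twig (ratios included
— mean of ratios, not ratio of means), averaged per tree, then per plot, so
unbalanced twig counts do not weight saplings unequally. All downstream
stages consume the n = 5 plot means per level.

## Percent-effect contrasts

Effects are d = 100·(Ȳ_treated − Ȳ_reference)/Ȳ_reference over the six
families (four against CK; added-P judged against N20; added-N against P4),
each tagged low/medium/high by a fixed concentration-class map. The 95% CI
is a two-group bootstrap over plot means (B = 10 000 by default, per-
estimate seeds split deterministically from the run seed); significance is
CI excludes zero. No multiple-testing correction is applied (the report
records the number of tests, 306).

**Interval choice.** With n = 5 plots per group the plain percentile
bootstrap is badly anti-conservative for this ratio statistic: its measured
type-I error under the null is ≈ 11–12% at nominal 5%. The default is
therefore a studentized (bootstrap-t) interval using a delta-method
standard error of the ratio, se(d) ≈ 100·sqrt(v_t/m_r² + m_t²·v_r/m_r⁴),
whose measured type-I error is ≈ 4–5% and whose coverage of a true +50%
effect is ≈ 95%. `ci_method="percentile"` and `"expanded"` (percentile with
t-quantile-widened levels) remain available. Degenerate zero-variance
samples collapse the interval to the point estimate; bootstrap replicates
with a resampled reference mean of exactly zero are redrawn and counted
(impossible for strictly positive traits).

## Group statistics

One-way ANOVA is the explicit between/within decomposition (defined F = 0
when the between-group sum of squares is zero; scipy returns NaN there) and
is cross-checked against `scipy.stats.f_oneway`. Two-way ANOVA (type-II SS
via statsmodels OLS) requires a complete crossed grid; the 12-level design
is not fully crossed, so it runs on the two complete sub-grids
N∈{0,20}×P∈{0,2,4,8} and N∈{0,10,20,40}×P∈{0,4} — the only factorial
rectangles that admit interaction estimation. The K-S normality check tests
against a normal with estimated mean/sd; because estimation makes the
asymptotic p conservative, a Lilliefors-corrected variant is available by
flag. Duncan's multiple range test uses critical ranges R_p =
q(1−(1−α)^(p−1); p, df_error)·sqrt(MSE/n_h) (studentized-range quantiles
computed from the distribution, cached because the ppf is expensive; n_h =
harmonic mean group size), the standard step-down span procedure, and
letter displays from maximal homogeneous spans.

## Trait networks

Edges are trait pairs with two-sided Spearman p < α (default 0.05,
unadjusted — each network stands alone, mirroring common PTN practice);
isolated traits remain nodes; constant columns yield undefined correlations
and never edges. Topology is computed on the unweighted graph (|rho| is
stored on edges for reporting only), consistent with integer degree counts:
degree, local clustering, edge density m/136, connectedness = fraction of
reachable node pairs, average path length over reachable pairs only (NaN
with a `degenerate` flag when there are no edges), Freeman degree
centralization Σ(d_max − d_i)/((n−1)(n−2)), and modularity. Betweenness is
reported raw (sum of pair-wise geodesic fractions) and normalized by
(n−1)(n−2)/2; comparisons and tie-breaking use the raw value, since the
scale behind published decimal betweenness values is not standardized.

Community detection: exact exhaustive partition search for graphs of ≤ 8
nodes (instantaneous there, guaranteed optimal; available to 12 by
request), otherwise deterministic greedy agglomeration followed by a
deterministic local refinement (single-node moves and community merges in
sorted order while Q strictly improves) — plain greedy agglomeration can
sit ≈ 0.04 below the optimum even on 8-node graphs. Modularity of an
edgeless graph is reported as NaN. Key traits are all nodes attaining the
maximal (degree, raw betweenness) pair; ranking breaks ties
lexicographically. Per-series networks use the control plus the three
levels of that series.

## Membership scoring

U(x) = (x − x_min)/(x_max − x_min) per trait with min/max across the
treatment-level means (not raw twigs, so the score compares treatments, not
individuals); inverse orientation 1 − U for traits negatively associated
with growth. Which traits to invert is user-configurable; the default map
inverts traits whose pooled Spearman correlation with twig mass TM is
negative, and the chosen map is logged with the outputs. A trait constant
across levels contributes a neutral 0.5 rather than being dropped. The
comprehensive score is the unweighted mean of U over the 17 traits; a
series score is the mean over its member levels (CK belongs to none;
N20P4 to both combined series). Ranking ties within 10⁻⁹ are flagged.

## Numerical and reproducibility choices

All randomness flows from a single root seed: the generator uses
`numpy.random.default_rng(seed)`, and `effect_table` splits one child seed
per estimate via `SeedSequence`, so results are independent of estimate
order. Pipeline bundles embed the seed and a SHA-256 hash of the full
configuration; identical configurations reproduce byte-identical CSV/JSON
artifacts. Problem sizes used by the shipped checks — 60 plots for network
and membership analyses, ~10⁴ twigs for identity conservation, 2000
simulated two-group comparisons at B = 1000 for null calibration, 500
random ≤ 6-node graphs against exhaustive enumeration — keep every check
well inside interactive runtimes while leaving Monte-Carlo margins of ≥ 3
binomial standard errors.

## Known limitations

- The generator's single-latent-factor structure makes nearly all trait
  pairs correlate; it cannot produce the sparser, treatment-contingent
  networks of real data (where, e.g., different series yield visibly
  different key traits).
- The studentized bootstrap protects the type-I error at n = 5 but
  intervals are wide; with so few plots, power for <15% effects is limited.
- Duncan's procedure and the unadjusted network edge filter inherit the
  multiplicity permissiveness of the classical workflow they reproduce.
- Two-way ANOVA is restricted to the complete sub-grids; no mixed-effects
  modelling of the tree/twig hierarchy is attempted (plot means absorb it).
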
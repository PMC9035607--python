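# Methods

## The model

Stillbirth is scored on US calving records as 1 (born alive), 2 (born
dead) or 3 (died within 48 h); scores 2 and 3 are pooled, making the
trait binary. The evaluation model is a threshold (liability) model: each
calving carries a latent normal liability

    l = hy + YS + PS + sB + mB + sPSB + mPSB + s + m + e,   e ~ N(0, 1),

and the calf is stillborn exactly when `l` exceeds a threshold. Fixed
effects are year-season of calving (seasons start in October and May),
parity-sex of the calf (parities 1, 2, 3-and-later by sex), sire and
maternal-grandsire (MGS) birth-year groups, and two parity-sex x
birth-year interactions (one per bull role) that absorb the sexed-semen
shift in calf sex ratios. Herd-year is random, `hy ~ N(0, sigma_hy^2)`,
to avoid the extreme-category problem of all-alive fixed cells. The bull
effects `(s, m)` are jointly multivariate normal with covariance
`G0 (x) A`, where `G0` is the 2x2 sire-MGS covariance and `A` the
pedigree relationship matrix over bulls. The residual variance is fixed
at 1: in a threshold model only the ratio of effects to residual is
identified. The threshold itself is fixed at 0 and the overall level is
carried by the year-season effects; the reporting threshold reappears in
the observed-scale conversion, where only differences matter.

## Pedigree relationships

Bull pedigrees record sire and MGS. The relationship recursion is
`u_child = 1/2 u_sire + 1/4 u_MGS + phi`, with Mendelian-sampling
variance `d` = 11/16, 3/4, 15/16 or 1 of the base variance according to
which ancestors are known. `A^{-1}` assembles directly from per-bull
contributions `(1/d) k k'` with `k = (1, -1/2, -1/4)`; inbreeding is
ignored, which keeps `d` closed-form (classic sire-MGS practice). The
dense tabular oracle used in tests carries the exact generative diagonal
`a_ii = d + 1/4 a_ss + 1/16 a_mm + 1/4 a_sm`, so oracle and inverse are
exact partners on any pedigree; the simulator draws bull effects from the
same recursion, making the simulator the exact inverse of the estimator's
assumptions.

## Gibbs sampler

Per iteration: (a) each record's liability is drawn from `N(mean, 1)`
truncated to the side its score dictates, by inverse CDF with tail-safe
complementary branches (Acklam's normal quantile plus one Halley
refinement, ~1e-14); (b) each fixed/herd-year factor is updated as a
block — levels of one factor are conditionally independent because every
record hits exactly one level; (c) each bull's `(s, m)` pair is drawn
jointly from its 2x2 full conditional with the `A^{-1}` neighbour
coupling (a bull used as both service sire and MGS contributes the data
cross-term to the off-diagonal); (d) `sigma_hy^2` from its scaled
inverse-chi-square full conditional and `G0` from its inverse-Wishart
full conditional using the bull-effect quadratic form with `A^{-1}`
(Bartlett construction), which makes every retained `G0` draw positive
definite by construction. Priors are weakly informative: IW(df = 4,
scale = df x start values) for `G0`, scaled inverse-chi-square(df = 4)
for `sigma_hy^2`; with hundreds of bulls the prior scale contributes
under 0.5% of the posterior-mean numerator.

Identifiability: year-season keeps all its levels (it is the intercept
basis); parity-sex and the birth-year groups drop their first level;
interaction cells collinear with the margins are detected by a
sequential rank screen on the fixed-effect Gram matrix (main effects
ordered first, tolerance 1e-8) and pinned to zero.

Birth-year groups default to 5-year classes. At feasibility-study data
sizes (hundreds of bulls), single-year groups multiply the parity-sex x
birth-year interactions into hundreds of sparse flat-prior cells that
soak up liability noise and push heritability up; 5-year cohorts are the
same granularity the evaluation uses to stabilise its PTA bases.
Single-year grouping (with sparse years pooled) remains available via
`birth_year_bin=1`.

Debug modes used by the test suite: liabilities can be held fixed, the
variance draws frozen, and the conditional noise switched off, in which
case one sweep is exactly a Gauss-Seidel iteration on the mixed-model
equations — the tests verify convergence to a dense MME solve to 1e-6.

Chain sizes: the production schedule is 500,000 iterations, 100,000
burn-in, thinning 100. The package default (and the scale used by the
acceptance run) is 20,000 / 5,000 / 10, which on ~25,000 records and
~900 bulls runs in about a minute and yields effective sample sizes of
roughly 50-400 for the variance components. Convergence is monitored
with a Geweke first-10%-vs-last-50% z (spectral variances by
Bartlett-windowed autocovariances) and arviz effective sample sizes.

## Genetic parameters

Per retained draw: `sigma_D2 = 4 sigma_s2`, `sigma_M2 = 4 sigma_mgs2 -
4 sigma_s,mgs + sigma_s2`, `sigma_DM = 4 sigma_s,mgs - 2 sigma_s2`,
`sigma_P2 = sigma_s2 + sigma_mgs2 + 1`, with heritabilities and the
direct-maternal correlation formed per draw and then averaged — never
the transform of averaged components. Draws with non-positive maternal
variance are excluded from the correlation summary and counted. 95% HPD
intervals use the shortest sorted window containing ceil(0.95 n) draws.

A caution established during validation: at desk scale (~300 sires with
~80 progeny each at 5% incidence, ~12 effective binomial records per
bull) the posterior of a variance component is strongly right-skewed, so
its posterior mean sits 15-35% above the generating value even though
maximum-likelihood point estimates (cross-checked with lme4's probit
glmer) recover it. This is a property of the exact posterior, not of the
sampler; it shrinks as information per bull grows, and it is the same
phenomenon the feasibility analysis reports for breeds with only
3k-12k records.

## Observed-scale PTA, reliabilities, trends

A bull's underlying solution is `epsilon` = his effect solution plus his
birth-year group solution. The reported scale is anchored by a genetic
base cohort (service sires born 2011-2015; MGS born 2006-2010) and a
phenotypic base %SB* (record-weighted heifer stillbirth percentage over
the base birth years): the anchor `t` solves
`mean_base[1 - F(t - eps*)] = %SB*` exactly (Brent root-find), and
`%SB(bull) = 100 (1 - F(t - epsilon))`. The interchange-of-mean closed
form `t = mean[F^{-1}(1 - %SB*) + eps*]` is available as
`anchor="linear"`; the exact anchor is the default because the linear
form biases the base mean by ~ 1/2 z* phi(z*) var(eps*), which exceeds
0.01 percentage points once the base solutions spread beyond ~0.03.
Conversion fails loudly if no bull falls in a base window: the base
defines the trait's reported scale.

Reliabilities use only the mixed-model-equation diagonal,
`rel = 1 - d^{-1}/sigma_a^2` floored at zero, with
`d = n_records + A^{-1}_bb (G0^{-1})_rr` and `sigma_a^2` the sire (or
MGS) variance for the respective role. Ignoring relationships and
off-diagonals can only overstate reliability; the tests document the
bound against a dense prediction-error-variance oracle.

Trends are ordinary least squares of yearly mean %SB (heifers, by sire
birth year) or yearly mean PTA on year, with the two-sided t test of
zero slope; a constant series reports slope 0 with p = 1. Cubic
smoothing splines (scipy's `make_smoothing_spline`, GCV-chosen roughness)
are provided for plotting only and never enter slope tests.

## Synthetic data

The generator draws herd-year effects, bull-effect pairs down the
pedigree (founders from `N(0, G0)`, descendants by the recursion above),
and record liabilities with unit residual; the livability score is 2
above the threshold, with a configurable fraction relabeled 3 to
exercise the recoding edit. Calving ease is a monotone 5-bin
discretisation of the same liability (summary plumbing only). Defaults
emulate a Jersey-like population: parity mix (0.37, 0.26, 0.37),
female-calf probability (0.75, 0.64, 0.59) by parity reflecting sexed
semen, 40 herds x 18 calving years x ~35 records, 300 service sires and
300 MGS drawn from a cohort of 450 bulls born 1995-2015 so the two PTA
base windows populate. The MGS pool is the older end of the cohort and
the service-sire pool the younger, overlapping in the middle (~150
dual-role bulls): AI bulls sire calves and later appear as maternal
grandsires, and without dual-role bulls the sire-MGS covariance is
identified only through remote pedigree links. The threshold is set to
the empirical (1 - incidence) liability quantile when a target incidence
(default 5%) is requested. Herd-year variance defaults to 0.05 on the
liability scale — no published value exists for it, and 0.05 puts about
as much variance between herd-years as the two genetic components
combined, which is conservative for management variation.

What the generator does not emulate: twins, crossbred calvings beyond a
token fraction (kept only to exercise the purebred edit), embryo
transfer, dams with their own genetic effect (dams are pure links
carrying an MGS), age structure within dam (parities are drawn
independently of dam history), and reporting artifacts such as
herd-specific score usage. Passing tests therefore show the estimator is
correct under its own assumptions, not that real calving data meet them.

## Degenerate inputs and numerical choices

Empty datasets, all-alive herds (which edit to empty), constant chains
(Geweke undefined), bases with no bulls, %SB* of exactly 0 or 100, and
non-positive-definite start matrices all raise explicit errors rather
than propagating NaNs. The rank screen tolerance (1e-8 relative), the
HPD window rule (ceil, guaranteeing at least the nominal mass), and the
0.75 cohort-overlap fraction are fixed constants chosen once and
documented here.
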
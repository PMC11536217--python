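# Methods

## The illness–death model with remission

The population is compartmentalised into susceptible (S), diseased (C)
and dead states on a single-year age grid (0–95). Transitions per step of
length τ years are governed by the incidence rate *i* (per person-year),
state-specific mortality rates *m₀*, *m₁*, and the per-step remission
probability *r*. The adopted first-order explicit scheme applies every
flow to the start-of-step stocks:

    S' = S(1 − (i + m₀)τ) + rC
    C' = C(1 − m₁τ − r) + iτS

Remission is a *probability per step*, not a rate, which is why it is not
multiplied by τ; the engine stores remission rules as per-year
probabilities and converts to the step length as
r_step = 1 − (1 − r_year)^τ. The equivalent prevalence-odds recursion
(π = p/(1 − p)),

    π' = (π(1 − m₁τ − r) + iτ) / (1 − (i + m₀)τ + rπ),

is implemented independently of the compartment form; their elementwise
agreement is a permanent property test, which guards the algebra of both.
Solving the recursion for *r* gives the model-inversion estimator of
remission from (p, i, m₀, m₁) series. The inversion is undefined where
the diseased mass is zero (p = 0); those cells are reported as missing,
never clamped. Raw inverses outside [0, 1] are clamped and counted.

Ordering assumptions worth stating explicitly:

- all flows in a step act on start-of-step stocks; in particular,
  same-step incident cases are not exposed to remission until the next
  step;
- deaths leave the system; there is no migration (see Limitations);
- aging is separate bookkeeping: once per calendar year every cohort's
  (S, C) shifts up one age bin, the age-95 cohort exits the analysis, and
  the year's births enter at age 0 as susceptible.

Stability: the explicit scheme requires per-step probabilities iτ, m₀τ,
m₁τ < 0.5; constructing `StepRates` beyond that bound fails with an
instruction to reduce τ. The default projection step is weekly
(τ = 1/52) because the incidence shock varies within a year; halving τ
changes year-end prevalence by far less than 0.1% on the synthetic
fixture. Negative compartment values (possible only under extreme shocks
at coarse τ) are clamped to zero with a logged counter; a run fails if
clamped mass exceeds 10⁻⁴ of the population, so silent mass
creation/destruction cannot pass unnoticed.

## Trend surfaces

Historical incidence and prevalence are smoothed per sex as additive
natural-cubic-spline models in age and calendar time on the log scale,
fitted by ordinary least squares. The basis is the truncated-power
natural-spline construction, which is linear outside its boundary knots
by construction; calendar-time evaluation beyond the data therefore
continues the fitted log-linear trend — the behaviour the projections
rely on. An additive (age terms + time terms) surface was chosen over a
full tensor product as the most parsimonious smooth consistent with the
inputs and the most stable under extrapolation; a tensor-product
interaction is available behind a constructor switch. Age extrapolation
outside [0, 95] is refused.

Defaults, all overridable: age knots every 10 years (0, 10, …, 90); time
knots every 5 calendar years across the observed range; values are
floored at 10⁻⁸ before the log transform (below any plausible rate
resolution). Rank deficiency (too many knots for the observed grid) is
detected and reported naming the offending dimension. Prevalence
evaluations are clipped to ≤ 1.

## Mortality split

No disease-specific mortality source is assumed. Overall mortality m_all
can be supplied directly or derived from cohort shrinkage of the
population-projection pyramid (with zero migration,
m_all = −log(count(a+1, y+1)/count(a, y))). Given prevalence p and a
mortality-risk ratio RR(t), the two group rates solve

    m_all = p·m₁ + (1 − p)·m₀,   m₁ = RR(t)·m₀
    ⇒ m₀ = m_all / (1 + p(RR − 1)),  m₁ = RR·m₀.

RR(t) = max(1, rr0 − rr_decline·(t − t_ref)) with rr0 = 1.4 — the
meta-analytic all-cause mortality-risk ratio for the motivating disorder
— declining linearly to encode improving disease and comorbidity
management, faster in the diseased group, floored at 1. The decline
slope is genuinely unknown; the default 0.01/year is a configuration
value, not an empirical claim, and the floor guarantees m₁ ≥ m₀ ≥ 0 at
all projected times. p = 1 exactly leaves m₀ undefined and is refused.

## Remission in the fitted pipeline

For file-driven studies, remission is estimated by applying the odds
inversion along cohort diagonals of the annual fitted surfaces
(p(a, y) → p(a+1, y+1), τ = 1). The per-age profile is the median of the
last five cohort transitions, held constant over the projection horizon
(remission is assumed stable into the future); undefined cells fall back
to the overall median. Holding remission fixed makes shocked projections
conservative in the sense that pandemic-era incident cases are assumed
to remit at historical rates.

## Wave decomposition

The weekly epidemic series is modelled as a sum of K Gaussians with no
baseline offset (incidence is assumed to decay to ≈ 0 between waves; a
constant offset is available behind a flag). Fitting is bounded
nonlinear least squares (SciPy's trust-region-reflective), initialised
from the K most prominent local maxima with each σ seeded from the
peak's half-height span; waves are returned sorted by centre.
Non-convergence and under-supplied peaks raise informative errors. Each
wave's duration is its full width at half maximum,
FWHM = 2√(2 ln 2)·σ ≈ 2.3548σ, giving the interval
[μ − FWHM/2, μ + FWHM/2]. Overlapping fitted waves are allowed;
delineation uses each wave's own FWHM regardless of overlap. ISO-week
labels are converted to decimal years at the week midpoint (the ISO
Thursday), confining calendar handling to the readers so that one time
axis serves all modules.

## Incidence shocks and the scenario grid

Per wave w with FWHM interval [s, e] of duration D, the relative
incidence increase A(t) is a trapezoid: linear rise from 0 at s to
h_w = h₀·e^(−λ(w−1)) over W_in·D; a plateau at h_w through e + Δ·D (the
delay Δ models disorder incidence staying elevated while infections
already subside); linear decline to 0 over W_out·D. The delay is a
*fraction of wave duration*, for dimensional consistency with
W_in/W_out. The trapezoid (peak held through the delay) is the simplest
shape consistent with a linear rise, a sustained elevation and a
wash-out decline; a triangle variant (decline immediately after wash-in)
sits behind a switch since the shape is genuinely underdetermined.
Contributions of overlapping waves add, preserving continuity and
monotonicity in h₀. The shock multiplies baseline incidence uniformly
over age and sex: i_eff = i_base·(1 + A(t)), so h₀ = 1, 5, 10 mean
+100%, +500%, +1000% at the first wave's peak.

The grid holds a null baseline (scenario 0) plus the full factorial over
h₀ ∈ {1, 5, 10}, λ ∈ {0.1, 0.2, 0.3}, Δ ∈ {0, 0.25, 0.5} and
W_in = W_out ∈ {0.1, 0.2, 0.3}: 82 scenarios, with
id = 27a + 9c + 3b + d + 1 indexing (h₀, λ, Δ, W) ascending.

## Projection engine

The default horizon is 2019–2031 with year-start reporting (the
conventional reporting years are 2020, 2021, 2023 and 2030). Initial
compartments at the start year split the pyramid by the prevalence rule:
C(a) = p(a)·N(a), S(a) = N(a) − C(a). Births come from the
population-projection input; deaths come from the model's m₀/m₁, so
small discrepancies against the official projection's deaths are
accepted — internal consistency of the illness–death accounting is
prioritised. Migration is set to zero throughout, on the assumption that
prevalence is comparable between resident and migrant populations.
Summaries report cases raw and in millions (2 d.p.) and prevalence in
percent (2 d.p.).

## Synthetic data: what it emulates and what it does not

The generators produce all three input classes with known ground truth:

- **History.** Incidence is log-quadratic in age (peak at 18 years,
  width 28), with a −0.2%/year log-linear calendar decline; female peak
  incidence 0.009/year, male 0.005/year, reflecting the roughly
  two-fold female excess of the motivating disorder. Remission is a
  constant 0.08 per annual step; mortality is Gompertz
  (2.5·10⁻⁵·e^{0.085·age}) declining 1%/year, with a constant 1.4 risk
  ratio. Every cohort is simulated from birth (prevalence 0 at age 0)
  with annual odds-recursion steps, so the prevalence surface satisfies
  the recursion *exactly* along cohort diagonals — the remission
  round-trip recovers the ground truth at machine precision, and that
  exactness is the module's defining contract.
- **Population.** A stationary initial pyramid under year-0 mortality,
  propagated with deaths only (cohort-consistent by construction) and
  360,000 births per sex per year with 2% lognormal fluctuation.
- **Weekly series.** Seven Gaussian waves spanning early 2020 to late
  2022 (centres 2020.22–2022.88, σ 0.045–0.08 years, amplitudes 45–1250
  per 100,000 per week, the largest in early 2022), separated by more
  than one FWHM so the mixture is identifiable, with multiplicative
  lognormal noise of scale 0.05 truncated at zero — incidence rates are
  positive and heteroscedastic.

All randomness flows from one integer seed through per-stream
`numpy.random.default_rng` spawns, so identical configurations give
byte-identical outputs. The generators do *not* mimic real demography,
reporting artefacts (holiday dips, weekday effects), GBD uncertainty
intervals, or age-structured epidemic waves; passing tests demonstrate
the correctness of the machinery under the model's own assumptions, not
the realism of any particular national projection.

## Problem sizes and numerical tolerances

The test suite and acceptance checks run the full 82-scenario grid at
weekly steps over 2019–2031 for both sexes on the 96-bin age grid (a few
seconds), the remission round trip over 30 years of weekly steps
(tolerance 10⁻⁸), the odds/compartment equivalence on 1,000 random
states (10⁻¹⁰, relative for large odds), FWHM against numerically
located half-maximum crossings (10⁻⁹), and mixture/ratio identities of
the mortality model (10⁻¹²).

## Known limitations

- The shock is uniform over age and sex; heterogeneous mental-health
  impacts (by age, sex, education, pre-existing illness) are outside the
  model.
- Projections are deterministic; no uncertainty propagation from the
  input estimates.
- The exact shape of the shock between wash-in and wash-out (trapezoid
  vs triangle) and the remission of pandemic-era incident cases are
  assumptions, isolated behind single switches.
- Remission, as estimated by inversion, absorbs any misfit between the
  smoothed prevalence/incidence surfaces and the true dynamics.
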
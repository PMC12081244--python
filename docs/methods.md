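# Methods

## Decision problem and model structure

The package evaluates treatment strategies for advanced EGFR-mutated
non-small-cell lung cancer with a partitioned-survival cohort model over
three health states: progression-free (PFS), progressed disease (PD) and
death. All patients start progression-free; transitions are unidirectional.
State occupancy at each cycle boundary is read directly from the fitted
endpoint curves rather than from an explicit transition matrix:

- `pfs(t) = S_PFS(t)`
- `death(t) = 1 − S_OS(t)`
- `pd(t) = S_OS(t) − S_PFS(t)`, clipped at 0.

Because PFS and OS are fitted independently, the fitted PFS curve can cross
above the fitted OS curve in the extrapolated tail; the trace clips PD to
zero there (taking `pfs = min(S_PFS, S_OS)` so rows still sum to 1) and logs
the worst violation. `survecon.cohort.transition_probabilities` exports the
implied per-cycle transition probabilities for users who want a strict
Markov reading, attributing deaths to the PD pool first.

### Time conventions

- Cycle length 21 days; horizon 5 years; `n_cycles = ceil(5·365.25/21) = 87`,
  the final cycle counted in full.
- 1 month = 30.4375 days, 1 year = 365.25 days, used everywhere.
- Discounting at 3.0% per year (DSA range 0–5%), applied per cycle as
  `(1.03)^(−k·21/365.25)`.
- Half-cycle correction is available (averaging adjacent boundary
  occupancies) but off by default.
- Outcome accrual uses start-of-cycle occupancy over accrual cycles
  0..86. The undiscounted life-years ceiling is therefore
  87·21/365.25 = 5.002 years. Published three-strategy analyses of this
  comparison print life-year totals above 5 under a nominally identical
  design; that is unreachable under a literal 5-year/21-day accounting, so
  this package implements the stated design and documents the discrepancy
  rather than reverse-engineering an effective horizon.

## Survival families

Six families share a `(shape λ, scale γ)` parameterization, γ in months
(`survecon.distributions`):

| family       | S(t)                                | notes |
|--------------|-------------------------------------|-------|
| exponential  | exp(−t/γ)                           | 1 parameter |
| Weibull      | exp(−(t/γ)^λ)                       | λ=1 → exponential |
| Gompertz     | exp(−(e^{λt}−1)/(λγ))               | λ any real; λ→0 → exponential |
| log-logistic | 1/(1+(t/γ)^λ)                       | γ = median |
| log-normal   | 1 − Φ(ln(t/γ)/λ)                    | γ = e^μ = median, λ = σ |
| gamma        | Q(λ, t/γ) (upper regularized)       | |

Medians are closed-form via the inverse survival function (the gamma family
through `gammainccinv`, accurate well past 1e−8 months). Sampling is by
inverse transform, so draws are reproducible and monotone in the underlying
uniforms.

## Synthetic evidence base

No deposited patient-level dataset exists for this comparison, so the
generator produces the evidence the analysis assumes, and its defaults *are*
the study conditions:

- **Efficacy calibration.** PFS curves are a proportional-hazards Weibull
  pair with shared shape `λ = ln(1/0.70)/ln(23.7/16.6) ≈ 1.0017` and scales
  34.171 / 23.934 months. This satisfies, simultaneously and exactly, the
  trial's headline medians (23.7 months combination, 16.6 months
  osimertinib) and hazard ratio (0.70), because Weibulls with a common shape
  are proportional-hazards with HR = (γ₀/γ₁)^λ.
- **OS structure.** OS is sampled as PFS plus an independent post-progression
  survival increment (exponential, mean 36 months for the combination arm
  and 24 months for osimertinib — consistent with an unreached combination
  OS median at the cut-off and a plausible post-progression course). This
  construction guarantees PFS ≤ OS patient by patient.
- **Censoring.** Administrative only at a 42-month data cut-off by default
  (entry staggering and random dropout are supported but default to zero).
  Arm size defaults to 429, matching a 2:2 randomized arm of a 1,074-patient
  trial.
- **Digitization.** The generator reproduces the figure-digitization step:
  the KM step function sampled on a regular grid (default 1 month), optional
  Gaussian jitter on the ordinates (default 0, so round trips are exact),
  clipped to [0,1], monotonized by running minimum, first point pinned to
  (0,1). At-risk tables are emitted every 3 months by default.
- **Lazertinib monotherapy** has no published curve data and reuses the
  osimertinib arm's PFS and OS curves as a proxy; its economics differ only
  through drug cost and adverse-event profile, so it can never gain QALYs
  over osimertinib under the default configuration.
- **Adverse-event incidences** are not published alongside the management
  costs and disutilities; the packaged per-strategy incidence proportions
  are the package's own calibration to a plausible grade ≥3 profile for
  these regimens and are fully config-driven.

What the generator does **not** emulate: treatment switching, dose
modification, AE-driven discontinuation, non-proportional hazards, or
reporting-quality artifacts of real digitized figures beyond ordinate
jitter. Passing tests therefore demonstrate internal correctness of the
pipeline under the stated generating process, not fidelity to any particular
trial dataset.

## Pseudo-IPD reconstruction

`reconstruct_pseudo_ipd` implements the standard interval-wise allocation:
within each interval between consecutive at-risk reports, events at the
digitized time points are obtained by inverting the product-limit recursion
(`d_k = round(n_k (1 − S_k / Ŝ_{k−1}))`), censorings are spread uniformly
over the interval, and the interval's censoring count is iterated (≤60
rounds) until the implied risk set matches the next published number.
Subjects still at risk after the last coordinate are censored there. Without
an at-risk table the function falls back to an event-only reconstruction
from a caller-supplied cohort size, with a logged warning. On noiseless
digitizations of a 200-patient arm the reconstructed KM matches the input
coordinates with sup-norm well under 0.02.

## Maximum likelihood and model selection

Right-censored log-likelihood `Σ event·log f + (1−event)·log S`, maximized
by Nelder–Mead over log-transformed parameters (raw shape for Gompertz) from
three moment-flavoured starts, tolerance 1e−10 on the objective.
Non-convergence is flagged and the fit excluded from selection. AIC = 2k −
2ℓ and BIC = k·ln n − 2ℓ with k = 1 (exponential) or 2; both are always
recomputable from the stored fields. Selection minimizes AIC by default (BIC
available); exact ties resolve to the earlier family in the fixed order
(exponential, Weibull, Gompertz, log-logistic, log-normal, gamma), putting
the most parsimonious family first. PFS and OS are fitted independently per
arm and endpoint.

## Costs and utilities

2023 USD throughout (amounts converted upstream at 1 USD = 7.08 CNY; the
rate is a documented constant, not a computation). Per cycle:

- **Drug acquisition** accrues against PFS occupancy (treatment until
  progression). The combination strategy's cycle cost is the sum of its
  component prices (amivantamab 17,418.13 + lazertinib 13,420.47);
  amivantamab's weekly-then-biweekly schedule is flattened into the per-cycle
  price with no first-cycle loading adjustment.
- **Monitoring** items carry a billing interval (outpatient and follow-up
  every cycle, laboratory every 2 cycles, MRI every 4 cycles, in PFS; best
  supportive care every PD cycle). Item costs are amortized —
  `unit_cost / every_n_cycles` per cycle — which keeps DSA responses smooth
  and is equivalent in expectation to lumpy billing.
- **End-of-life care** (40,708.33) accrues once per death, at the cycle
  boundary where the death appears in the trace.
- **Adverse events** are one-off at model entry: incidence-weighted
  management costs and incidence-weighted utility decrements. The published
  framing treats AEs as treatment-initiation events without timing detail;
  the one-off convention keeps the DSA interpretable.

QALYs: `Σ_k disc(k)·cycle_years·(0.71·pfs_k + 0.67·pd_k)` minus the one-off
AE disutility. The base-case utility ordering (u_PD ≤ u_PFS) is enforced at
config validation; one-way and probabilistic sensitivity draws may invert it
(the published ranges overlap: PFS 0.57–0.85, PD 0.47–0.71), which triggers
a warning rather than an error.

## Incremental statistics

ICER = ΔC/ΔQ between two strategies; dominance labels replace the ratio when
ΔQ and ΔC make it uninterpretable (dominant: more QALYs for no more cost;
dominated: the reverse; undefined at ΔQ = 0). The frontier routine removes
strictly dominated strategies, then iteratively removes extendedly dominated
ones (ICER non-monotonicity along the cost-sorted frontier) and reports
pairwise ICERs between adjacent frontier members.

## Sensitivity analysis

- **DSA.** Each parameter in turn is set to its low and high bound (source
  bounds where published; ±20% of base otherwise, utilities capped at 1),
  the economics re-evaluated, and parameters ranked by |ICER_high −
  ICER_low|. Non-monotone responses (base ICER outside the bound ICERs) are
  flagged.
- **PSA.** 1,000 iterations by default. Gamma for costs, beta for utilities,
  disutilities and the discount rate, moments matched to (base, range) with
  `sd = (high − low)/3.92`; infeasible beta moments fall back to a uniform on
  the bounds with a warning; degenerate ranges are point masses, so an
  all-degenerate PSA reproduces the deterministic base case exactly.
  Parameters are drawn independently (no correlation structure is
  published). Survival-curve uncertainty is deliberately excluded: the
  published distribution table lists no survival parameters, so curves stay
  at base while cost/utility parameters vary.
- **CEAC.** At each willingness-to-pay value, the fraction of draws in which
  each strategy maximizes NMB; exact NMB ties go to the cheaper strategy, so
  the probabilities always partition unity. Default grid: 0 to 3× per-capita
  GDP ($36,887) in 100 steps.
- **EVPI.** `E[max_s NMB_s] − max_s E[NMB_s]` per patient, reported on a
  grid up to $300,000/QALY. Non-negativity is guaranteed by construction and
  asserted in tests.

## Willingness-to-pay thresholds

Two printed 1–3× per-capita-GDP pairs circulate for 2023 China:
$12,295.7/$36,887.0 and $12,621.19/$37,863.51. The package defaults to the
first pair and ships the second as `WTP_THRESHOLDS_ALTERNATE`.

## Scenario analyses

Packaged overrides, each refreshing the parameter's ±20% bounds:

1. osimertinib at its Chinese medical-insurance unit price (509.11);
2. lazertinib at 1.5× its base price (20,130.71; a published scenario table
   prints 5,840.10 for this row, which is inconsistent with 13,420.47 × 1.5 —
   that literal value ships as the alternate scenario `scenario2_table_value`);
3. alternative utilities u_PFS = 0.804, u_PD = 0.321.

Scenario runs reuse the base survival fits; only the economics re-evaluate.

## Numerical and reproducibility choices

- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning (one child stream per arm, separate
  streams for generation and PSA), so identical seeds give byte-identical
  output CSVs; the run manifest records a config hash and per-file SHA-256.
- KM estimation and the Cox proportional-hazards estimate are delegated to
  lifelines; the reconstruction, parametric MLE, trace and economics are
  implemented here and cross-checked against closed forms and enumeration
  oracles in the test suite.
- Default problem sizes (429 patients/arm for full runs; 10,000/arm for the
  calibration script; 1,000 PSA iterations) keep a full pipeline run in a
  few seconds while leaving Monte Carlo error well inside the tolerances the
  tests assert.

## Known limitations

- Exact reproduction of any published three-strategy totals is out of scope:
  those depend on digitized trial curves and fitted parameters that are not
  deposited. The calibration targets are the generator's medians and hazard
  ratio, plus arithmetic identities on published summary totals.
- The lazertinib proxy makes that strategy's effectiveness identical to
  osimertinib's by construction.
- No treatment switching, societal-perspective or out-of-pocket costs, cure
  fractions, spline models, or covariate-adjusted survival.
- EVPI reflects only the parameter uncertainty the PSA samples; with
  survival uncertainty excluded it understates total decision uncertainty.
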
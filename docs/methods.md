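# Methods

## Models and state space

A patient is in one of four states after resection: **dormancy** (all
metastases growth-restricted micrometastases), **growth** (at least one
escaped), **relapse** (clinically detectable, a fixed growth time τ after the
first escape), or **clearance** (no residual cancer). All four models share
the assumptions: micrometastasis counts at resection are Poisson (equivalent
to seeding by the primary as a time-varying Poisson process); lineages
evolve independently; escape events are exponential with the stated rates;
τ is common to all micrometastases; within- and between-micrometastasis
cell-level heterogeneity is coarse-grained into the rates. Treatment is not
modelled explicitly — its hypothetical effect enters only through parameter
reductions in the relapse-peak sweeps.

Per-lineage no-escape probabilities q(t):

* **Zeroth**: q = e^{−κt}.
* **Model 1**, non-permissive lineage (death λ vs escape κ):
  q₀ = λ/(κ+λ) + κ/(κ+λ) e^{−(κ+λ)t}. Permissive lineage (birth μ, death λ,
  escape κ, secondaries permissive): q_M solves the backward Riccati equation
  q′ = μq² − (κ+λ+μ)q + λ, q(0)=1, solved in closed form through the roots
  q∓ of the quadratic; the numerically stable form
  q = (q₊e^{−Dt} − q₋u₀)/(e^{−Dt} − u₀) with D the root gap and
  u₀ = (1−q₊)/(1−q₋) ≤ 0 avoids overflow at large t. The μ→0 and κ→0 limits
  are taken explicitly.
* **Model 2**: one-step lineages q_V = e^{−κ_V t}; two-step lineages carry a
  hypoexponential escape time, q_s = (κ_V e^{−κ_s t} − κ_s e^{−κ_V t})/(κ_V−κ_s),
  replaced by the Erlang limit (1+κt)e^{−κt} at the mean rate when
  |κ_s−κ_V| < 10⁻⁹·max(κ_s,κ_V) (the general form loses ~6 digits to
  cancellation below that window; at a gap of 10⁻⁶ the two forms agree to
  ~3·10⁻¹¹).
* **Model 3**: integrated rate Λ(t) = at + bt²/2, q = e^{−Λ(t)}.

Patient survival is S(t) = exp(−N̄(1−q(t))) per lineage type (product over
types); hazards and their derivatives are analytic for all four models.

## Conditioned (killed-process) moments

Among patients with no escape by t, Poisson initial counts and independent
lineages keep every per-type count Poisson (thinning), except Model 1's
permissive type. There, with F(x,t)=E[x^n; no escape], the factorial moments
m = F_x(1,t) and v = F_xx(1,t) satisfy linear ODEs whose solutions are
closed-form: m = −q′_M/κ and v = 2μm(1−q_M)/κ. For Poisson(N̄p_M) ancestors
the conditional mean is N̄p_M m and the variance N̄p_M(v+m) (compound-Poisson
identity). The hazard identity h = (escape intensity applied to the
conditioned means) holds exactly in all models and is unit-tested against an
independent `solve_ivp` integration of the ODE system.

The hazard derivative decomposes as dh/dt = E_t[(L+∂_t)I] − Var_t[I] with I
the total escape intensity and L the model generator (gain terms: 0;
κ(μn_M − λn); κ_Vκ_s n_s; bn). Both sides are available independently —
analytically from the moments, and empirically from conditioned-ensemble
simulation — and agree within Monte Carlo error across all models.

## Simulator

Models 0, 2, 3 sample first-escape times exactly per lineage (competing
exponentials; hypoexponential sums; inverse-CDF of the integrated rate — the
quadratic at+bt²/2 is inverted in closed form, no thinning). Model 1 runs a
Gillespie loop over (n_permissive, n_nonpermissive) with a 10⁶-event cap;
breaching the cap (possible when μp_M > λ+κ, a supercritical seeding regime)
raises an explicit error. Conditioned ensembles resimulate to time t and
keep no-escape runs, failing loudly if fewer than 100 survive. Per-patient κ
heterogeneity (two-point or Gamma) is a simulator-only option: the closed
forms never silently mix over parameter distributions, matching the
zero-population-variance convention used for fitting.

A note on the heterogeneity property: a κ-mixture cohort at matched mean has
a *lower* hazard than the homogeneous cohort throughout the observable
follow-up window (the variance term), but at asymptotically late times the
mixture tracks its most indolent stratum and the ordering reverses. The test
asserts the window version (years 1–4 at κ̄ = 0.3).

## Kaplan–Meier layer

KM estimation is delegated to lifelines; Greenwood standard errors are
computed from the fitted event table. Because relapse cannot precede τ, the
estimated curve is anchored at S(τ)=1. Times in files are always years
post-resection; the escape clock is t − τ, converted centrally. Hazard
estimation uses life-table bins (default: the data spacing; configurable
bin width with linear-in-log-f resampling), optional Gaussian-kernel
smoothing (bandwidth 1 y by default in the drivers), negative finite
differences floored at zero and counted in metadata. Extrapolation to 20 y
defaults to a constant tail — the least-assumption rule consistent with a
non-increasing late hazard — with a log-linear alternative. The published
analyses did not state their smoothing/extrapolation procedures; these are
this package's conventions, recorded in curve metadata.

## Synthetic study curves

The real inputs to this kind of analysis are RFI curves digitized from
published figures; no machine-readable accession exists, so fixtures emulate
them: exact closed-form values on a figure-like grid (yearly 3–15 y for the
EBCTCG-like cohorts of 6399 patients, τ = 3 y; half-yearly 1.5–10 y for the
Chia-like cohorts of 1187 patients, τ = 1.5 y), binomial noise at the cohort
size (sd √(f(1−f)/n), the dominant sampling error of a KM curve at these
sizes), optional uniform digitization jitter, running-minimum monotone
correction, renormalisation at τ. Preset parameters were chosen once to give
~40–60% 15-year recurrence (realistic for no-adjuvant-therapy cohorts); the
ER+-like preset uses the two-step model with N̄_V ≈ 0 so its hazard rises to
an interior maximum. What the fixtures do *not* emulate: correlated KM noise
across time points (binomial draws are independent per point), reader error
beyond uniform jitter, cohort censoring structure, and stage/treatment
heterogeneity — so passing tests show the pipeline recovers its own data-
generating process at study-like noise, not that the models describe real
cohorts.

## Fitting

The objective is the total squared deviation Σᵢ(f_model(tᵢ)−f_data(tᵢ))² at
the data's time points (tᵢ ≥ τ); τ is fixed, never fitted. Fitting is pure
random search: uniform draws from per-parameter boxes (count means [0, 50];
rates [0, 2]/y; p_M [0, 1]; b [0, 0.5]/y²), vectorised in batches of 2¹⁵
draws; the draw stream is sequential, so the best tsd is non-increasing in
the sample count at fixed seed. An optional Nelder–Mead polish exists but is
off by default. Budgets: 10⁶ draws reproduces the published method; the
monotone-fixture "all models within 2×" experiment uses 10⁷ draws because at
10⁶ the 4–5-parameter searches still carry visible convergence noise
(observed ratios up to ~2.7 purely from the search, ~1.1–1.4 at 10⁷); both
run in seconds to tens of seconds.

## Diagnostics

Hazard-increase conditions at t = 0 under Poisson counts: μp_M > λ+κ,
κ_sN̄_s > κ_VN̄_V, b > a². The relapse rate r = h·S peaks away from 0 iff
dr/dt|₀⁺ > 0, i.e. dh/dt(0) > h(0)², giving μp_M > λ+κ(1+N̄),
κ_sN̄_s > κ_VN̄_V(1+N̄_V), b > a²(1+N̄); the sweep drives the ratio
rhs/lhs to [2, 1, 1/5, 1/25] by root-finding on the therapy-mimicking
parameter (κ, N̄_V, a), with a dense-grid + bounded-refinement search over
r(t) as ground truth for peak existence. As the ratio falls the peak moves
*later* and grows more prominent relative to the early relapse rate (the
swept parameter also scales overall relapse intensity, so the absolute peak
height can fall).

Burden estimation assumes the late-time collapse of Models 1–3 onto
Zeroth-type dynamics (all seeding-capable patients have relapsed; all
two-step micrometastases have taken their first step; κ(t) has stopped
rising): then E_t[n] = h/κ and Var_t[n] = −h′/κ². The estimators refuse
windows where the hazard increases (the collapse assumption fails there),
floor slightly negative variances with a warning, and accept an analytic h′
when one is available.

## Numerical conventions and problem sizes

Degenerate all-zero-rate parameter sets return S ≡ 1, h ≡ 0 rather than
erroring. Validation runs use 10⁵ simulated patients per setting (binomial
SE ~0.0016 per survival point), conditioned ensembles of 1.2–3×10⁴ runs
(Model 1's Gillespie ensembles at the smaller size), 50 random draws for the
decomposition identity, 1000 draws per model for the sign-agreement check,
and 2-year life-table bins for the burden validation at t = 10 y. All
stochastic code draws from `numpy.random.default_rng` seeded explicitly;
identical seeds give byte-identical CSV outputs.

## Known limitations

Closed forms assume the "secondaries are permissive" convention for Model 1
(they descend from cells that already colonised); the alternative
(permissive with probability p_M) is available in the simulator only.
Population heterogeneity in κ or N̄ has no closed-form treatment here — it
exists solely as a simulator option. Exact per-patient growth-time
variability, treatment effects, and spatial/cellular structure inside a
micrometastasis are out of scope. The burden estimators inherit the
smoothing and extrapolation conventions of the hazard layer; with figure-
digitized inputs their uncertainty would be dominated by digitization error,
which is only crudely emulated here.
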
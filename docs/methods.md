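# Methods

## The model

A subject's lever presses are modeled as the output of two latent Poisson
processes.  Entries into response bouts arrive at the **bout-initiation
rate** *b* (min⁻¹); once a bout is underway, responses arrive at the much
faster **within-bout rate** *w* (min⁻¹).  The **mean bout length** *L*
(responses beyond the bout initiator) fixes the probability that the next
inter-response time (IRT) is a within-bout interval, `p = L/(1+L)`.  Every
IRT is lengthened by an absolute **refractory period** δ, the minimum time
the apparatus and organism need between two presses, so the IRT density is
a δ-shifted two-component exponential mixture with weights `p, 1−p` and
rates `w, b` (zero below δ).  The model requires `w > b` — the mixture is
only interpretable when within-bout pauses are systematically shorter than
between-bout pauses.

During extinction the performance is nonstationary: `L_t = L0·e^{−γt}`
decays toward zero while `w_t` and `b_t` decay from their baselines toward
a shared floor Ω (`β ≥ α ≥ 0`, `w0 > b0 ≥ Ω ≥ 0`).  The parameters of the
IRT beginning at time *t* are frozen at *t*; there is no decay within a
single interval.  Decay rates are reported as half-lives `H = ln2/rate`.
Between consecutive extinction sessions each parameter changes by a
multiplicative recovery coefficient, `x₂ = C(x)·x₁`, with the coefficients
for the decay processes acting on the half-lives (so the session-2 rate is
`rate/C(H)`).  Ω is shared between `w_t` and `b_t` exactly as written; the
package does not implement variants with separate asymptotes.

Canonical units are minutes throughout the internals; δ is converted to
seconds only at I/O boundaries and in summary tables.

## Simulation

Sessions are generated by the model's own sequential recipe, from `t₁ = 0`:
evaluate the dynamics at the pending IRT's start time, draw the bout state
(within-bout with probability `p_t`), draw an exponential pause at the
state's rate, add δ, advance the clock.  The first latency (lever extension
to first response) is produced by the same mixture, and a flag records
that convention so inference can treat it symmetrically.  The session is a
hard truncation: the first response that would land beyond the session end
is discarded.

Cohorts emulate a two-strain extinction experiment (default 6 rats per
strain, one or two 65-min sessions).  Each strain is a log-normal
population per parameter; individual vectors are drawn by exponentiating
Gaussian draws and rejecting joint draws that violate the ordering
constraints (budget 1000 retries — with realistic dispersions rejections
are rare, and an exhausted budget raises rather than silently truncating).
The default log-scale population SD is 0.2: fitted group dispersions for
this preparation are not published, and ±20% individual variation around
the group median is typical of what operant parameter estimates show
across subjects.  RNG streams are keyed by (seed, strain, rat, session)
counters, so enlarging a cohort never reshuffles existing animals and
every dataset is byte-reproducible from its seed.

Reference median parameter sets for the two strains (`SHR_REFERENCE`,
`WKY_REFERENCE`) are built in and drive the examples, the default
recovery experiments, and the acceptance script.  A full 6 + 6 × two-session
design generated from them produces ≈18,000 IRTs.

What the generator does *not* emulate: maintenance (reinforced) sessions,
reinforcer deliveries, inter-trial intervals, discriminative stimuli,
satiation or circadian drift, and any within-IRT nonstationarity.  Passing
recovery tests therefore demonstrate that the estimator is faithful to the
model's own generative process, not that the model is true of any
particular preparation.

## Likelihood

A rat-session contributes the product of mixture densities over its
modeled intervals, each evaluated with dynamics frozen at the interval's
start.  Two conventions are flag-controlled and on by default:

- the **first latency** enters as an ordinary interval (it is generated by
  the same process in the simulator);
- the gap from the last response to the session end enters as a
  **right-censored survival term**.  Ignoring that terminal pause — often
  many minutes in late extinction — would bias rate estimates upward.

A δ at or above the shortest modeled interval gives likelihood −∞ (an
impossible dataset), not an error.  Mixture terms are combined by
log-sum-exp; extremely long intervals underflow to large negative finite
values rather than −∞, which keeps MCMC arithmetic stable.

## Hierarchical estimation

Each rat has 8 log-parameters (plus 8 log recovery coefficients when a
second session is present).  Within a strain each log-parameter is
Normal(μ, σ²); μ and σ carry flat priors on bounded supports:

- μ and individual log-parameters: `[log 10⁻⁴, log 10⁴]` in canonical
  units;
- decay rates additionally bounded below by `ln2 / 5.6×10⁶ min⁻¹`, the
  rate corresponding to the half-life reporting cap.  Unbounded decay-rate
  priors make the posterior improper when the data cannot exclude
  zero decay; the cap (≈10 years, effectively "no decay within a session")
  bounds the estimand instead;
- population SDs: uniform on (0, 5].

**Sampler.**  Adaptive Metropolis-within-Gibbs.  Each individual
log-parameter gets a Gaussian random-walk update; proposals violating the
ordering constraints (`w0 > b0 ≥ Ω`, `β ≥ α`, and the analogous check on
the implied session-2 parameters) are rejected, which is an exact
Metropolis step on the constraint-truncated space.  We sample the natural
log-parameters rather than a constraint-free reparameterization because
the population model is declared on exactly these coordinates — a
reparameterization would drag Jacobian terms through the population
density and obscure the recovery-coefficient algebra — and because the
constraints bind rarely at realistic values, so rejection costs little
mixing (observed per-coordinate acceptance ≈ 0.38–0.53 against the 0.44
target).  Group μ and σ have closed-form conditional draws (truncated
Gaussian; inverse-square-root-Gamma via `u = σ⁻² ~ Gamma((n−1)/2, S/2)`,
with a Metropolis fallback for single-rat strains).

Step sizes adapt by Robbins-Monro scaling toward 0.44 acceptance during
burn-in only and are frozen afterwards, keeping the retained chain
Markovian.  Defaults: 5,000 burn-in sweeps, 20,100 retained samples, one
chain.  Reduced chains (1,000–1,500 burn-in, 2,000–4,000 retained) are
used for the experiments in the test-suite and acceptance script; the
6-rat posteriors here are unimodal and these lengths reproduce the
long-chain quantiles to well within their Monte-Carlo error.

**Initialization.**  A data-driven heuristic (overall rate, minimum
interval) refined by a short Nelder-Mead likelihood climb per rat; δ is
then clamped below the rat's shortest modeled interval across all
sessions.  A non-finite starting likelihood raises with the offending rat
named.

**Reporting.**  Group location samples are exponentiated; medians and
central 95% intervals are reported on the linear scale — `e^μ` estimates
the strain's *median* parameter.  Decay rates are reported as half-lives
(capped, with a flag), δ in seconds.  The strain effect for parameter *x*
is `E_x = μ_x(A) − μ_x(B)` per retained sample; `e^{E_x}` is the ratio of
group medians, and the difference is called significant when the 95% CI of
`E_x` excludes 0.  No multiple-comparison correction is applied across the
eight parameters — single-parameter inferences should be read accordingly.

**Numerical conventions.**  δ proposals are implicitly bounded by the data
(likelihood −∞ at or above the minimum interval, strict inequality, so a
tie at the boundary is rejected); half-life capping happens at the
reporting layer while the sampler works on rates; empty sessions
contribute only their censored term (or nothing when censoring is off).

## Diagnostics

**Binned rates.**  Sessions are divided into eight equal bins (8.125 min
for a 65-min session); counts over bin width give rates whose sum × width
reconstructs the response total exactly.  These are the same summaries a
conventional extinction ANOVA consumes, and they are exported as plain
tables for use in any stats package.

**Log-survivor curves.**  Within a session window (defaults: first 10 min,
last 15 min) the IRTs whose *start times* fall in the window form an
empirical survivor function; on semi-log axes the bi-exponential mixture
shows the diagnostic convex "broken-stick" shape whose early slope tracks
−w and late slope −b.

**Posterior-predictive checks.**  Joint posterior draws (sampled without
replacement when the request does not exceed the chain length, with
replacement — flagged — otherwise) drive fresh simulations of every rat;
binned-rate curves and survivor curves of the replicates are summarized by
pointwise medians and central 95% bands.  Survivor curves are evaluated as
right-continuous step functions on a fixed 200-point duration grid before
percentiles are taken.

**Recovery harness.**  `recovery_experiment` loops simulate → fit →
compare: per replicate and parameter it records the generative group
median, the posterior median and 95% CI, a coverage flag, and log-scale
bias.  Generative overrides express bias probes: `("swap", other_strain)`
sources a parameter's median from the other strain, `("scale", k)`
multiplies it.  Two scenarios are preconfigured: the short-bout strain
simulated with the control strain's fast bout-length decay, and the same
with baseline bout length scaled to one third.  In both, the recovered
bout-length half-life envelops the swapped generative value — short bouts
do not masquerade as absent decay.  A known limit surfaced by the second
scenario: with `L0 ≈ 0.3` only ~20% of responses are within-bout, and the
group-level posterior of the *within-bout* decay rate α concentrates near
"no decay", missing its generative value — a weak-identifiability effect,
not a sampler artifact (insensitive to chain length).  Conclusions about α
at very short bout lengths need longer or more sessions.

## Experiment sizes and test design

Closed-form operations are tested against independent arithmetic,
quadrature (density normalization to 1 within 10⁻⁶), and round-trip
identities.  The simulator is validated distributionally (KS against the
closed-form shifted-mixture CDF at n = 10⁵, α = 0.01).  The Metropolis
kernel is checked against the analytic Gamma posterior of the degenerate
single-exponential submodel.  Calibration uses 20 replicate 3-rat, 15-min
cohorts (coverage within [0.85, 1] of nominal 0.95, a band set in advance
to absorb binomial error and within-replicate correlation); the headline
recovery experiment uses 6 + 6 rats × 65 min with reduced chains.  These
sizes are the package's defaults for its own experiments; all are
overridable through `MCMCConfig` and the harness arguments.

## Known limitations

- Single-chain default; the multi-chain R-hat workflow is left to the
  user (chains are reproducible per seed, so running several seeds and
  comparing quantiles is straightforward).
- Only one- and two-session designs; longer series would need a model for
  how recovery coefficients compound, which multiplicativity alone does
  not settle.
- The δ posterior presses against the sample-minimum IRT (its likelihood
  is increasing up to that boundary), so δ intervals are asymmetric and
  slightly conservative below the true value.
- Group-level α (and to a lesser degree w0) is weakly identified when
  bout lengths are very short; see the recovery-harness note above.
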
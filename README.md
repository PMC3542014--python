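# dberm — dynamic bi-exponential refractory modeling of operant extinction

Free-operant responding (e.g., a rat pressing a lever) is not a single
Poisson stream: responses cluster into *bouts*.  The dynamic bi-exponential
refractory model (DBERM) describes the inter-response times (IRTs) of such
performance with two Poisson processes — a slow **bout-initiation** process
with rate *b* and a fast **within-bout** process with rate *w* — separated
by an absolute refractory period *δ*.  During extinction (reinforcement
withheld), responding declines, and DBERM lets the mean bout length *L*,
*w*, and *b* decay exponentially over the session.

The IRT that starts at session time *t* has density

```
Pr(IRT_t = τ)  =  0                                                   τ < δ
Pr(IRT_t = τ)  =  p_t w_t e^{−w_t(τ−δ)} + (1−p_t) b_t e^{−b_t(τ−δ)}   τ ≥ δ
```

with mixing probability `p_t = L_t / (1 + L_t)` and dynamics

```
L_t = L0 e^{−γt}
w_t = (w0 − Ω) e^{−αt} + Ω          w0 > b0 ≥ Ω ≥ 0
b_t = (b0 − Ω) e^{−βt} + Ω          β ≥ α ≥ 0
```

where Ω is an asymptotic rate floor and the decay rates are reported as
half-lives, `H = ln 2 / rate` (capped at 5.6 × 10⁶ min).  A multiplicative
*recovery coefficient* `C(x)` relates each parameter's value in a second
extinction session to its first-session value, `x₂ = C(x)·x₁`.

The package is aimed at behavior analysts dissecting response
microstructure — for example comparing the spontaneously hypertensive rat
(SHR, an ADHD model) with its Wistar-Kyoto (WKY) control during extinction.
It provides:

- **`dberm.core`** — the mixture density, dynamics, constraint checks,
  half-life transforms, recovery coefficients (all closed-form, unit-tested
  against independent arithmetic and quadrature);
- **`dberm.cohort`** — a Monte-Carlo session simulator and two-strain cohort
  generator with log-normal individual heterogeneity;
- **`dberm.inference`** — hierarchical Bayesian estimation (log-normal
  individual parameters within strain, flat bounded hyperpriors, adaptive
  Metropolis-within-Gibbs), posterior summaries on the conventional
  reporting scale, and strain effect sizes `E_x = μ_x(A) − μ_x(B)`;
- **`dberm.diagnostics`** — binned response rates, log-survivor curves,
  posterior-predictive envelopes, and a simulate-fit-compare
  parameter-recovery harness;
- **`dberm.io`** / a thin `dberm` CLI — event-time CSV interchange, truth
  sidecars, HDF5 chain stores, and `simulate / fit / summarize / effects /
  ppc / recover` subcommands.

## Worked example

`examples/fit_hierarchical.py` simulates 6 WKY-like rats for one 65-min
extinction session from the package's reference group medians (log-scale
population SD 0.2) and refits them with a reduced chain:

```
fitting 2853 IRTs from 6 rats ...

     parameter generative    median                 95% CI
            L0       2.81      2.61   [    1.80,     3.64]
            w0     175.68    174.77   [  129.14,   243.75]
            b0      14.70     14.79   [   11.70,    18.68]
           H_L      19.37     22.59   [   16.21,    31.46]
           H_w      21.28     18.72   [   13.29,    27.44]
           H_b       4.69      4.85   [    3.32,     6.70]
 delta_seconds       0.12      0.12   [    0.11,     0.13]
         omega       1.64      1.64   [    1.21,     2.09]
```

Every generative value sits inside its 95% credible interval.  The
bout-initiation rate `b0` (how often lever-pressing episodes start), the
refractory period `δ`, and the asymptote `Ω` are sharply identified; the
half-lives carry wider intervals because a single 65-min session contains
limited information about slow decay.  The other example scripts
(`examples/simulate_cohort.py`, `examples/posterior_checks.py`,
`examples/recovery_study.py`) demonstrate cohort generation (a full
6 + 6 rat × two-session design yields ~18,000 IRTs), posterior-predictive
checking, and credible-interval calibration (coverage 0.97 over 32
parameter-replicates against the nominal 0.95).

A classic closed-form result falls out of the reference medians: the WKY
bout length (L0 = 2.81, H_L = 19.37 min) decays past the nearly constant
SHR bout length (L0 = 0.91, H_L = 2794 min) at

```python
>>> from dberm import bout_length_crossing_time, SHR_REFERENCE, WKY_REFERENCE
>>> round(bout_length_crossing_time(SHR_REFERENCE, WKY_REFERENCE), 2)
31.73
```

minutes — mid-session — so short SHR bouts cannot by themselves explain the
absence of bout-length decay in that strain.

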
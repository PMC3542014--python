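"""Hierarchical Bayesian estimation of the bout-mixture extinction model.

The hierarchy has two levels.  Each rat's inter-response times (IRTs) in one
or two extinction sessions are modeled by the time-varying bi-exponential
refractory mixture, with the rat's own eight parameters (plus eight
multiplicative recovery coefficients when a second session is present).
Each individual parameter is log-normally distributed across rats within a
strain, and the log-scale group locations (mu) and spreads (sigma) carry
flat priors on bounded supports (bounded so the joint posterior is proper;
decay rates are additionally bounded below so that half-lives cannot exceed
the reporting cap).

Sampling is adaptive Metropolis-within-Gibbs: each individual log-parameter
gets a Gaussian random-walk update whose step size adapts toward a 0.44
acceptance rate during burn-in (and is frozen afterwards, keeping the
retained chain Markovian); proposals that violate the model's ordering
constraints are rejected outright, which is an exact Metropolis step on the
constraint-truncated parameter space.  Group-level mu and sigma have
closed-form conditional draws (Gaussian, and inverse-square-root-Gamma)
truncated to their prior supports.

Posterior summaries are reported on the linear scale (medians and central
95% credible intervals via exponentiation), with decay rates converted to
half-lives and the refractory period to seconds; strain differences are
summarized by the effect size E_x = mu_x(strain A) - mu_x(strain B), whose
exponential is the ratio of group medians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import COEFF_NAMES, PARAM_NAMES, CohortDataset, SessionRecord
from .core import HALF_LIFE_CAP, LN2, ConstraintViolation, HalfLife

__all__ = [
    "EffectSize",
    "InitializationError",
    "MCMCConfig",
    "PosteriorChains",
    "PosteriorSummary",
    "cap_half_life",
    "fit_shifted_exponential_mcmc",
    "log_posterior",
    "rat_log_likelihood",
    "run_mcmc",
    "strain_effect",
    "summarize_posterior",
]

_IDX = {n: i for i, n in enumerate(PARAM_NAMES)}
_RATE_IDX = (_IDX["gamma"], _IDX["alpha"], _IDX["beta"])

# Flat-prior supports on the log scale.  General parameters live in
# [1e-4, 1e4] canonical units (minutes / per-minute); decay rates are
# bounded below by ln(2)/cap so half-lives respect the reporting cap.
_LOG_LOW = np.full(8, math.log(1e-4))
_LOG_HIGH = np.full(8, math.log(1e4))
for _i in _RATE_IDX:
    _LOG_LOW[_i] = math.log(LN2 / HALF_LIFE_CAP)
_SIGMA_MAX = 5.0

# Recovery coefficients (dimensionless) use the generic support only.
_CLOG_LOW = np.full(8, math.log(1e-4))
_CLOG_HIGH = np.full(8, math.log(1e4))


class InitializationError(RuntimeError):
    """Raised when the sampler cannot find a finite starting point."""


# ---------------------------------------------------------------------------
# likelihood machinery


@dataclass(frozen=True)
class _SessionData:
    """Precomputed modeling arrays for one session."""

    starts: np.ndarray      # start time of each modeled interval
    durs: np.ndarray        # duration of each modeled interval
    tail_start: float | None  # start of the right-censored terminal interval
    tail_dur: float | None
    min_interval: float


def _prepare_session(
    record: SessionRecord, include_first_latency: bool, censor_tail: bool
) -> _SessionData:
    times = record.response_times
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("response times must be strictly increasing")
    starts_parts = []
    durs_parts = []
    if times.size:
        if include_first_latency:
            starts_parts.append([0.0])
            durs_parts.append([times[0]])
        starts_parts.append(times[:-1])
        durs_parts.append(np.diff(times))
    starts = np.concatenate(starts_parts) if starts_parts else np.empty(0)
    durs = np.concatenate(durs_parts) if durs_parts else np.empty(0)
    tail_start = tail_dur = None
    if censor_tail:
        tail_start = float(times[-1]) if times.size else 0.0
        tail_dur = record.session_duration - tail_start
    min_int = float(durs.min()) if durs.size else math.inf
    return _SessionData(starts, durs, tail_start, tail_dur, min_int)


def _theta_ok(th: np.ndarray) -> bool:
    """Ordering constraints on a natural-scale parameter vector
    (positivity is automatic for exponentiated log parameters)."""
    return (th[1] > th[2] >= th[7]) and (th[5] >= th[4])


def _apply_recovery_vec(th: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Session-2 natural parameters from session-1 values and coefficients
    (decay rates divide by the half-life coefficients)."""
    out = th * c
    out[3] = th[3] / c[3]
    out[4] = th[4] / c[4]
    out[5] = th[5] / c[5]
    return out


def _session_loglik(th: np.ndarray, sess: _SessionData) -> float:
    L0, w0, b0, g, a, b, dlt, om = th
    if sess.min_interval < dlt:
        return -math.inf
    ll = 0.0
    if sess.durs.size:
        s = sess.starts
        L = L0 * np.exp(-g * s)
        wt = (w0 - om) * np.exp(-a * s) + om
        bt = (b0 - om) * np.exp(-b * s) + om
        pt = L / (1.0 + L)
        u = sess.durs - dlt
        with np.errstate(divide="ignore"):
            la = np.log(pt) + np.log(wt) - wt * u
            lb = np.log1p(-pt) + np.log(bt) - bt * u
        ll += float(np.logaddexp(la, lb).sum())
    if sess.tail_dur is not None:
        ut = sess.tail_dur - dlt
        if ut > 0:
            t0 = sess.tail_start
            L = L0 * math.exp(-g * t0)
            wt = (w0 - om) * math.exp(-a * t0) + om
            bt = (b0 - om) * math.exp(-b * t0) + om
            pt = L / (1.0 + L)
            with np.errstate(divide="ignore"):
                la = (math.log(pt) if pt > 0 else -math.inf) - wt * ut
                lb = math.log1p(-pt) - bt * ut
            ll += float(np.logaddexp(la, lb))
    return ll


def _rat_loglik(
    th: np.ndarray, c: np.ndarray | None, sessions: list[_SessionData]
) -> float:
    if not _theta_ok(th):
        return -math.inf
    ll = _session_loglik(th, sessions[0])
    if len(sessions) > 1:
        th2 = _apply_recovery_vec(th, c)
        if not _theta_ok(th2):
            return -math.inf
        ll += _session_loglik(th2, sessions[1])
    return ll


# ---------------------------------------------------------------------------
# public likelihood / posterior entry points


def rat_log_likelihood(
    record_ext1: SessionRecord,
    record_ext2: SessionRecord | None,
    params,
    coeffs=None,
    include_first_latency: bool = True,
    censor_tail: bool = True,
) -> float:
    """Log-likelihood of one rat's session(s) under given parameters.

    The likelihood is the product of the mixture density over the modeled
    intervals, with dynamics frozen at each interval's start time.  The
    latency from lever extension to the first response is included as an
    ordinary interval, and the gap from the last response to the session
    end enters as a right-censored survival term; both are flag-controlled.
    A refractory period exceeding the shortest modeled interval yields
    ``-inf`` (an impossible dataset), not an error.
    """
    th = np.array([getattr(params, n) for n in PARAM_NAMES], dtype=float)
    sessions = [_prepare_session(record_ext1, include_first_latency, censor_tail)]
    c = None
    if record_ext2 is not None:
        if coeffs is None:
            raise ConstraintViolation("recovery coefficients required with a second session")
        sessions.append(_prepare_session(record_ext2, include_first_latency, censor_tail))
        c = coeffs.as_array()
    return _rat_loglik(th, c, sessions)


def _log_normal_logpdf(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    z = (x - mu) / sigma
    return float(np.sum(-0.5 * z * z - np.log(sigma)) - 0.5 * x.size * math.log(2 * math.pi))


def log_posterior(
    dataset: CohortDataset,
    individual_params: dict,
    group_hyperparams: dict,
    include_first_latency: bool = True,
    censor_tail: bool = True,
) -> float:
    """Unnormalized log-posterior of the full hierarchy at a point.

    ``individual_params`` maps rat_id to a ``(DBERMParams, RecoveryCoefficients
    or None)`` pair; ``group_hyperparams`` maps strain to a dict with
    log-scale ``mu``/``sigma`` arrays in canonical parameter order (and
    ``coeff_mu``/``coeff_sigma`` for two-session designs).  Hyperparameters
    outside the flat-prior supports give ``-inf``.
    """
    total = 0.0
    for strain, hp in group_hyperparams.items():
        for key, low, high in (("mu", _LOG_LOW, _LOG_HIGH),):
            mu = np.asarray(hp[key], dtype=float)
            if np.any(mu < low) or np.any(mu > high):
                return -math.inf
        sig = np.asarray(hp["sigma"], dtype=float)
        if np.any(sig <= 0) or np.any(sig > _SIGMA_MAX):
            return -math.inf
    for rat_id in dataset.rat_ids:
        params, coeffs = individual_params[rat_id]
        recs = dataset.sessions_for(rat_id)
        rec2 = recs[1] if len(recs) > 1 else None
        total += rat_log_likelihood(
            recs[0], rec2, params, coeffs,
            include_first_latency=include_first_latency, censor_tail=censor_tail,
        )
        hp = group_hyperparams[dataset.strain_of(rat_id)]
        v = np.log([getattr(params, n) for n in PARAM_NAMES])
        total += _log_normal_logpdf(v, np.asarray(hp["mu"]), np.asarray(hp["sigma"]))
        if coeffs is not None:
            lc = np.log(coeffs.as_array())
            total += _log_normal_logpdf(
                lc, np.asarray(hp["coeff_mu"]), np.asarray(hp["coeff_sigma"])
            )
        if not math.isfinite(total):
            return -math.inf
    return total


# ---------------------------------------------------------------------------
# sampler configuration and output containers


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``n_samples`` retained draws are collected after ``burn_in`` discarded
    adaptation sweeps; the default retained count is 20,100.  Step sizes
    adapt only during burn-in.  ``init_optimize`` refines each rat's
    starting point by a short derivative-free likelihood maximization.
    """

    n_samples: int = 20100
    burn_in: int = 5000
    include_first_latency: bool = True
    censor_tail: bool = True
    init_optimize: bool = True
    init_maxiter: int = 400
    target_accept: float = 0.44
    initial_step: float = 0.08

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class PosteriorChains:
    """Retained MCMC draws for every individual and group parameter.

    Individual parameters and recovery coefficients are stored on the log
    scale in canonical order; group locations/spreads per strain likewise.
    ``acceptance`` records per-block mean acceptance rates.
    """

    param_names: tuple
    coeff_names: tuple | None
    rat_ids: list
    rat_strains: dict
    individual: dict            # rat_id -> (n_samples, 8) log scale
    individual_coeffs: dict | None
    group_mu: dict              # strain -> (n_samples, 8)
    group_sigma: dict
    coeff_mu: dict | None
    coeff_sigma: dict | None
    config: dict = field(default_factory=dict)
    seed: int = 0
    acceptance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return next(iter(self.group_mu.values())).shape[0]

    @property
    def strains(self) -> list:
        return list(self.group_mu)

    def group_linear_samples(self, strain: str, parameter: str) -> np.ndarray:
        """Back-transformed (linear-scale) samples of a group median.

        Accepts canonical names, half-life names (``H_L``/``H_w``/``H_b``)
        and ``delta_seconds``.
        """
        mu = self.group_mu[strain]
        if parameter in _IDX:
            return np.exp(mu[:, _IDX[parameter]])
        if parameter in ("H_L", "H_w", "H_b"):
            j = {"H_L": _IDX["gamma"], "H_w": _IDX["alpha"], "H_b": _IDX["beta"]}[parameter]
            return LN2 * np.exp(-mu[:, j])
        if parameter == "delta_seconds":
            return 60.0 * np.exp(mu[:, _IDX["delta"]])
        if self.coeff_mu is not None and parameter in (self.coeff_names or ()):
            return np.exp(self.coeff_mu[strain][:, (self.coeff_names).index(parameter)])
        raise KeyError(f"unknown parameter label {parameter!r}")


# ---------------------------------------------------------------------------
# initialization


def _heuristic_init(sessions: list[_SessionData], duration: float) -> np.ndarray:
    """Crude data-driven starting values on the natural scale."""
    s0 = sessions[0]
    n = max(s0.durs.size, 1)
    rate = n / duration
    min_irt = min(s.min_interval for s in sessions)
    dlt = max(min(0.9 * min_irt, 0.05), 1.5e-4)
    omega = max(0.2 * rate, 2e-4)
    b0 = max(0.6 * rate, omega * 1.5, 1e-3)
    w0 = max(20.0 * b0, 2.0 * b0 + 1.0)
    return np.array([1.0, w0, b0, LN2 / 20.0, LN2 / 20.0, LN2 / 10.0, dlt, omega])


def _refine_init(
    th0: np.ndarray, sessions: list[_SessionData], maxiter: int
) -> np.ndarray:
    """Short Nelder-Mead maximization of the rat likelihood on the log scale."""
    from scipy.optimize import minimize

    def neg(x):
        if np.any(x < _LOG_LOW) or np.any(x > _LOG_HIGH):
            return 1e12
        th = np.exp(x)
        ll = _rat_loglik(th, None, sessions[:1])
        return 1e12 if not math.isfinite(ll) else -ll

    res = minimize(
        neg, np.log(th0), method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-3},
    )
    x = res.x
    if neg(x) >= 1e12:
        return th0
    return np.exp(x)


# ---------------------------------------------------------------------------
# the sampler


def run_mcmc(
    dataset: CohortDataset,
    config: MCMCConfig | None = None,
    seed: int = 0,
) -> PosteriorChains:
    """Fit the hierarchical model by adaptive Metropolis-within-Gibbs.

    Returns chains of ``config.n_samples`` retained draws taken after
    ``config.burn_in`` adaptation sweeps (one sweep updates every individual
    log-parameter and every group hyperparameter once).  Fully reproducible
    from ``seed``.
    """
    config = config or MCMCConfig()
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 202)))

    rat_ids = dataset.rat_ids
    if not rat_ids:
        raise InitializationError("dataset contains no rats")
    strains = dataset.strains
    strain_of = {r: dataset.strain_of(r) for r in rat_ids}

    sessions: dict[str, list[_SessionData]] = {}
    durations: dict[str, float] = {}
    for r in rat_ids:
        recs = dataset.sessions_for(r)
        sessions[r] = [
            _prepare_session(rec, config.include_first_latency, config.censor_tail)
            for rec in recs
        ]
        durations[r] = recs[0].session_duration
    two_sessions = any(len(s) > 1 for s in sessions.values())
    if two_sessions and not all(len(s) == 2 for s in sessions.values()):
        raise InitializationError("all rats must have the same set of sessions")

    # ---- starting point -----------------------------------------------------
    v: dict[str, np.ndarray] = {}
    c: dict[str, np.ndarray] = {}
    for r in rat_ids:
        th = _heuristic_init(sessions[r], durations[r])
        if config.init_optimize:
            th = _refine_init(th, sessions[r], config.init_maxiter)
        # the refractory period must undercut every session's shortest interval
        min_int = min(s.min_interval for s in sessions[r])
        th[6] = min(th[6], 0.9 * min_int)
        x = np.clip(np.log(th), _LOG_LOW + 1e-9, _LOG_HIGH - 1e-9)
        th = np.exp(x)
        # nudge into the constraint region if the heuristic landed outside
        if not _theta_ok(th):
            th[7] = min(th[7], 0.5 * th[2])
            th[1] = max(th[1], 2.0 * th[2])
            th[5] = max(th[5], th[4])
            x = np.clip(np.log(th), _LOG_LOW + 1e-9, _LOG_HIGH - 1e-9)
        v[r] = x
        if two_sessions:
            c[r] = np.zeros(8)  # coefficients start at 1 (log 0)
        if not math.isfinite(
            _rat_loglik(np.exp(v[r]), np.exp(c[r]) if two_sessions else None, sessions[r])
        ):
            raise InitializationError(
                f"no finite starting likelihood for rat {r!r} "
                "(check refractory period vs. shortest interval)"
            )

    def _init_hypers(values: dict[str, np.ndarray], low, high):
        mu, sg = {}, {}
        for s in strains:
            arr = np.array([values[r] for r in rat_ids if strain_of[r] == s])
            mu[s] = np.clip(arr.mean(axis=0), low + 1e-9, high - 1e-9)
            sg[s] = np.clip(arr.std(axis=0), 0.1, _SIGMA_MAX)
        return mu, sg

    mu, sigma = _init_hypers(v, _LOG_LOW, _LOG_HIGH)
    cmu, csigma = (_init_hypers(c, _CLOG_LOW, _CLOG_HIGH) if two_sessions else (None, None))

    # cached per-rat log-likelihoods
    loglik = {
        r: _rat_loglik(np.exp(v[r]), np.exp(c[r]) if two_sessions else None, sessions[r])
        for r in rat_ids
    }

    # ---- storage ------------------------------------------------------------
    n_keep = config.n_samples
    total_sweeps = config.burn_in + n_keep
    keep_v = {r: np.empty((n_keep, 8)) for r in rat_ids}
    keep_c = {r: np.empty((n_keep, 8)) for r in rat_ids} if two_sessions else None
    keep_mu = {s: np.empty((n_keep, 8)) for s in strains}
    keep_sg = {s: np.empty((n_keep, 8)) for s in strains}
    keep_cmu = {s: np.empty((n_keep, 8)) for s in strains} if two_sessions else None
    keep_csg = {s: np.empty((n_keep, 8)) for s in strains} if two_sessions else None

    step_v = {r: np.full(8, config.initial_step) for r in rat_ids}
    step_c = {r: np.full(8, config.initial_step) for r in rat_ids} if two_sessions else None
    acc_v = {r: np.zeros(8) for r in rat_ids}
    acc_c = {r: np.zeros(8) for r in rat_ids} if two_sessions else None
    n_prop = 0

    members = {s: [r for r in rat_ids if strain_of[r] == s] for s in strains}

    def _update_individual(r, vec, steps, accs, is_coeff, adapt_scale):
        hmu = (cmu if is_coeff else mu)[strain_of[r]]
        hsg = (csigma if is_coeff else sigma)[strain_of[r]]
        low = _CLOG_LOW if is_coeff else _LOG_LOW
        high = _CLOG_HIGH if is_coeff else _LOG_HIGH
        base = v[r]
        coeff = c[r] if two_sessions else None
        for j in range(8):
            old = vec[j]
            new = old + steps[j] * rng.standard_normal()
            accepted = False
            if low[j] <= new <= high[j]:
                vec[j] = new
                ll = _rat_loglik(
                    np.exp(base), np.exp(coeff) if two_sessions else None, sessions[r]
                )
                if math.isfinite(ll):
                    dprior = ((old - hmu[j]) ** 2 - (new - hmu[j]) ** 2) / (2 * hsg[j] ** 2)
                    if math.log(rng.random()) < (ll - loglik[r]) + dprior:
                        loglik[r] = ll
                        accepted = True
                if not accepted:
                    vec[j] = old
            if adapt_scale > 0:
                steps[j] *= math.exp(adapt_scale * ((1.0 if accepted else 0.0) - config.target_accept))
            accs[j] += accepted

    def _update_hypers(values, hmu, hsg, low, high):
        for s in strains:
            arr = np.array([values[r] for r in members[s]])
            n = arr.shape[0]
            for j in range(8):
                vals = arr[:, j]
                m = hmu[s][j]
                # sigma | mu: inverse-square-root-Gamma, truncated to (0, 5]
                S = float(np.sum((vals - m) ** 2))
                if n >= 2 and S > 0:
                    shape = 0.5 * (n - 1)
                    for _ in range(100):
                        u = rng.gamma(shape, 2.0 / S)
                        if u > 0 and u ** -0.5 <= _SIGMA_MAX:
                            hsg[s][j] = u ** -0.5
                            break
                else:
                    # single-rat strain: random-walk step on log sigma with the
                    # flat-on-sigma prior's Jacobian
                    sg = hsg[s][j]
                    prop = sg * math.exp(0.3 * rng.standard_normal())
                    if 0 < prop <= _SIGMA_MAX:
                        lp_new = (1 - n) * math.log(prop) - S / (2 * prop ** 2)
                        lp_old = (1 - n) * math.log(sg) - S / (2 * sg ** 2)
                        if math.log(rng.random()) < lp_new - lp_old:
                            hsg[s][j] = prop
                # mu | sigma: Gaussian around the sample mean, truncated
                sd = hsg[s][j] / math.sqrt(n)
                mean = float(vals.mean())
                for _ in range(100):
                    m_new = rng.normal(mean, sd)
                    if low[j] <= m_new <= high[j]:
                        hmu[s][j] = m_new
                        break

    for sweep in range(total_sweeps):
        adapting = sweep < config.burn_in
        adapt_scale = min(0.25, 2.0 / math.sqrt(sweep + 10.0)) if adapting else 0.0
        for r in rat_ids:
            _update_individual(r, v[r], step_v[r], acc_v[r], False, adapt_scale)
            if two_sessions:
                _update_individual(r, c[r], step_c[r], acc_c[r], True, adapt_scale)
        _update_hypers(v, mu, sigma, _LOG_LOW, _LOG_HIGH)
        if two_sessions:
            _update_hypers(c, cmu, csigma, _CLOG_LOW, _CLOG_HIGH)
        n_prop += 1
        if not adapting:
            k = sweep - config.burn_in
            for r in rat_ids:
                keep_v[r][k] = v[r]
                if two_sessions:
                    keep_c[r][k] = c[r]
            for s in strains:
                keep_mu[s][k] = mu[s]
                keep_sg[s][k] = sigma[s]
                if two_sessions:
                    keep_cmu[s][k] = cmu[s]
                    keep_csg[s][k] = csigma[s]

    acceptance = {
        "individual": {r: (acc_v[r] / n_prop).round(4).tolist() for r in rat_ids},
    }
    if two_sessions:
        acceptance["coefficients"] = {
            r: (acc_c[r] / n_prop).round(4).tolist() for r in rat_ids
        }

    return PosteriorChains(
        param_names=PARAM_NAMES,
        coeff_names=COEFF_NAMES if two_sessions else None,
        rat_ids=rat_ids,
        rat_strains=strain_of,
        individual=keep_v,
        individual_coeffs=keep_c,
        group_mu=keep_mu,
        group_sigma=keep_sg,
        coeff_mu=keep_cmu,
        coeff_sigma=keep_csg,
        config=config.as_dict(),
        seed=int(seed),
        acceptance=acceptance,
    )


# ---------------------------------------------------------------------------
# summaries and effects


def cap_half_life(value: float, cap: float = HALF_LIFE_CAP) -> HalfLife:
    """Truncate a half-life summary at the reporting cap (minutes)."""
    if value < 0:
        raise ConstraintViolation(f"half-life must be nonnegative, got {value}")
    return HalfLife(min(value, cap), value > cap)


#: Parameter labels in conventional reporting order, with units.
REPORT_PARAMS = (
    ("L0", "responses", None),
    ("w0", "min^-1", None),
    ("b0", "min^-1", None),
    ("H_L", "min", "gamma"),
    ("H_w", "min", "alpha"),
    ("H_b", "min", "beta"),
    ("delta_seconds", "s", "delta"),
    ("omega", "min^-1", None),
)


@dataclass
class PosteriorSummary:
    """Linear-scale medians and central 95% credible intervals.

    ``group`` summarizes the back-transformed group medians per strain;
    ``individual`` summarizes each rat's own parameters; ``coefficients``
    (two-session fits only) summarizes group recovery coefficients.
    Half-lives are in minutes (truncated at the reporting cap, flagged) and
    the refractory period is in seconds.
    """

    group: pd.DataFrame
    individual: pd.DataFrame
    coefficients: pd.DataFrame | None = None


def _quantile_row(samples: np.ndarray) -> tuple[float, float, float]:
    lo, med, hi = np.quantile(samples, [0.025, 0.5, 0.975])
    return float(med), float(lo), float(hi)


def summarize_posterior(chains: PosteriorChains) -> PosteriorSummary:
    """Tabulate posterior medians and 95% CIs on the reporting scale."""
    group_rows = []
    for strain in chains.strains:
        for label, units, _src in REPORT_PARAMS:
            samples = chains.group_linear_samples(strain, label)
            med, lo, hi = _quantile_row(samples)
            capped = False
            if label in ("H_L", "H_w", "H_b"):
                h_med, h_lo, h_hi = (cap_half_life(x) for x in (med, lo, hi))
                capped = h_med.capped
                med, lo, hi = h_med.minutes, h_lo.minutes, h_hi.minutes
            group_rows.append(
                dict(strain=strain, parameter=label, units=units,
                     median=med, ci_low=lo, ci_high=hi, capped=capped)
            )
    indiv_rows = []
    for rat in chains.rat_ids:
        arr = chains.individual[rat]
        for label, units, src in REPORT_PARAMS:
            j = _IDX[src or label]
            samples = np.exp(arr[:, j])
            if label in ("H_L", "H_w", "H_b"):
                samples = np.minimum(LN2 / samples, HALF_LIFE_CAP)
            elif label == "delta_seconds":
                samples = samples * 60.0
            med, lo, hi = _quantile_row(samples)
            indiv_rows.append(
                dict(rat_id=rat, strain=chains.rat_strains[rat], parameter=label,
                     units=units, median=med, ci_low=lo, ci_high=hi)
            )
    coeff_df = None
    if chains.coeff_mu is not None:
        rows = []
        for strain in chains.strains:
            for k, name in enumerate(chains.coeff_names):
                med, lo, hi = _quantile_row(np.exp(chains.coeff_mu[strain][:, k]))
                rows.append(
                    dict(strain=strain, parameter=name,
                         median=med, ci_low=lo, ci_high=hi)
                )
        coeff_df = pd.DataFrame(rows)
    return PosteriorSummary(
        group=pd.DataFrame(group_rows),
        individual=pd.DataFrame(indiv_rows),
        coefficients=coeff_df,
    )


@dataclass(frozen=True)
class EffectSize:
    """Posterior strain contrast for one parameter.

    ``log_samples`` holds draws of E_x = mu_x(strain_a) - mu_x(strain_b);
    on the linear scale exp(E_x) is the ratio of group medians.  The
    difference is flagged significant when the 95% CI of E_x excludes 0
    (equivalently the ratio CI excludes 1).
    """

    parameter: str
    strain_a: str
    strain_b: str
    log_samples: np.ndarray
    ratio_median: float
    ratio_ci: tuple
    significant: bool


def strain_effect(
    chains: PosteriorChains,
    parameter: str,
    strain_a: str | None = None,
    strain_b: str | None = None,
) -> EffectSize:
    """Effect size of strain on one parameter (difference of group log-means)."""
    if strain_a is None or strain_b is None:
        if len(chains.strains) != 2:
            raise ValueError("specify strain_a and strain_b explicitly")
        strain_a, strain_b = chains.strains
    la = np.log(chains.group_linear_samples(strain_a, parameter))
    lb = np.log(chains.group_linear_samples(strain_b, parameter))
    e = la - lb
    lo, med, hi = np.quantile(e, [0.025, 0.5, 0.975])
    return EffectSize(
        parameter=parameter,
        strain_a=strain_a,
        strain_b=strain_b,
        log_samples=e,
        ratio_median=float(math.exp(med)),
        ratio_ci=(float(math.exp(lo)), float(math.exp(hi))),
        significant=bool(lo > 0 or hi < 0),
    )


# ---------------------------------------------------------------------------
# degenerate-submodel sampler (kernel check against a conjugate posterior)


def fit_shifted_exponential_mcmc(
    irts: np.ndarray,
    delta: float,
    n_samples: int = 5000,
    burn_in: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Sample the rate of a shifted-exponential IRT model by the same
    adaptive random-walk kernel the hierarchical sampler uses.

    With the bout probability fixed at zero the mixture collapses to a
    single exponential beyond ``delta``; under a flat prior on log rate the
    posterior of the rate is the Gamma(n, sum(irt - delta)) distribution,
    which makes this a closed-form check of the Metropolis kernel.
    """
    irts = np.asarray(irts, dtype=float)
    if np.any(irts < delta):
        raise ConstraintViolation("IRT shorter than the refractory period")
    s = float(np.sum(irts - delta))
    n = irts.size
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 77)))
    x = math.log(n / s)  # log rate, started at the MLE
    step = 0.5
    out = np.empty(n_samples)

    def logpost(lx):
        b = math.exp(lx)
        return n * lx - b * s  # flat prior on log rate

    lp = logpost(x)
    for i in range(burn_in + n_samples):
        prop = x + step * rng.standard_normal()
        lp_new = logpost(prop)
        accepted = math.log(rng.random()) < lp_new - lp
        if accepted:
            x, lp = prop, lp_new
        if i < burn_in:
            step *= math.exp(min(0.25, 2.0 / math.sqrt(i + 10.0)) * ((1.0 if accepted else 0.0) - 0.44))
        else:
            out[i - burn_in] = math.exp(x)
    return out
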
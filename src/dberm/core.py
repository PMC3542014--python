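"""Deterministic mathematics of the dynamic bi-exponential refractory model.

The model (DBERM) describes free-operant responding as the output of two
Poisson processes: a slow *bout-initiation* process with rate ``b`` and a
fast *within-bout* process with rate ``w``, separated by an absolute
refractory period ``delta`` (the minimum time between two responses).  The
mean bout length ``L`` (responses per bout beyond the initiating response)
determines the probability ``p = L / (1 + L)`` that an inter-response time
(IRT) is drawn from the fast process.  During extinction, ``L``, ``w`` and
``b`` decay exponentially from their baselines toward an asymptote
(``omega`` for the two rates, zero for ``L``).

All quantities here use a single canonical time unit, the **minute**:
rates are per minute and ``delta`` is stored in minutes.  ``delta`` is
conventionally reported in seconds at I/O boundaries; the conversion is
exactly ``seconds / 60``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

__all__ = [
    "HALF_LIFE_CAP",
    "LN2",
    "ConstraintViolation",
    "DBERMParams",
    "DynamicState",
    "HalfLife",
    "RecoveryCoefficients",
    "apply_recovery",
    "bout_length_crossing_time",
    "bout_stay_probability",
    "evaluate_dynamics",
    "expected_irt",
    "half_life_to_rate",
    "irt_log_density",
    "irt_log_survival",
    "rate_to_half_life",
    "top_speed",
    "validate_constraints",
]

LN2 = math.log(2.0)

#: Cap on reported half-lives, in minutes (roughly ten years).  Decay rates
#: indistinguishable from zero imply unbounded half-lives, which in turn can
#: make the posterior of a decay rate improper; capping bounds the estimand.
HALF_LIFE_CAP = 5.6e6


class ConstraintViolation(ValueError):
    """Raised when model parameters or inputs violate DBERM's constraints."""


@dataclass(frozen=True)
class DBERMParams:
    """One subject's eight model parameters for a single extinction session.

    Parameters
    ----------
    L0 : float
        Mean bout length at session start (responses beyond the bout
        initiator; dimensionless count).
    w0 : float
        Within-bout response rate at session start (min^-1).
    b0 : float
        Bout-initiation rate at session start (min^-1).
    gamma, alpha, beta : float
        Exponential decay rates of ``L_t``, ``w_t`` and ``b_t`` (min^-1).
    delta : float
        Refractory period in **minutes** (reported in seconds at I/O
        boundaries).
    omega : float
        Asymptotic response rate toward which both ``w_t`` and ``b_t``
        decay (min^-1); a candidate operant level of the response.

    Constraints: ``w0 > b0 >= omega >= 0``, ``beta >= alpha >= 0``,
    ``gamma >= 0``, ``L0 >= 0``, ``delta > 0``.
    """

    L0: float
    w0: float
    b0: float
    gamma: float
    alpha: float
    beta: float
    delta: float
    omega: float

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_half_lives(
        cls,
        L0: float,
        w0: float,
        b0: float,
        H_L: float,
        H_w: float,
        H_b: float,
        delta_seconds: float,
        omega: float,
    ) -> "DBERMParams":
        """Build parameters from half-lives (minutes) and delta in seconds.

        Half-lives are the conventional reporting scale for the decay rates,
        ``H = ln(2) / rate``; infinite half-life means no decay.
        """
        return cls(
            L0=L0,
            w0=w0,
            b0=b0,
            gamma=half_life_to_rate(H_L),
            alpha=half_life_to_rate(H_w),
            beta=half_life_to_rate(H_b),
            delta=delta_seconds / 60.0,
            omega=omega,
        )

    @property
    def delta_seconds(self) -> float:
        return self.delta * 60.0

    def half_lives(self, cap: float = HALF_LIFE_CAP) -> "dict[str, HalfLife]":
        return {
            "H_L": rate_to_half_life(self.gamma, cap),
            "H_w": rate_to_half_life(self.alpha, cap),
            "H_b": rate_to_half_life(self.beta, cap),
        }

    def validate(self) -> "DBERMParams":
        violations = validate_constraints(self)
        if violations:
            raise ConstraintViolation("; ".join(violations))
        return self


@dataclass(frozen=True)
class DynamicState:
    """Model parameters evaluated at a moment ``t`` of a session.

    ``p_t = L_t / (1 + L_t)`` is the probability that the IRT beginning at
    ``t`` is generated by the within-bout (fast) process.
    """

    t: float
    L_t: float
    w_t: float
    b_t: float
    p_t: float


@dataclass(frozen=True)
class RecoveryCoefficients:
    """Multiplicative between-session change factors, one per parameter.

    A coefficient ``C(x)`` relates a parameter's value in the second
    extinction session to its value in the first: ``x_2 = C(x) * x_1``.
    Coefficients for the three decay processes act on the *half-lives*
    (``H_L``, ``H_w``, ``H_b``), so the session-2 decay rate is
    ``rate / C(H)``.  A coefficient of 1 means no change between sessions.
    """

    c_L0: float = 1.0
    c_w0: float = 1.0
    c_b0: float = 1.0
    c_HL: float = 1.0
    c_Hw: float = 1.0
    c_Hb: float = 1.0
    c_delta: float = 1.0
    c_omega: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.c_L0, self.c_w0, self.c_b0, self.c_HL,
             self.c_Hw, self.c_Hb, self.c_delta, self.c_omega]
        )

    def validate(self) -> "RecoveryCoefficients":
        vals = self.as_array()
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ConstraintViolation(
                "recovery coefficients must be strictly positive and finite"
            )
        return self


@dataclass(frozen=True)
class HalfLife:
    """A half-life in minutes, with a flag marking truncation at the cap."""

    minutes: float
    capped: bool


# ---------------------------------------------------------------------------
# constraint checking


def validate_constraints(params: DBERMParams) -> list[str]:
    """Return a list of human-readable constraint violations (empty if valid).

    The inequalities checked are the model's ordering constraints:
    ``w0 > b0 >= omega >= 0`` and ``beta >= alpha >= 0``, plus positivity
    of ``delta`` and nonnegativity of ``L0`` and ``gamma``, and finiteness
    of everything.
    """
    p = params
    out: list[str] = []
    fields = {
        "L0": p.L0, "w0": p.w0, "b0": p.b0, "gamma": p.gamma,
        "alpha": p.alpha, "beta": p.beta, "delta": p.delta, "omega": p.omega,
    }
    for name, v in fields.items():
        if not math.isfinite(v):
            out.append(f"{name} is not finite")
    if out:
        return out
    if not p.w0 > p.b0:
        out.append("w0 > b0 violated (within-bout rate must exceed initiation rate)")
    if not p.b0 >= p.omega:
        out.append("b0 >= omega violated")
    if not p.omega >= 0:
        out.append("omega >= 0 violated")
    if not p.beta >= p.alpha:
        out.append("beta >= alpha violated")
    if not p.alpha >= 0:
        out.append("alpha >= 0 violated")
    if not p.gamma >= 0:
        out.append("gamma >= 0 violated")
    if not p.L0 >= 0:
        out.append("L0 >= 0 violated")
    if not p.delta > 0:
        out.append("delta > 0 violated")
    return out


# ---------------------------------------------------------------------------
# dynamics


def bout_stay_probability(L: float) -> float:
    """Probability of remaining in a bout given mean bout length ``L``.

    ``p = L / (1 + L)``, in ``[0, 1)``.
    """
    if L < 0:
        raise ConstraintViolation(f"bout length must be nonnegative, got {L}")
    return L / (1.0 + L)


def evaluate_dynamics(params: DBERMParams, t: float) -> DynamicState:
    """Evaluate the time-varying parameters at session time ``t`` (minutes).

    ``L_t = L0 e^{-gamma t}``; ``w_t`` and ``b_t`` decay exponentially from
    their baselines toward the shared asymptote ``omega``.
    """
    params.validate()
    if t < 0:
        raise ConstraintViolation(f"session time must be nonnegative, got {t}")
    L_t = params.L0 * math.exp(-params.gamma * t)
    w_t = (params.w0 - params.omega) * math.exp(-params.alpha * t) + params.omega
    b_t = (params.b0 - params.omega) * math.exp(-params.beta * t) + params.omega
    return DynamicState(t=t, L_t=L_t, w_t=w_t, b_t=b_t, p_t=bout_stay_probability(L_t))


def bout_length_crossing_time(params_a: DBERMParams, params_b: DBERMParams) -> float:
    """Time at which two subjects' mean bout lengths ``L_t`` are equal.

    Solves ``L0_a e^{-gamma_a t} = L0_b e^{-gamma_b t}`` in closed form:
    ``t = ln(L0_a / L0_b) / (gamma_a - gamma_b)``.  Raises if the curves are
    parallel (equal decay rates) or either baseline is zero.
    """
    if params_a.L0 <= 0 or params_b.L0 <= 0:
        raise ConstraintViolation("crossing time requires strictly positive baselines")
    if params_a.gamma == params_b.gamma:
        raise ConstraintViolation("equal decay rates: curves never cross (or coincide)")
    return math.log(params_a.L0 / params_b.L0) / (params_a.gamma - params_b.gamma)


# ---------------------------------------------------------------------------
# the IRT mixture density


def _mixture_log_terms(state: DynamicState, delta: float, tau: np.ndarray):
    if not state.w_t > state.b_t:
        raise ConstraintViolation(
            f"mixture components not ordered: w_t={state.w_t} <= b_t={state.b_t}"
        )
    if delta <= 0:
        raise ConstraintViolation(f"delta must be positive, got {delta}")
    p = state.p_t
    u = tau - delta
    with np.errstate(divide="ignore"):
        log_p = np.log(p) if p > 0 else -np.inf
        log_q = math.log1p(-p)
        a = log_p + math.log(state.w_t) - state.w_t * u
        b = log_q + math.log(state.b_t) - state.b_t * u
    return a, b


def irt_log_density(state: DynamicState, delta: float, tau) -> np.ndarray | float:
    """Log-density (per minute) of an IRT of duration ``tau`` starting at ``t``.

    The density is zero (log-density ``-inf``) for ``tau < delta``; on the
    support ``tau >= delta`` it is the two-component exponential mixture
    ``p w e^{-w(tau-delta)} + (1-p) b e^{-b(tau-delta)}`` with parameters
    frozen at the IRT's start time.  Mixing is done in log space
    (log-sum-exp), so very long IRTs yield large negative but finite values.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ConstraintViolation("IRT durations must be nonnegative")
    a, b = _mixture_log_terms(state, delta, tau_arr)
    out = np.logaddexp(a, b)
    out = np.where(tau_arr < delta, -np.inf, out)
    return float(out) if np.isscalar(tau) or tau_arr.ndim == 0 else out


def irt_log_survival(state: DynamicState, delta: float, tau) -> np.ndarray | float:
    """Log-survival ``log Pr(IRT > tau)`` of the mixture frozen at ``t``.

    Equals 0 for ``tau <= delta`` (every IRT exceeds the refractory period).
    Used for right-censoring the interval from the last response to the end
    of the session.
    """
    tau_arr = np.asarray(tau, dtype=float)
    a, b = _mixture_log_terms(state, delta, tau_arr)
    # survival terms drop the rate factors of the density terms
    a = a - math.log(state.w_t) if state.p_t > 0 else a
    b = b - math.log(state.b_t)
    out = np.logaddexp(a, b)
    out = np.where(tau_arr <= delta, 0.0, out)
    return float(out) if np.isscalar(tau) or tau_arr.ndim == 0 else out


def expected_irt(state: DynamicState, delta: float) -> float:
    """Mean IRT of the mixture with parameters frozen at ``t``:
    ``delta + p/w + (1-p)/b``."""
    p = state.p_t
    if (p > 0 and state.w_t <= 0) or (p < 1 and state.b_t <= 0):
        raise ConstraintViolation("expected IRT undefined for zero component rates")
    mean = delta
    if p > 0:
        mean += p / state.w_t
    if p < 1:
        mean += (1.0 - p) / state.b_t
    return mean


def top_speed(delta: float) -> float:
    """Maximum instantaneous response rate (min^-1) implied by the
    refractory period: ``1 / delta`` with ``delta`` in minutes."""
    if delta <= 0:
        raise ConstraintViolation(f"delta must be positive, got {delta}")
    return 1.0 / delta


# ---------------------------------------------------------------------------
# half-life transforms


def rate_to_half_life(rate: float, cap: float = HALF_LIFE_CAP) -> HalfLife:
    """Convert a decay rate (min^-1) to a half-life ``ln(2)/rate`` in minutes,
    truncated at ``cap`` (a zero rate maps to the cap itself)."""
    if rate < 0:
        raise ConstraintViolation(f"decay rate must be nonnegative, got {rate}")
    if rate == 0:
        return HalfLife(cap, True)
    h = LN2 / rate
    if h > cap:
        return HalfLife(cap, True)
    return HalfLife(h, False)


def half_life_to_rate(half_life: float) -> float:
    """Inverse of :func:`rate_to_half_life` for uncapped values;
    an infinite half-life maps to rate 0."""
    if half_life <= 0:
        raise ConstraintViolation(f"half-life must be positive, got {half_life}")
    if math.isinf(half_life):
        return 0.0
    return LN2 / half_life


# ---------------------------------------------------------------------------
# between-session recovery


def apply_recovery(
    params_ext1: DBERMParams, coeffs: RecoveryCoefficients
) -> DBERMParams:
    """Parameters for the second extinction session given the first's.

    Baselines, ``delta`` and ``omega`` are multiplied directly; the decay
    rates are adjusted through their half-lives (``rate / C(H)``), so a
    coefficient above 1 means slower decay in the second session.  The
    result is validated against the model's ordering constraints.
    """
    params_ext1.validate()
    coeffs.validate()
    out = replace(
        params_ext1,
        L0=params_ext1.L0 * coeffs.c_L0,
        w0=params_ext1.w0 * coeffs.c_w0,
        b0=params_ext1.b0 * coeffs.c_b0,
        gamma=params_ext1.gamma / coeffs.c_HL,
        alpha=params_ext1.alpha / coeffs.c_Hw,
        beta=params_ext1.beta / coeffs.c_Hb,
        delta=params_ext1.delta * coeffs.c_delta,
        omega=params_ext1.omega * coeffs.c_omega,
    )
    violations = validate_constraints(out)
    if violations:
        raise ConstraintViolation(
            "recovery produced invalid session-2 parameters: " + "; ".join(violations)
        )
    return out
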
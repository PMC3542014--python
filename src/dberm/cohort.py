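"""Synthetic extinction cohorts generated from the bout-mixture model.

A session is simulated by the model's own Monte-Carlo recipe, iterated from
session time 0: (1) evaluate the dynamic parameters at the start of the
pending IRT, (2) sample the bout state (within-bout with probability
``p_t``), (3) sample an exponential pause at the state's rate, (4) add the
refractory period ``delta``.  The session truncates the process: the final
response whose time would exceed the session duration is discarded.

Cohorts emulate a two-strain extinction experiment: each strain is a
log-normal population over the eight model parameters (and, for a second
session, over the eight recovery coefficients); each rat draws its own
parameter vector and is simulated for one or two 65-min sessions.

Randomness is fully deterministic given a root seed: each (strain, rat,
session) gets its own counter-derived stream, so enlarging a cohort does not
reshuffle existing rats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    ConstraintViolation,
    DBERMParams,
    RecoveryCoefficients,
    apply_recovery,
    evaluate_dynamics,
    validate_constraints,
)

__all__ = [
    "PARAM_NAMES",
    "COEFF_NAMES",
    "SHR_REFERENCE",
    "WKY_REFERENCE",
    "CohortDataset",
    "GroupDistribution",
    "SessionRecord",
    "sample_individual_params",
    "sample_recovery_coefficients",
    "simulate_cohort",
    "simulate_rat",
    "simulate_session",
]

#: Canonical parameter order used throughout (natural scale).
PARAM_NAMES = ("L0", "w0", "b0", "gamma", "alpha", "beta", "delta", "omega")

#: Canonical recovery-coefficient order (matching the half-life convention).
COEFF_NAMES = ("c_L0", "c_w0", "c_b0", "c_HL", "c_Hw", "c_Hb", "c_delta", "c_omega")

#: Reference group-median parameter sets for the two strains, typical of
#: extinction after variable-interval training: the spontaneously
#: hypertensive rat (SHR, an ADHD model) initiates bouts ~3x as often as the
#: Wistar-Kyoto control (WKY) and shows essentially no within-session decay
#: of bout length, while WKY bout length halves in about 20 minutes.
SHR_REFERENCE = DBERMParams.from_half_lives(
    L0=0.91, w0=253.71, b0=42.74, H_L=2794.48, H_w=42.94, H_b=7.77,
    delta_seconds=0.11, omega=2.37,
)
WKY_REFERENCE = DBERMParams.from_half_lives(
    L0=2.81, w0=175.68, b0=14.70, H_L=19.37, H_w=21.28, H_b=4.69,
    delta_seconds=0.12, omega=1.64,
)


@dataclass(frozen=True)
class SessionRecord:
    """One rat-session: ordered response times since lever extension.

    Times are in minutes, strictly increasing, within
    ``[0, session_duration]``.  ``first_latency_included`` records whether
    the latency from lever extension to the first response was generated by
    (and should be modeled by) the same mixture process.
    """

    rat_id: str
    strain: str
    session_index: int
    response_times: np.ndarray
    session_duration: float = 65.0
    first_latency_included: bool = True

    def __post_init__(self):
        times = np.asarray(self.response_times, dtype=float)
        object.__setattr__(self, "response_times", times)
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError(
                    f"{self.rat_id} session {self.session_index}: "
                    "response times must be strictly increasing"
                )
            if times[0] < 0 or times[-1] > self.session_duration:
                raise ValueError(
                    f"{self.rat_id} session {self.session_index}: "
                    f"response times outside [0, {self.session_duration}] min"
                )

    @property
    def n_responses(self) -> int:
        return int(self.response_times.size)

    def irts(self) -> np.ndarray:
        """Inter-response times (minutes) between consecutive responses."""
        return np.diff(self.response_times)

    def irt_start_times(self) -> np.ndarray:
        """Session time at which each IRT begins (the earlier response)."""
        return self.response_times[:-1]


@dataclass(frozen=True)
class GroupDistribution:
    """A strain's log-normal population over model parameters.

    ``median_params`` holds the linear-scale population medians (the
    exponentiated log-scale locations); ``sdlog`` is the log-scale standard
    deviation, either one value shared by all parameters or a per-parameter
    mapping.  ``median_coeffs``/``coeff_sdlog`` play the same role for the
    between-session recovery coefficients and may be omitted for
    single-session designs.
    """

    strain: str
    median_params: DBERMParams
    sdlog: float | Mapping[str, float] = 0.2
    median_coeffs: RecoveryCoefficients | None = None
    coeff_sdlog: float | Mapping[str, float] = 0.2

    def sdlog_for(self, name: str) -> float:
        src = self.coeff_sdlog if name.startswith("c_") else self.sdlog
        if isinstance(src, Mapping):
            return float(src[name])
        return float(src)

    def __post_init__(self):
        self.median_params.validate()
        for name in PARAM_NAMES:
            if self.sdlog_for(name) < 0:
                raise ValueError(f"negative log-scale SD for {name}")


@dataclass
class CohortDataset:
    """A collection of simulated (or loaded) rat-sessions with provenance.

    ``metadata`` carries everything needed to regenerate a simulated cohort
    byte-identically: the root seed, the generative group specifications and
    each rat's true parameters.  Loaded real data has empty metadata.
    """

    records: list[SessionRecord]
    metadata: dict = field(default_factory=dict)

    @property
    def strains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.strain, None)
        return list(seen)

    @property
    def rat_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.rat_id, None)
        return list(seen)

    def sessions_for(self, rat_id: str) -> list[SessionRecord]:
        recs = [r for r in self.records if r.rat_id == rat_id]
        return sorted(recs, key=lambda r: r.session_index)

    def strain_of(self, rat_id: str) -> str:
        for r in self.records:
            if r.rat_id == rat_id:
                return r.strain
        raise KeyError(rat_id)

    @property
    def n_irts(self) -> int:
        return sum(max(r.n_responses - 1, 0) for r in self.records)


# ---------------------------------------------------------------------------
# RNG plumbing


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream for a (strain, rat, session, ...) identity."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), *key)))


# ---------------------------------------------------------------------------
# session and rat simulation


def simulate_session(
    params: DBERMParams,
    duration: float = 65.0,
    seed: int | np.random.Generator = 0,
    rat_id: str = "rat",
    strain: str = "NA",
    session_index: int = 1,
) -> SessionRecord:
    """Simulate one extinction session's response times.

    Iterates the four-step Monte-Carlo recipe from ``t = 0`` (the latency to
    the first response is drawn from the same mixture) and stops at the first
    response that would fall beyond ``duration``, which is discarded.
    """
    params.validate()
    if duration <= 0:
        raise ConstraintViolation(f"duration must be positive, got {duration}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times: list[float] = []
    t = 0.0
    while True:
        state = evaluate_dynamics(params, t)
        in_bout = rng.random() < state.p_t
        rate = state.w_t if in_bout else state.b_t
        tau = rng.exponential(1.0 / rate) + params.delta
        t = t + tau
        if t > duration:
            break
        times.append(t)
    return SessionRecord(
        rat_id=rat_id,
        strain=strain,
        session_index=session_index,
        response_times=np.array(times),
        session_duration=duration,
    )


def simulate_rat(
    params_ext1: DBERMParams,
    coeffs: RecoveryCoefficients | None = None,
    durations: Sequence[float] = (65.0, 65.0),
    seed: int = 0,
    rat_id: str = "rat",
    strain: str = "NA",
) -> list[SessionRecord]:
    """Simulate a rat's extinction sessions.

    The first session uses ``params_ext1``; each later session applies the
    recovery coefficients cumulatively and restarts the session clock at 0.
    With ``coeffs=None`` only one session is simulated.
    """
    if coeffs is None and len(durations) > 1:
        raise ConstraintViolation("recovery coefficients required for multiple sessions")
    out = []
    params = params_ext1
    for i, dur in enumerate(durations, start=1):
        if i > 1:
            params = apply_recovery(params, coeffs)
        out.append(
            simulate_session(
                params, dur, seed=_stream(seed, i),
                rat_id=rat_id, strain=strain, session_index=i,
            )
        )
    return out


# ---------------------------------------------------------------------------
# population sampling


def _lognormal_draw(median: float, sdlog: float, rng: np.random.Generator) -> float:
    if median < 0:
        raise ConstraintViolation("log-normal medians must be nonnegative")
    if median == 0:
        return 0.0
    return float(math.exp(math.log(median) + sdlog * rng.standard_normal()))


def sample_individual_params(
    group: GroupDistribution,
    seed: int | np.random.Generator = 0,
    max_retries: int = 1000,
) -> DBERMParams:
    """Draw one rat's parameter vector from the strain's log-normal population.

    Each parameter is an independent exponentiated-Gaussian draw; the joint
    draw is rejected and retried until the ordering constraints hold
    (rejections are rare for realistic dispersions).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = group.median_params
    medians = {name: getattr(m, name) for name in PARAM_NAMES}
    for _ in range(max_retries):
        cand = DBERMParams(
            **{n: _lognormal_draw(medians[n], group.sdlog_for(n), rng) for n in PARAM_NAMES}
        )
        if not validate_constraints(cand):
            return cand
    raise ConstraintViolation(
        f"group specification for strain {group.strain!r} is incompatible with "
        f"the model constraints ({max_retries} rejected draws)"
    )


def sample_recovery_coefficients(
    group: GroupDistribution,
    params_ext1: DBERMParams,
    seed: int | np.random.Generator = 0,
    max_retries: int = 1000,
) -> RecoveryCoefficients:
    """Draw a rat's recovery coefficients, retrying until the implied
    session-2 parameters satisfy the ordering constraints."""
    if group.median_coeffs is None:
        raise ConstraintViolation(
            f"group {group.strain!r} declares no recovery-coefficient population"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mc = group.median_coeffs
    for _ in range(max_retries):
        cand = RecoveryCoefficients(
            **{n: _lognormal_draw(getattr(mc, n), group.sdlog_for(n), rng) for n in COEFF_NAMES}
        )
        try:
            apply_recovery(params_ext1, cand)
        except ConstraintViolation:
            continue
        return cand
    raise ConstraintViolation(
        f"recovery-coefficient population for strain {group.strain!r} is "
        f"incompatible with the constraints ({max_retries} rejected draws)"
    )


def simulate_cohort(
    groups: Sequence[GroupDistribution],
    n_rats_per_strain: int = 6,
    n_sessions: int = 2,
    duration: float = 65.0,
    seed: int = 0,
) -> CohortDataset:
    """Simulate a full multi-strain extinction cohort.

    Each rat's true parameters (and, for two-session designs, recovery
    coefficients) are drawn from its strain's population and stored in the
    dataset metadata for parameter-recovery experiments.
    """
    if n_rats_per_strain < 1:
        raise ConstraintViolation("need at least one rat per strain")
    if n_sessions not in (1, 2):
        raise ConstraintViolation("only one or two extinction sessions are supported")
    records: list[SessionRecord] = []
    truth: dict[str, dict] = {}
    for gi, group in enumerate(groups):
        for ri in range(n_rats_per_strain):
            rat_id = f"{group.strain}_{ri + 1}"
            prng = _stream(seed, gi, ri, 0)
            params = sample_individual_params(group, prng)
            coeffs = None
            if n_sessions == 2:
                coeffs = sample_recovery_coefficients(group, params, prng)
            # session streams keyed by identity, not draw order
            for si in range(1, n_sessions + 1):
                p = params if si == 1 else apply_recovery(params, coeffs)
                records.append(
                    simulate_session(
                        p, duration, seed=_stream(seed, gi, ri, si),
                        rat_id=rat_id, strain=group.strain, session_index=si,
                    )
                )
            truth[rat_id] = {
                "params": params,
                "coeffs": coeffs,
            }
    return CohortDataset(
        records=records,
        metadata={
            "seed": int(seed),
            "groups": list(groups),
            "true_params": truth,
            "n_sessions": n_sessions,
            "duration": float(duration),
        },
    )
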
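"""Posterior-predictive checks and parameter-recovery experiments.

Two observable summaries drive the model checks: binned response rates
(responses per minute over eight equal bins of a 65-min session, the same
summary a conventional extinction ANOVA consumes) and log-survivor curves
of inter-response times within selected session windows, whose
"broken-stick" shape is the signature of the two-process bout mixture.

Posterior-predictive curves are built by replaying the Monte-Carlo session
simulator under joint posterior draws, exactly the generative recipe the
model assumes, and summarizing the replicates by pointwise medians and
central 95% bands.

The recovery harness closes the loop: simulate a cohort from known group
parameters, fit the hierarchy, and ask whether the credible intervals
envelop the generative values.  Preconfigured scenarios probe whether a
strain with short bouts and no bout-length decay could mask a real decay:
its generative bout-length half-life is swapped for the other strain's
(optionally with baseline bout length cut to a third) and the fit must
still recover the swapped value without bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    COEFF_NAMES,
    PARAM_NAMES,
    CohortDataset,
    GroupDistribution,
    SessionRecord,
    SHR_REFERENCE,
    WKY_REFERENCE,
    simulate_cohort,
    simulate_session,
)
from .core import DBERMParams, HALF_LIFE_CAP, LN2
from .inference import MCMCConfig, PosteriorChains, run_mcmc

__all__ = [
    "BinnedRates",
    "DEFAULT_WINDOWS",
    "SurvivorCurve",
    "binned_response_rates",
    "hl_swap_scenarios",
    "log_survivor_curve",
    "posterior_predictive_rates",
    "ppc_survivor_envelope",
    "recovery_experiment",
]

#: Session windows conventionally used for IRT-distribution checks:
#: the first 10 min and the last 15 min of each session.
DEFAULT_WINDOWS = ((0.0, 10.0), (50.0, 65.0))


@dataclass(frozen=True)
class BinnedRates:
    """Response rates over consecutive equal time bins of one session."""

    rat_id: str
    session_index: int
    rates: np.ndarray       # responses per minute, one entry per bin
    midpoints: np.ndarray   # bin midpoints in minutes
    bin_width: float

    @property
    def total_responses(self) -> float:
        return float(self.rates.sum() * self.bin_width)


def binned_response_rates(record: SessionRecord, n_bins: int = 8) -> BinnedRates:
    """Bin a session into ``n_bins`` equal intervals and convert counts to
    rates (the default eight bins of a 65-min session are 8.125 min wide).

    Bins are half-open ``[k*w, (k+1)*w)`` with the final bin closed, so the
    rates reconstruct the total response count exactly.
    """
    dur = record.session_duration
    edges = np.linspace(0.0, dur, n_bins + 1)
    t = record.response_times
    if t.size and (t.min() < 0 or t.max() > dur):
        raise ValueError("responses outside the session window")
    counts, _ = np.histogram(t, bins=edges)
    width = dur / n_bins
    return BinnedRates(
        rat_id=record.rat_id,
        session_index=record.session_index,
        rates=counts / width,
        midpoints=(edges[:-1] + edges[1:]) / 2.0,
        bin_width=width,
    )


@dataclass(frozen=True)
class SurvivorCurve:
    """Empirical survivor function of IRT durations within a window.

    ``proportion[i]`` is the fraction of IRTs strictly exceeding
    ``durations[i]``; plotted against duration on a log-probability axis
    a bi-exponential mixture produces a convex broken-stick shape.
    """

    durations: np.ndarray
    proportion: np.ndarray
    window: tuple
    n_irts: int
    empty: bool = False

    def log_proportion(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.proportion)


def log_survivor_curve(
    record: SessionRecord, window: tuple[float, float] = (0.0, 10.0)
) -> SurvivorCurve:
    """Survivor curve of the IRTs whose *start times* fall in ``window``.

    An IRT belongs to the window of the response that opens it.  An empty
    window yields an empty, flagged curve rather than an error.
    """
    lo, hi = window
    if not (0.0 <= lo < hi <= record.session_duration):
        raise ValueError(f"window {window} outside session [0, {record.session_duration}]")
    starts = record.irt_start_times()
    irts = record.irts()
    sel = (starts >= lo) & (starts < hi)
    durs = np.sort(irts[sel])
    n = durs.size
    if n == 0:
        return SurvivorCurve(np.empty(0), np.empty(0), window, 0, empty=True)
    # proportion strictly exceeding each sorted duration
    surv = 1.0 - np.searchsorted(durs, durs, side="right") / n
    return SurvivorCurve(durs, surv, window, int(n), empty=False)


# ---------------------------------------------------------------------------
# posterior-predictive machinery


def _params_from_log_row(row: np.ndarray) -> DBERMParams:
    vals = np.exp(row)
    return DBERMParams(**{n: float(vals[i]) for i, n in enumerate(PARAM_NAMES)})


def _draw_indices(chains: PosteriorChains, n_draws: int, rng) -> np.ndarray:
    n = chains.n_samples
    if n_draws <= n:
        # without replacement, matching the size of the retained chain
        return rng.choice(n, size=n_draws, replace=False)
    return rng.choice(n, size=n_draws, replace=True)


def posterior_predictive_rates(
    chains: PosteriorChains,
    dataset: CohortDataset,
    n_draws: int = 10000,
    n_bins: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Predicted binned response rates per strain and session.

    For each of ``n_draws`` joint posterior draws (sampled without
    replacement when possible) every rat's sessions are re-simulated from
    that draw's individual parameters and binned; per strain-session the
    replicate mean rate over rats is summarized by its mean and central 95%
    band across draws.  Returns a tidy frame with one row per
    (strain, session, bin).
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 31)))
    idx = _draw_indices(chains, n_draws, rng)
    sessions = sorted({r.session_index for r in dataset.records})
    strains = dataset.strains
    acc: dict[tuple, list] = {(s, si): [] for s in strains for si in sessions}
    durations = {
        (r.strain, r.session_index): r.session_duration for r in dataset.records
    }
    for k in idx:
        per_key: dict[tuple, list] = {key: [] for key in acc}
        for rat in chains.rat_ids:
            strain = chains.rat_strains[rat]
            params = _params_from_log_row(chains.individual[rat][k])
            for si in sessions:
                p = params
                if si > 1:
                    coeff_row = np.exp(chains.individual_coeffs[rat][k])
                    from .inference import _apply_recovery_vec  # natural-scale helper

                    th = np.array([getattr(params, n) for n in PARAM_NAMES])
                    p = DBERMParams(
                        **dict(zip(PARAM_NAMES, _apply_recovery_vec(th, coeff_row)))
                    )
                dur = durations.get((strain, si), 65.0)
                rec = simulate_session(p, dur, seed=rng, session_index=si)
                per_key[(strain, si)].append(binned_response_rates(rec, n_bins).rates)
        for key, rows in per_key.items():
            if rows:
                acc[key].append(np.mean(rows, axis=0))
    out_rows = []
    for (strain, si), draws in acc.items():
        arr = np.array(draws)
        dur = durations.get((strain, si), 65.0)
        width = dur / n_bins
        mids = (np.arange(n_bins) + 0.5) * width
        mean = arr.mean(axis=0)
        lo, hi = np.percentile(arr, [2.5, 97.5], axis=0)
        obs = np.array(
            [
                binned_response_rates(r, n_bins).rates
                for r in dataset.records
                if r.strain == strain and r.session_index == si
            ]
        ).mean(axis=0)
        for j in range(n_bins):
            out_rows.append(
                dict(strain=strain, session=si, bin=j + 1, midpoint=mids[j],
                     predicted_mean=mean[j], predicted_low=lo[j],
                     predicted_high=hi[j], observed_mean=obs[j])
            )
    return pd.DataFrame(out_rows)


def ppc_survivor_envelope(
    chains: PosteriorChains,
    dataset: CohortDataset,
    rat_id: str,
    session_index: int = 1,
    window: tuple[float, float] = (0.0, 10.0),
    n_draws: int = 500,
    n_grid: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Median and central 95% band of predicted log-survivor curves for one
    rat-session window, with the observed curve interpolated onto the same
    duration grid.

    Each posterior draw re-simulates the session and contributes one
    survivor curve; curves are evaluated as right-continuous step functions
    on a fixed grid before pointwise percentiles are taken.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 32)))
    idx = _draw_indices(chains, n_draws, rng)
    recs = dataset.sessions_for(rat_id)
    rec = next(r for r in recs if r.session_index == session_index)
    obs = log_survivor_curve(rec, window)
    max_dur = float(obs.durations.max()) if obs.n_irts else 1.0
    grid = np.linspace(0.0, max_dur * 1.05, n_grid)
    curves = []
    for k in idx:
        params = _params_from_log_row(chains.individual[rat_id][k])
        if session_index > 1:
            from .inference import _apply_recovery_vec

            th = np.array([getattr(params, n) for n in PARAM_NAMES])
            coeff_row = np.exp(chains.individual_coeffs[rat_id][k])
            params = DBERMParams(
                **dict(zip(PARAM_NAMES, _apply_recovery_vec(th, coeff_row)))
            )
        sim = simulate_session(
            params, rec.session_duration, seed=rng, session_index=session_index
        )
        sc = log_survivor_curve(sim, window)
        if sc.empty:
            curves.append(np.full(n_grid, np.nan))
            continue
        # survivor proportion at each grid point (step function)
        surv = 1.0 - np.searchsorted(sc.durations, grid, side="right") / sc.n_irts
        curves.append(surv)
    arr = np.array(curves)
    med = np.nanmedian(arr, axis=0)
    lo, hi = np.nanpercentile(arr, [2.5, 97.5], axis=0)
    obs_surv = (
        1.0 - np.searchsorted(obs.durations, grid, side="right") / obs.n_irts
        if obs.n_irts
        else np.full(n_grid, np.nan)
    )
    return pd.DataFrame(
        dict(duration=grid, observed=obs_surv, predicted_median=med,
             predicted_low=lo, predicted_high=hi)
    )


# ---------------------------------------------------------------------------
# parameter-recovery harness


def _override_groups(
    groups: Sequence[GroupDistribution],
    overrides: Mapping[str, Mapping[str, tuple]] | None,
) -> list[GroupDistribution]:
    """Apply generative overrides: per strain, per parameter, either
    ``("swap", other_strain)`` to source the median from another strain or
    ``("scale", factor)`` to multiply it."""
    if not overrides:
        return list(groups)
    by_strain = {g.strain: g for g in groups}
    out = []
    for g in groups:
        rules = overrides.get(g.strain)
        if not rules:
            out.append(g)
            continue
        values = {n: getattr(g.median_params, n) for n in PARAM_NAMES}
        for pname, (kind, arg) in rules.items():
            if pname not in values:
                raise KeyError(f"unknown parameter {pname!r} in override")
            if kind == "swap":
                values[pname] = getattr(by_strain[arg].median_params, pname)
            elif kind == "scale":
                values[pname] = values[pname] * float(arg)
            else:
                raise ValueError(f"unknown override kind {kind!r}")
        out.append(dc_replace(g, median_params=DBERMParams(**values)))
    return out


def hl_swap_scenarios() -> dict[str, tuple[list[GroupDistribution], dict]]:
    """The two preconfigured bias-probe scenarios.

    ``hl_swap``: simulate the short-bout strain (SHR-like reference) with
    its bout-length half-life swapped for the control strain's fast-decaying
    value.  ``hl_swap_l0_third``: additionally cut the generative baseline
    bout length to one third.  In both, an unbiased fit should envelop the
    swapped generative values.
    """
    base = [
        GroupDistribution(strain="SHR", median_params=SHR_REFERENCE, sdlog=0.2),
        GroupDistribution(strain="WKY", median_params=WKY_REFERENCE, sdlog=0.2),
    ]
    return {
        "hl_swap": (base, {"SHR": {"gamma": ("swap", "WKY")}}),
        "hl_swap_l0_third": (
            base,
            {"SHR": {"gamma": ("swap", "WKY"), "L0": ("scale", 1.0 / 3.0)}},
        ),
    }


def recovery_experiment(
    groups: Sequence[GroupDistribution],
    overrides: Mapping[str, Mapping[str, tuple]] | None = None,
    n_reps: int = 20,
    n_rats_per_strain: int = 6,
    n_sessions: int = 1,
    duration: float = 65.0,
    fit_config: MCMCConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate-fit-compare replicates and report coverage and bias.

    Each replicate simulates a cohort from the (possibly overridden)
    generative groups, fits the hierarchy, and compares the posterior group
    medians with the generative medians: a parameter is *covered* when the
    generative value lies inside the 95% CI, and bias is the posterior
    median minus the generative value on the log scale.  Returns one row
    per (replicate, strain, parameter).
    """
    fit_config = fit_config or MCMCConfig(n_samples=2000, burn_in=1000)
    gen_groups = _override_groups(groups, overrides)
    rows = []
    for rep in range(n_reps):
        cohort = simulate_cohort(
            gen_groups,
            n_rats_per_strain=n_rats_per_strain,
            n_sessions=n_sessions,
            duration=duration,
            seed=int(np.random.SeedSequence((int(seed), 41, rep)).generate_state(1)[0] % (2**31)),
        )
        chains = run_mcmc(
            cohort, fit_config,
            seed=int(np.random.SeedSequence((int(seed), 42, rep)).generate_state(1)[0] % (2**31)),
        )
        for g in gen_groups:
            for j, pname in enumerate(PARAM_NAMES):
                gen_val = getattr(g.median_params, pname)
                samples = chains.group_linear_samples(g.strain, pname)
                lo, med, hi = np.quantile(samples, [0.025, 0.5, 0.975])
                rows.append(
                    dict(
                        replicate=rep,
                        strain=g.strain,
                        parameter=pname,
                        generative=gen_val,
                        median=float(med),
                        ci_low=float(lo),
                        ci_high=float(hi),
                        covered=bool(lo <= gen_val <= hi),
                        log_bias=float(math.log(med) - math.log(gen_val))
                        if gen_val > 0
                        else np.nan,
                    )
                )
    return pd.DataFrame(rows)
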
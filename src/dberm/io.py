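"""Data interchange: event-time files, truth sidecars, chain stores, configs.

The on-disk event format is deliberately minimal: UTF-8 comma-separated
text, one row per lever press, columns ``rat_id, strain, session_index,
response_time_s``.  Timestamps are **seconds since lever extension**
(natural for operant hardware and for the conventional reporting unit of
the refractory period) and are converted to the package's canonical
minutes on read by exact division by 60.  Leading ``# key = value`` lines
carry session metadata (duration, declared strain labels, flags).

Simulated cohorts can also write a JSON *truth sidecar* holding the seed,
the generative group specification and every rat's true parameters, which
parameter-recovery experiments read back.

MCMC chains persist to HDF5 with the resolved sampler config and seed
embedded as attributes, so any fit can be traced to its inputs.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .cohort import (
    COEFF_NAMES,
    PARAM_NAMES,
    CohortDataset,
    GroupDistribution,
    SessionRecord,
)
from .core import DBERMParams, RecoveryCoefficients
from .inference import PosteriorChains

__all__ = [
    "EventFileError",
    "RunConfig",
    "read_events",
    "write_events",
    "read_truth",
    "write_truth",
    "load_chains",
    "save_chains",
]


@dataclass
class RunConfig:
    """Structured pipeline configuration, validated before any computation.

    Collects the sampler settings, likelihood conventions, simulation
    design, and posterior-predictive windows in one YAML-serializable
    object; :meth:`validate` enforces every owning module's preconditions
    up front so a bad field fails fast with its name.
    """

    n_samples: int = 20100
    burn_in: int = 5000
    seed: int = 0
    include_first_latency: bool = True
    censor_tail: bool = True
    n_rats_per_strain: int = 6
    n_sessions: int = 2
    duration: float = 65.0
    sdlog: float = 0.2
    ppc_windows: list = field(default_factory=lambda: [[0.0, 10.0], [50.0, 65.0]])
    ppc_draws: int = 10000

    def validate(self) -> "RunConfig":
        if self.n_samples < 1 or self.burn_in < 0:
            raise ValueError("n_samples must be >= 1 and burn_in >= 0")
        if self.n_rats_per_strain < 1:
            raise ValueError("n_rats_per_strain must be >= 1")
        if self.n_sessions not in (1, 2):
            raise ValueError("n_sessions must be 1 or 2")
        if self.duration <= 0:
            raise ValueError("duration must be positive (minutes)")
        if self.sdlog < 0:
            raise ValueError("sdlog must be nonnegative")
        if self.ppc_draws < 1:
            raise ValueError("ppc_draws must be >= 1")
        for w in self.ppc_windows:
            lo, hi = w
            if not (0 <= lo < hi <= self.duration):
                raise ValueError(f"ppc window {w} outside [0, {self.duration}]")
        return self

    def mcmc_config(self):
        from .inference import MCMCConfig

        return MCMCConfig(
            n_samples=self.n_samples,
            burn_in=self.burn_in,
            include_first_latency=self.include_first_latency,
            censor_tail=self.censor_tail,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw).validate()

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8"
        )


class EventFileError(ValueError):
    """Raised for malformed event-time files, with row context."""


_COLUMNS = ["rat_id", "strain", "session_index", "response_time_s"]


def write_events(dataset: CohortDataset, path) -> None:
    """Write a cohort to the canonical event-time CSV.

    Rows are ordered by (strain, rat, session, time) and times are printed
    in seconds with microsecond precision, so output is deterministic and
    round-trips byte-identically through :func:`read_events`.
    """
    rows = []
    durations = {}
    strains = []
    for rec in sorted(
        dataset.records, key=lambda r: (r.strain, r.rat_id, r.session_index)
    ):
        if rec.strain not in strains:
            strains.append(rec.strain)
        durations[(rec.rat_id, rec.session_index)] = rec.session_duration
        for t in rec.response_times:
            rows.append((rec.rat_id, rec.strain, rec.session_index, t * 60.0))
    dur_set = sorted({d for d in durations.values()})
    if len(dur_set) > 1:
        raise EventFileError("mixed session durations are not representable")
    duration_min = dur_set[0] if dur_set else 65.0
    first_latency = all(r.first_latency_included for r in dataset.records)
    buf = _io.StringIO()
    buf.write(f"# session_duration_min = {duration_min:g}\n")
    buf.write(f"# strains = {','.join(strains)}\n")
    buf.write(f"# first_latency_included = {str(first_latency).lower()}\n")
    buf.write(",".join(_COLUMNS) + "\n")
    for rat, strain, si, ts in rows:
        buf.write(f"{rat},{strain},{si},{ts:.6f}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_events(path) -> CohortDataset:
    """Parse and validate an event-time CSV into a cohort.

    Rejects (with row numbers) non-increasing or duplicate timestamps
    within a rat-session, times outside the declared session, and strain
    labels not among the declared set.  No silent coercion.
    """
    text = Path(path).read_text(encoding="utf-8")
    meta: dict[str, str] = {}
    data_lines = []
    header_row = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#"):
            if "=" in line:
                k, _, val = line[1:].partition("=")
                meta[k.strip()] = val.strip()
            continue
        if not line.strip():
            continue
        if header_row is None:
            header_row = line
            if [c.strip() for c in line.split(",")] != _COLUMNS:
                raise EventFileError(
                    f"line {lineno}: expected header {','.join(_COLUMNS)!r}, got {line!r}"
                )
            continue
        data_lines.append((lineno, line))
    if header_row is None:
        raise EventFileError("no header row found")
    duration_min = float(meta.get("session_duration_min", 65.0))
    declared = meta.get("strains")
    declared_set = [s.strip() for s in declared.split(",")] if declared else None
    first_latency = meta.get("first_latency_included", "true").lower() != "false"

    grouped: dict[tuple, list] = {}
    order: list[tuple] = []
    for lineno, line in data_lines:
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 4:
            raise EventFileError(f"line {lineno}: expected 4 fields, got {len(parts)}")
        rat, strain, si_s, t_s = parts
        if declared_set is not None and strain not in declared_set:
            raise EventFileError(f"line {lineno}: unknown strain {strain!r}")
        try:
            si = int(si_s)
            t = float(t_s)
        except ValueError as exc:
            raise EventFileError(f"line {lineno}: {exc}") from exc
        if t < 0 or t > duration_min * 60.0:
            raise EventFileError(
                f"line {lineno}: time {t} s outside session "
                f"[0, {duration_min * 60.0:g}] s"
            )
        key = (strain, rat, si)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        prev = grouped[key]
        if prev and t <= prev[-1][1]:
            raise EventFileError(
                f"line {lineno}: non-increasing time {t} s for rat {rat!r} "
                f"session {si}"
            )
        prev.append((lineno, t))

    records = []
    for strain, rat, si in order:
        times_min = np.array([t for _, t in grouped[(strain, rat, si)]]) / 60.0
        records.append(
            SessionRecord(
                rat_id=rat,
                strain=strain,
                session_index=si,
                response_times=times_min,
                session_duration=duration_min,
                first_latency_included=first_latency,
            )
        )
    return CohortDataset(records=records, metadata={"source": str(path)})


# ---------------------------------------------------------------------------
# truth sidecar (generative parameters for recovery experiments)


def write_truth(dataset: CohortDataset, path) -> None:
    """Write a simulated cohort's generative metadata as JSON."""
    md = dataset.metadata
    out = {
        "seed": md.get("seed"),
        "n_sessions": md.get("n_sessions"),
        "duration": md.get("duration"),
        "groups": [
            {
                "strain": g.strain,
                "median_params": {n: getattr(g.median_params, n) for n in PARAM_NAMES},
                "sdlog": g.sdlog if not isinstance(g.sdlog, dict) else dict(g.sdlog),
                "median_coeffs": (
                    {n: getattr(g.median_coeffs, n) for n in COEFF_NAMES}
                    if g.median_coeffs is not None
                    else None
                ),
                "coeff_sdlog": g.coeff_sdlog,
            }
            for g in md.get("groups", [])
        ],
        "true_params": {
            rat: {
                "params": {n: getattr(d["params"], n) for n in PARAM_NAMES},
                "coeffs": (
                    {n: getattr(d["coeffs"], n) for n in COEFF_NAMES}
                    if d.get("coeffs") is not None
                    else None
                ),
            }
            for rat, d in md.get("true_params", {}).items()
        },
    }
    Path(path).write_text(json.dumps(out, indent=1, sort_keys=True), encoding="utf-8")


def read_truth(path) -> dict:
    """Read a truth sidecar back into domain objects."""
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    out = dict(raw)
    out["groups"] = [
        GroupDistribution(
            strain=g["strain"],
            median_params=DBERMParams(**g["median_params"]),
            sdlog=g["sdlog"],
            median_coeffs=(
                RecoveryCoefficients(**g["median_coeffs"])
                if g.get("median_coeffs")
                else None
            ),
            coeff_sdlog=g.get("coeff_sdlog", 0.2),
        )
        for g in raw.get("groups", [])
    ]
    out["true_params"] = {
        rat: {
            "params": DBERMParams(**d["params"]),
            "coeffs": RecoveryCoefficients(**d["coeffs"]) if d.get("coeffs") else None,
        }
        for rat, d in raw.get("true_params", {}).items()
    }
    return out


# ---------------------------------------------------------------------------
# chain store


def save_chains(chains: PosteriorChains, path) -> None:
    """Persist posterior chains to HDF5 with embedded config and seed."""
    from . import __version__

    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(chains.config)
        f.attrs["package_version"] = __version__
        f.attrs["seed"] = chains.seed
        f.attrs["param_names"] = json.dumps(list(chains.param_names))
        f.attrs["coeff_names"] = json.dumps(
            list(chains.coeff_names) if chains.coeff_names else None
        )
        f.attrs["rat_strains"] = json.dumps(chains.rat_strains)
        f.attrs["acceptance"] = json.dumps(chains.acceptance)
        gi = f.create_group("individual")
        for rat, arr in chains.individual.items():
            gi.create_dataset(rat, data=arr)
        if chains.individual_coeffs is not None:
            gc = f.create_group("individual_coeffs")
            for rat, arr in chains.individual_coeffs.items():
                gc.create_dataset(rat, data=arr)
        for name, d in (
            ("group_mu", chains.group_mu),
            ("group_sigma", chains.group_sigma),
            ("coeff_mu", chains.coeff_mu),
            ("coeff_sigma", chains.coeff_sigma),
        ):
            if d is None:
                continue
            g = f.create_group(name)
            for strain, arr in d.items():
                g.create_dataset(strain, data=arr)


def load_chains(path) -> PosteriorChains:
    """Load chains previously written by :func:`save_chains`."""
    with h5py.File(path, "r") as f:
        coeff_names = json.loads(f.attrs["coeff_names"])
        rat_strains = json.loads(f.attrs["rat_strains"])
        individual = {rat: f["individual"][rat][...] for rat in f["individual"]}
        individual_coeffs = None
        if "individual_coeffs" in f:
            individual_coeffs = {
                rat: f["individual_coeffs"][rat][...] for rat in f["individual_coeffs"]
            }

        def _grp(name):
            if name not in f:
                return None
            return {s: f[name][s][...] for s in f[name]}

        return PosteriorChains(
            param_names=tuple(json.loads(f.attrs["param_names"])),
            coeff_names=tuple(coeff_names) if coeff_names else None,
            rat_ids=list(individual),
            rat_strains=rat_strains,
            individual=individual,
            individual_coeffs=individual_coeffs,
            group_mu=_grp("group_mu"),
            group_sigma=_grp("group_sigma"),
            coeff_mu=_grp("coeff_mu"),
            coeff_sigma=_grp("coeff_sigma"),
            config=json.loads(f.attrs["config"]),
            seed=int(f.attrs["seed"]),
            acceptance=json.loads(f.attrs["acceptance"]),
        )
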
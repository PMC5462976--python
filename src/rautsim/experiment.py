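"""Monte-Carlo evaluation of recording procedures over a prevalence grid.

For each prevalence ``pi`` on a grid the mean interim time is derived from
the chosen mean event duration, ``replicates`` equilibrium streams are
simulated, and every requested procedure is applied *to the same stream*
within a replicate so that procedures are compared on a common behavior
stream.  Per (procedure, pi) cell the estimators are summarized by their
mean and sample SD, with +/-1 and +/-2 SD bands, and by relative bias
against both the generating prevalence and the continuous-recording mean.

Replicate substreams are seeded deterministically from
(seed, grid index, replicate index), so any cell can be reproduced in
isolation and the whole experiment is bit-reproducible for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .arp_core import (
    StreamParameters,
    derive_incidence_per_minute,
    derive_interim_time,
    interval_ratio,
    simulate_stream,
)
from .estimators import estimate_set, relative_bias
from .recorders import record, record_continuous

__all__ = [
    "DEFAULT_PI_GRID",
    "ExperimentConfig",
    "ExperimentResult",
    "ReplicateSummary",
    "summarize_replicates",
    "run_experiment",
    "info_table",
    "RESULT_COLUMNS",
]

#: Prevalence grid 0.05 .. 0.95 in steps of 0.05 (19 points).
DEFAULT_PI_GRID: tuple[float, ...] = tuple(np.round(np.arange(1, 20) * 0.05, 2))

ALL_PROCEDURES = ("continuous", "MTS", "PIR", "WIR")

RESULT_COLUMNS = [
    "procedure", "pi", "lam", "incidence_per_min", "n_intervals",
    "mean_cont_prev", "mean_cont_count", "mean_theta", "mean_pf",
    "mean_prev_raw", "sd_prev_raw", "mean_prev_corrected",
    "sd_prev_corrected", "mean_freq_formula", "n_undefined",
    "rel_bias_raw_vs_param", "rel_bias_corrected_vs_param",
    "rel_bias_raw_vs_cont",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings of one simulation experiment.

    Attributes
    ----------
    mu : float
        Mean event duration, seconds.
    tau : float
        Recording interval length, seconds.
    session_length_min : float
        Session length in minutes (typical designs: 10, 20, 30, 60).
    replicates : int
        Sessions simulated per grid point (1, 100 and 1000 are the usual
        choices; any count >= 1 is allowed).
    pi_grid : tuple of float
        Prevalence values evaluated.
    procedures : tuple of str
        Subset of {"continuous", "MTS", "PIR", "WIR"}.
    seed : int
        Root seed for all randomness.
    """

    mu: float
    tau: float
    session_length_min: float = 20.0
    replicates: int = 100
    pi_grid: tuple[float, ...] = DEFAULT_PI_GRID
    procedures: tuple[str, ...] = ALL_PROCEDURES
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mu > 0 or not self.tau > 0 or not self.session_length_min > 0:
            raise ValueError("mu, tau and session length must be positive")
        if self.tau > self.session_length_s:
            raise ValueError(
                f"interval length {self.tau} s exceeds session "
                f"length {self.session_length_s} s"
            )
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.pi_grid:
            raise ValueError("prevalence grid must be non-empty")
        for p in self.pi_grid:
            if not 0 < p < 1:
                raise ValueError(f"grid prevalence must be in (0, 1), got {p}")
        procs = tuple(
            p if p == "continuous" else p.upper() for p in self.procedures
        )
        for p in procs:
            if p not in ALL_PROCEDURES:
                raise ValueError(f"unknown procedure {p!r}")
        if not procs:
            raise ValueError("at least one procedure is required")
        object.__setattr__(self, "procedures", procs)
        object.__setattr__(self, "pi_grid", tuple(float(p) for p in self.pi_grid))

    @property
    def session_length_s(self) -> float:
        return self.session_length_min * 60.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key in ("pi_grid", "procedures"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean, sample SD and +/-1/+/-2 SD bands of one estimator over replicates.

    NaN inputs (undefined estimates) are excluded and counted; with fewer
    than two usable values the SD and bands are absent (None).
    """

    mean: float
    sd: float | None
    band1: tuple[float, float] | None
    band2: tuple[float, float] | None
    n_used: int
    n_excluded: int

    @property
    def empty(self) -> bool:
        return self.n_used == 0


def summarize_replicates(values) -> ReplicateSummary:
    """Summarize replicate-level estimates; see :class:`ReplicateSummary`."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 1:
        raise ValueError("at least one value is required")
    good = arr[~np.isnan(arr)]
    n_excl = int(arr.size - good.size)
    if good.size == 0:
        return ReplicateSummary(math.nan, None, None, None, 0, n_excl)
    mean = float(good.mean())
    if good.size < 2:
        return ReplicateSummary(mean, None, None, None, 1, n_excl)
    sd = float(good.std(ddof=1))
    return ReplicateSummary(
        mean, sd,
        (mean - sd, mean + sd), (mean - 2 * sd, mean + 2 * sd),
        int(good.size), n_excl,
    )


@dataclass(frozen=True)
class ExperimentResult:
    """Per (procedure, prevalence) summaries of one experiment."""

    config: ExperimentConfig
    table: pd.DataFrame = field(repr=False)

    def cell(self, procedure: str, pi: float) -> pd.Series:
        t = self.table
        proc = procedure if procedure == "continuous" else procedure.upper()
        sel = t[(t["procedure"] == proc) & (np.isclose(t["pi"], pi))]
        if sel.empty:
            raise KeyError(f"no cell for ({procedure}, {pi})")
        return sel.iloc[0]

    def bands(self, procedure: str, corrected: bool = False) -> pd.DataFrame | None:
        """+/-1 and +/-2 SD bands around the mean estimate, or None when
        replicates == 1 (no dispersion to show)."""
        if self.config.replicates < 2:
            return None
        proc = procedure if procedure == "continuous" else procedure.upper()
        t = self.table[self.table["procedure"] == proc]
        col = "prev_corrected" if corrected else "prev_raw"
        mean, sd = t[f"mean_{col}"], t[f"sd_{col}"]
        return pd.DataFrame({
            "pi": t["pi"].to_numpy(),
            "mean": mean.to_numpy(),
            "lo1": (mean - sd).to_numpy(), "hi1": (mean + sd).to_numpy(),
            "lo2": (mean - 2 * sd).to_numpy(), "hi2": (mean + 2 * sd).to_numpy(),
        })


def _substream(seed: int, i: int, j: int) -> np.random.Generator:
    # Deterministic per-(grid point, replicate) substream.
    return np.random.default_rng([seed, i, j])


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full grid: simulate, record, estimate and summarize."""
    L = config.session_length_s
    n_intervals = int(np.floor(L / config.tau + 1e-9))
    discontinuous = [p for p in config.procedures if p != "continuous"]
    rows = []

    for i, pi in enumerate(config.pi_grid):
        lam = derive_interim_time(config.mu, pi)
        params = StreamParameters(mu=config.mu, lam=lam, session_length=L)
        incidence = derive_incidence_per_minute(config.mu, lam)

        cont_prev = np.empty(config.replicates)
        cont_count = np.empty(config.replicates)
        per_proc: dict[str, dict[str, list]] = {
            p: {"theta": [], "pf": [], "raw": [], "corr": [], "freq": [],
                "rb_cont": []}
            for p in discontinuous
        }

        for j in range(config.replicates):
            rng = _substream(config.seed, i, j)
            stream = simulate_stream(params, rng)
            cont = record_continuous(stream)
            cont_prev[j] = cont.prevalence
            cont_count[j] = cont.frequency
            for p in discontinuous:
                est = estimate_set(record(stream, config.tau, p), cont, pi)
                d = per_proc[p]
                d["theta"].append(est.theta)
                d["pf"].append(est.pf)
                d["raw"].append(est.prev_raw)
                d["corr"].append(
                    est.prev_corrected if est.prev_corrected is not None else math.nan
                )
                d["freq"].append(
                    est.freq_formula if est.freq_formula is not None else math.nan
                )

        mean_cont_prev = float(cont_prev.mean())
        mean_cont_count = float(cont_count.mean())
        sd_cont = (
            float(cont_prev.std(ddof=1)) if config.replicates > 1 else math.nan
        )

        if "continuous" in config.procedures:
            rows.append({
                "procedure": "continuous", "pi": pi, "lam": lam,
                "incidence_per_min": incidence, "n_intervals": n_intervals,
                "mean_cont_prev": mean_cont_prev,
                "mean_cont_count": mean_cont_count,
                "mean_theta": math.nan, "mean_pf": math.nan,
                "mean_prev_raw": mean_cont_prev, "sd_prev_raw": sd_cont,
                "mean_prev_corrected": math.nan, "sd_prev_corrected": math.nan,
                "mean_freq_formula": math.nan, "n_undefined": 0,
                "rel_bias_raw_vs_param": relative_bias(mean_cont_prev, pi),
                "rel_bias_corrected_vs_param": math.nan,
                "rel_bias_raw_vs_cont": 0.0,
            })

        for p in discontinuous:
            d = per_proc[p]
            raw = summarize_replicates(d["raw"])
            corr = summarize_replicates(d["corr"])
            freq = summarize_replicates(d["freq"])
            rows.append({
                "procedure": p, "pi": pi, "lam": lam,
                "incidence_per_min": incidence, "n_intervals": n_intervals,
                "mean_cont_prev": mean_cont_prev,
                "mean_cont_count": mean_cont_count,
                "mean_theta": float(np.mean(d["theta"])),
                "mean_pf": float(np.mean(d["pf"])),
                "mean_prev_raw": raw.mean,
                "sd_prev_raw": raw.sd if raw.sd is not None else math.nan,
                "mean_prev_corrected": corr.mean,
                "sd_prev_corrected": corr.sd if corr.sd is not None else math.nan,
                "mean_freq_formula": freq.mean,
                "n_undefined": freq.n_excluded if p == "PIR" else 0,
                "rel_bias_raw_vs_param": relative_bias(raw.mean, pi),
                "rel_bias_corrected_vs_param": (
                    relative_bias(corr.mean, pi) if not corr.empty else math.nan
                ),
                "rel_bias_raw_vs_cont": (
                    relative_bias(raw.mean, mean_cont_prev)
                    if mean_cont_prev > 0 else math.nan
                ),
            })

    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return ExperimentResult(config=config, table=table)


def info_table(mu: float, tau: float, pi_grid=DEFAULT_PI_GRID) -> pd.DataFrame:
    """Derived quantities per grid prevalence: interim time and incidence.

    One row per prevalence with lam = mu*(1-pi)/pi and incidence
    60/(mu+lam) per minute; the tau/mu ratio is carried in
    ``DataFrame.attrs["tau_over_mu"]``.
    """
    if not len(pi_grid):
        raise ValueError("prevalence grid must be non-empty")
    rows = []
    for pi in pi_grid:
        lam = derive_interim_time(mu, pi)
        rows.append({
            "pi": float(pi), "lam": lam,
            "incidence_per_min": derive_incidence_per_minute(mu, lam),
        })
    df = pd.DataFrame(rows)
    df.attrs["tau_over_mu"] = interval_ratio(tau, mu)
    return df
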
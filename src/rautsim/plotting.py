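"""Static plots of experiment results.

The main display plots estimated prevalence (ordinate) against the
generating prevalence (abscissa): continuous-recording means, the
procedure's mean estimates with +/-1 and +/-2 SD bands, and the diagonal
of unbiased estimation.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .experiment import ExperimentResult

__all__ = ["plot_prevalence_estimates"]


def plot_prevalence_estimates(
    result: ExperimentResult,
    procedure: str,
    path,
    corrected: bool = False,
) -> None:
    """Save a prevalence-estimation plot for one discontinuous procedure."""
    proc = procedure.upper()
    t = result.table
    sub = t[t["procedure"] == proc]
    if sub.empty:
        raise ValueError(f"no results for procedure {procedure!r}")
    col = "mean_prev_corrected" if corrected else "mean_prev_raw"

    fig, ax = plt.subplots(figsize=(6.5, 6))
    ax.plot([0, 1], [0, 1], "k-", lw=1, label="unbiased")
    if "continuous" in result.config.procedures:
        cont = t[t["procedure"] == "continuous"]
        ax.plot(cont["pi"], cont["mean_prev_raw"], "o", color="green",
                ms=4, label="continuous")
    label = f"{proc} ({'corrected' if corrected else 'raw'})"
    ax.plot(sub["pi"], sub[col], "^", mfc="none", color="C1", label=label)
    bands = result.bands(proc, corrected=corrected)
    if bands is not None:
        ax.plot(bands["pi"], bands["lo1"], "--", color="gray", lw=0.8)
        ax.plot(bands["pi"], bands["hi1"], "--", color="gray", lw=0.8)
        ax.plot(bands["pi"], bands["lo2"], ":", color="gray", lw=0.8)
        ax.plot(bands["pi"], bands["hi2"], ":", color="gray", lw=0.8)
    cfg = result.config
    ax.set_xlabel("generating prevalence $\\pi$")
    ax.set_ylabel("estimated prevalence")
    ax.set_title(
        f"$\\mu$={cfg.mu} s, $\\tau$={cfg.tau} s, "
        f"{cfg.session_length_min:g} min, {cfg.replicates} replicates"
    )
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.05)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
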
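"""Basic diagnostic plots: observed-vs-fitted and npde QQ."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from .kinetics import evaluate_curve
from .population import NpdeReport, PopulationFitResult, UrineSeries

__all__ = ["plot_observed_vs_fitted", "plot_npde_qq"]


def plot_observed_vs_fitted(
    fit: PopulationFitResult, series: list[UrineSeries], path: str | Path
) -> None:
    """Scatter of observed against individually fitted ratios with the x=y line."""
    obs, pred = [], []
    for s in series:
        if s.animal_id not in fit.individual_params:
            continue
        mask = s.times_d > 0 if not fit.settings.include_t0 else np.ones(len(s.times_d), bool)
        obs.append(s.ratios[mask])
        pred.append(evaluate_curve(fit.individual_params[s.animal_id], s.times_d[mask]))
    obs, pred = np.concatenate(obs), np.concatenate(pred)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(pred, obs, "o", ms=4, alpha=0.7)
    lim = [0, max(obs.max(), pred.max()) * 1.05]
    ax.plot(lim, lim, "k-", lw=1)
    ax.set_xlabel("fitted Co:creatinine (mg/mg)")
    ax.set_ylabel("observed Co:creatinine (mg/mg)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_npde_qq(report: NpdeReport, path: str | Path) -> None:
    """Normal QQ plot of the pooled npde."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    stats.probplot(report.npde, dist="norm", plot=ax)
    ax.set_title("npde normal QQ")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
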
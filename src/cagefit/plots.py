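"""Publication-style figures for each pipeline stage (headless, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402
from scipy import stats  # noqa: E402

from . import doseresponse, popgen  # noqa: E402

__all__ = ["plot_trajectory", "plot_dose_mortality", "plot_copy_activity"]


def plot_trajectory(cages: pd.DataFrame, fit: popgen.FitnessParams, path: str | Path) -> None:
    """Observed per-cage R1 frequencies with the fitted model trajectory."""
    n_gen = int(cages["generation"].max())
    traj = popgen.simulate_trajectory(fit, n_gen)
    model_p1 = traj.larval[:, 0] + 0.5 * traj.larval[:, 1]
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, (cage, grp) in enumerate(cages.groupby("cage")):
        p1 = [
            popgen.allele_freq_from_counts(r.n_R1R1, r.n_R1R2, r.n_R2R2)
            for r in grp.itertuples()
        ]
        ax.plot(grp["generation"] + 0.05 * i, p1, "o", ms=4, alpha=0.7, label=str(cage))
    ax.plot(np.arange(1, n_gen + 1), model_p1, "r-", lw=2, label="model (ML fit)")
    ax.set_xlabel("generation")
    ax.set_ylabel("R1 allele frequency (larvae)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dose_mortality(bioassay: pd.DataFrame, path: str | Path) -> None:
    """Probit-transformed corrected mortality vs log10 dose, with fits and 95% bands."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for strain in bioassay["strain"].unique():
        fit = doseresponse.fit_probit(bioassay, strain)
        corr = doseresponse.abbott_correct(bioassay[bioassay["strain"] == strain])
        x = np.log10(corr["dose"])
        clipped = corr["p_corr"].clip(0.005, 0.995)
        pts = ax.plot(x, stats.norm.ppf(clipped), "o", ms=4, label=strain)
        grid = np.linspace(x.min(), x.max(), 100)
        pred = fit.intercept + fit.slope * grid
        X = np.column_stack([np.ones_like(grid), grid])
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov, X))
        color = pts[0].get_color()
        ax.plot(grid, pred, "-", color=color)
        ax.plot(grid, pred - 1.96 * se, ":", color=color, lw=0.8)
        ax.plot(grid, pred + 1.96 * se, ":", color=color, lw=0.8)
    ax.set_xlabel("log10 dose (µg/ml)")
    ax.set_ylabel("probit(corrected mortality)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_copy_activity(
    copy_per_individual: pd.DataFrame, activity: pd.DataFrame, path: str | Path
) -> None:
    """Two panels: per-strain copy-number ratios and enzyme activity."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    for ax, (df, col, ylabel) in zip(
        axes,
        [
            (copy_per_individual, "ratio", "ace-1 : ace-2 copy-number ratio"),
            (activity, "activity", "AChE1 activity (OD/min)"),
        ],
    ):
        strains = list(df["strain"].unique())
        data = [df.loc[df["strain"] == s, col] for s in strains]
        ax.boxplot(data, tick_labels=strains)
        for i, vals in enumerate(data, start=1):
            ax.plot(np.full(len(vals), i) + np.random.default_rng(0).uniform(-0.08, 0.08, len(vals)),
                    vals, "k.", ms=3, alpha=0.5)
        ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
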
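"""qPCR standard-curve copy-number quantification and the supporting linear models.

Gene copy number of the target locus (ace-1) is measured relative to a
single-copy reference locus (ace-2). Each locus has its own standard curve,
an ordinary least-squares fit of Cq against log10 of a tenfold dilution
series; per well, the relative quantity is the curve inversion

    q = 10 ** ((Cq - intercept) / slope),

technical replicates are averaged on the quantity scale, and the copy-number
estimate for an individual is q(ace-1) / q(ace-2). The amplification
efficiency implied by a curve is E = 10 ** (-1/slope) (E = 2 for perfect
doubling each cycle).

Two linear models support the assays: a one-way strain model for copy-number
ratios (with per-strain contrasts against a reference strain) and an additive
strain + sex + plate model for acetylcholinesterase activity. Strain effects
are tested by an F likelihood-ratio test of the full model against the model
without strain; heteroskedasticity (Breusch-Pagan) and residual normality
(Shapiro-Wilk) are reported as diagnostics, never acted on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

__all__ = [
    "StandardCurve",
    "CopyNumberResult",
    "LinearModelResult",
    "fit_standard_curve",
    "copy_number_ratio",
    "copy_number_lm",
    "activity_lm",
]

QPCR_COLUMNS = ("individual", "strain", "locus", "replicate", "cq")
CURVE_COLUMNS = ("locus", "log10_dilution", "cq")
ACTIVITY_COLUMNS = ("individual", "strain", "sex", "plate", "activity")

TARGET_LOCUS = "ace-1"
REFERENCE_LOCUS = "ace-2"


@dataclass(frozen=True)
class StandardCurve:
    """OLS calibration line Cq = intercept + slope * log10(relative concentration)."""

    locus: str
    slope: float
    intercept: float
    r2: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError(
                f"locus {self.locus!r}: standard-curve slope {self.slope} must be negative"
            )

    @property
    def efficiency(self) -> float:
        return 10 ** (-1.0 / self.slope)

    @property
    def efficiency_ok(self) -> bool:
        """Flag curves outside the plausible amplification range (1, 2.2]."""
        return 1.0 < self.efficiency <= 2.2

    def quantity(self, cq: np.ndarray) -> np.ndarray:
        """Invert the curve: relative quantity from Cq."""
        return 10 ** ((np.asarray(cq, dtype=float) - self.intercept) / self.slope)


@dataclass
class CopyNumberResult:
    """Per-individual ace-1:ace-2 ratios, per-strain summaries, excluded individuals."""

    per_individual: pd.DataFrame  # individual, strain, ratio
    per_strain: pd.DataFrame  # strain, mean, sd, n
    excluded: list = field(default_factory=list)


@dataclass
class LinearModelResult:
    """Fitted OLS model with strain-effect LRT and residual diagnostics."""

    params: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    strain_F: float
    strain_df: tuple[int, int]
    strain_pvalue: float
    bp_stat: float
    bp_pvalue: float
    shapiro_stat: float
    shapiro_pvalue: float
    model: object = None

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "tvalues": self.tvalues.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "strain_F": self.strain_F,
            "strain_df": list(self.strain_df),
            "strain_pvalue": self.strain_pvalue,
            "breusch_pagan": {"stat": self.bp_stat, "pvalue": self.bp_pvalue},
            "shapiro": {"stat": self.shapiro_stat, "pvalue": self.shapiro_pvalue},
        }


def fit_standard_curve(points: pd.DataFrame, locus: str | None = None) -> StandardCurve:
    """Fit a standard curve from a (locus, log10_dilution, cq) dilution table.

    Needs at least three dilution points; the slope must come out negative
    (more template, earlier Cq).
    """
    missing = [c for c in CURVE_COLUMNS if c not in points.columns]
    if missing:
        raise ValueError(f"standard-curve table missing columns: {missing}")
    if locus is not None:
        points = points[points["locus"] == locus]
    loci = points["locus"].unique()
    if len(loci) != 1:
        raise ValueError(f"fit_standard_curve needs a single locus, got {list(loci)}")
    if len(points) < 3:
        raise ValueError(f"locus {loci[0]!r}: need >= 3 dilution points, got {len(points)}")
    reg = stats.linregress(points["log10_dilution"], points["cq"])
    return StandardCurve(
        locus=str(loci[0]),
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r2=float(reg.rvalue**2),
    )


def copy_number_ratio(
    data: pd.DataFrame,
    curves: dict[str, StandardCurve],
    average_on: str = "quantity",
    calibrator: str | None = None,
) -> CopyNumberResult:
    """Per-individual copy-number ratios from Cq data and per-locus curves.

    ``average_on`` chooses where technical replicates are averaged:
    ``"quantity"`` (default; ratios are defined on quantities) or ``"cq"``.
    ``calibrator`` optionally names a strain whose mean ratio rescales all
    ratios to 1 (off by default). Individuals missing either locus are
    excluded and listed in ``excluded``.
    """
    missing = [c for c in QPCR_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns: {missing}")
    for locus in (TARGET_LOCUS, REFERENCE_LOCUS):
        if locus not in curves:
            raise ValueError(f"no standard curve for locus {locus!r}")
    if average_on not in ("quantity", "cq"):
        raise ValueError("average_on must be 'quantity' or 'cq'")

    rows, excluded = [], []
    for (individual, strain), grp in data.groupby(["individual", "strain"], sort=False):
        quantities = {}
        for locus in (TARGET_LOCUS, REFERENCE_LOCUS):
            sub = grp[grp["locus"] == locus]
            if len(sub) == 0:
                continue
            curve = curves[locus]
            if average_on == "quantity":
                quantities[locus] = float(curve.quantity(sub["cq"].to_numpy()).mean())
            else:
                quantities[locus] = float(curve.quantity(sub["cq"].mean()))
        if len(quantities) < 2:
            excluded.append(individual)
            continue
        rows.append(
            {"individual": individual, "strain": strain,
             "ratio": quantities[TARGET_LOCUS] / quantities[REFERENCE_LOCUS]}
        )
    per_ind = pd.DataFrame(rows)
    if len(per_ind) == 0:
        raise ValueError("no individual had both loci measured")
    if calibrator is not None:
        cal = per_ind.loc[per_ind["strain"] == calibrator, "ratio"]
        if len(cal) == 0:
            raise ValueError(f"calibrator strain {calibrator!r} not in data")
        per_ind["ratio"] = per_ind["ratio"] / cal.mean()
    per_strain = (
        per_ind.groupby("strain", sort=False)["ratio"]
        .agg(mean="mean", sd="std", n="size")
        .reset_index()
    )
    return CopyNumberResult(per_individual=per_ind, per_strain=per_strain, excluded=excluded)


def _diagnostics(res) -> tuple[float, float, float, float]:
    bp = het_breuschpagan(res.resid, res.model.exog)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sw = stats.shapiro(res.resid)
    return float(bp[0]), float(bp[1]), float(sw.statistic), float(sw.pvalue)


def _strain_lrt(full, reduced) -> tuple[float, tuple[int, int], float]:
    table = sm.stats.anova_lm(reduced, full)
    F = float(table["F"].iloc[1])
    df1 = int(table["df_diff"].iloc[1])
    df2 = int(full.df_resid)
    p = float(table["Pr(>F)"].iloc[1])
    return F, (df1, df2), p


def copy_number_lm(
    result: CopyNumberResult | pd.DataFrame, reference: str = "SLAB"
) -> LinearModelResult:
    """One-way strain model for copy-number ratios with contrasts vs a reference.

    gamma_ij = mu + alpha_j + eps_ij; per-strain t statistics test each
    strain's contrast against the reference; the overall strain effect is an
    F likelihood-ratio test against the intercept-only model.
    """
    df = result.per_individual if isinstance(result, CopyNumberResult) else result
    if df["strain"].nunique() < 2:
        raise ValueError("copy_number_lm needs >= 2 strains")
    sizes = df.groupby("strain").size()
    if (sizes < 2).any():
        raise ValueError(f"strains with a single observation: {list(sizes.index[sizes < 2])}")
    if reference not in set(df["strain"]):
        raise ValueError(f"reference strain {reference!r} not in data")
    full = smf.ols(f"ratio ~ C(strain, Treatment(reference='{reference}'))", data=df).fit()
    reduced = smf.ols("ratio ~ 1", data=df).fit()
    F, dfs, p = _strain_lrt(full, reduced)
    bp_stat, bp_p, sw_stat, sw_p = _diagnostics(full)
    return LinearModelResult(
        params=full.params, tvalues=full.tvalues, pvalues=full.pvalues,
        strain_F=F, strain_df=dfs, strain_pvalue=p,
        bp_stat=bp_stat, bp_pvalue=bp_p, shapiro_stat=sw_stat, shapiro_pvalue=sw_p,
        model=full,
    )


def activity_lm(data: pd.DataFrame) -> LinearModelResult:
    """Additive strain + sex + plate model for enzyme activity.

    gamma_ijkl = mu + alpha_j + beta_k + delta_l + eps; the strain effect is
    tested by an F likelihood-ratio test of the full model against the model
    without strain. A design where strain is perfectly aliased with plate
    (adding strain does not increase the design rank) is rejected.
    """
    missing = [c for c in ACTIVITY_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"activity table missing columns: {missing}")
    if data["strain"].nunique() < 2:
        raise ValueError("activity_lm needs >= 2 strains")
    full = smf.ols("activity ~ C(strain) + C(sex) + C(plate)", data=data).fit()
    reduced = smf.ols("activity ~ C(sex) + C(plate)", data=data).fit()
    if np.linalg.matrix_rank(full.model.exog) <= np.linalg.matrix_rank(reduced.model.exog):
        raise ValueError("strain is perfectly aliased with sex/plate; effect not estimable")
    F, dfs, p = _strain_lrt(full, reduced)
    bp_stat, bp_p, sw_stat, sw_p = _diagnostics(full)
    return LinearModelResult(
        params=full.params, tvalues=full.tvalues, pvalues=full.pvalues,
        strain_F=F, strain_df=dfs, strain_pvalue=p,
        bp_stat=bp_stat, bp_pvalue=bp_p, shapiro_stat=sw_stat, shapiro_pvalue=sw_p,
        model=full,
    )
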
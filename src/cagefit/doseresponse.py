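"""Probit dose-mortality analysis: Abbott correction, LD50, resistance ratios.

Larval bioassays expose batches of larvae to a dose series of insecticide and
record deaths after 24 h. The analysis follows the standard probit workflow
for such assays: pool replicates at each dose, rescale observed mortality by
pooled control (dose 0) mortality with Abbott's formula, fit a binomial GLM
with a probit link on log10(dose), and read lethal doses off the fitted line,

    probit(p) = a + b * log10(dose),    log10(LD50) = (probit(0.5) - a) / b.

Confidence intervals for LD50 use the delta method on the log10 scale;
two strains are compared through the ratio of their LD50s (RR50) with a
1-df Wald chi-square on the difference of log10 LD50s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SeparationError",
    "ProbitFit",
    "LD50Result",
    "ResistanceRatio",
    "abbott_correct",
    "fit_probit",
    "lethal_dose",
    "resistance_ratio",
]

BIOASSAY_COLUMNS = ("strain", "dose", "n_exposed", "n_dead", "replicate")


class SeparationError(ValueError):
    """Mortality jumps from 0% to 100% with no intermediate dose; the slope is unidentifiable."""


@dataclass(frozen=True)
class ProbitFit:
    """Probit regression of corrected mortality on log10(dose) for one strain.

    ``intercept``/``slope`` parametrize probit(p) = a + b*log10(dose); ``cov``
    is their 2x2 variance-covariance matrix. ``gof_chi2`` is a Pearson
    goodness-of-fit (linearity) statistic with ``gof_df`` = #dose groups - 2.
    """

    strain: str
    intercept: float
    slope: float
    cov: np.ndarray
    gof_chi2: float
    gof_df: int

    @property
    def gof_pvalue(self) -> float:
        if self.gof_df <= 0:
            return float("nan")
        return float(stats.chi2.sf(self.gof_chi2, self.gof_df))


@dataclass(frozen=True)
class LD50Result:
    strain: str
    ld50: float
    ci_low: float
    ci_high: float
    log10_ld50: float
    se_log10: float


@dataclass(frozen=True)
class ResistanceRatio:
    """LD50 ratio between two strains with a 1-df test of equality."""

    numerator: str
    denominator: str
    rr: float
    ci_low: float
    ci_high: float
    chi2: float
    df: int
    pvalue: float


def abbott_correct(table: pd.DataFrame) -> pd.DataFrame:
    """Abbott-corrected mortality table, replicates pooled per strain and dose.

    Control (dose 0) rows are pooled per strain into a control mortality
    ``c``; treated rows get ``p_corr = (p_obs - c) / (1 - c)`` clamped to
    [0, 1]. Strains without controls use c = 0. The returned frame has one
    row per strain x positive dose with columns strain, dose, n, p_obs, p_corr.
    """
    _check_bioassay(table)
    rows = []
    for strain, grp in table.groupby("strain", sort=False):
        controls = grp[grp["dose"] == 0]
        if len(controls):
            c = controls["n_dead"].sum() / controls["n_exposed"].sum()
        else:
            c = 0.0
        if c >= 1.0:
            raise ValueError(f"strain {strain!r}: 100% control mortality, assay uninterpretable")
        treated = grp[grp["dose"] > 0]
        pooled = treated.groupby("dose", sort=True).agg(
            n=("n_exposed", "sum"), dead=("n_dead", "sum")
        )
        for dose, row in pooled.iterrows():
            p_obs = row["dead"] / row["n"]
            p_corr = min(max((p_obs - c) / (1.0 - c), 0.0), 1.0)
            rows.append(
                {"strain": strain, "dose": dose, "n": int(row["n"]),
                 "p_obs": p_obs, "p_corr": p_corr, "control_mortality": c}
            )
    return pd.DataFrame(rows)


def _check_bioassay(table: pd.DataFrame) -> None:
    missing = [c for c in BIOASSAY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"bioassay table missing columns: {missing}")
    if len(table) == 0:
        raise ValueError("bioassay table is empty")
    if (table["dose"] < 0).any():
        raise ValueError("doses must be >= 0")
    bad = table["n_dead"] > table["n_exposed"]
    if bad.any():
        raise ValueError(f"n_dead exceeds n_exposed in rows {list(table.index[bad])}")


def fit_probit(table: pd.DataFrame, strain: str | None = None) -> ProbitFit:
    """Binomial ML probit fit of corrected mortality on log10(dose), one strain.

    ``table`` is a raw bioassay table; if it holds several strains, ``strain``
    selects one. Requires at least two distinct positive doses and at least
    one dose group with partial (0 < p < 1) corrected mortality.
    """
    _check_bioassay(table)
    if strain is not None:
        table = table[table["strain"] == strain]
        if len(table) == 0:
            raise ValueError(f"no rows for strain {strain!r}")
    strains = table["strain"].unique()
    if len(strains) != 1:
        raise ValueError(f"fit_probit needs a single strain, got {list(strains)}")
    name = str(strains[0])

    corr = abbott_correct(table)
    doses = corr["dose"].to_numpy(float)
    if len(doses) < 2:
        raise ValueError(f"strain {name!r}: need >= 2 distinct positive doses, got {len(doses)}")
    p = corr["p_corr"].to_numpy(float)
    n = corr["n"].to_numpy(float)
    partial = (p > 0) & (p < 1)
    if not partial.any():
        raise SeparationError(
            f"strain {name!r}: all dose groups at 0% or 100% corrected mortality"
        )

    X = sm.add_constant(np.log10(doses))
    model = sm.GLM(p, X, family=sm.families.Binomial(sm.families.links.Probit()), var_weights=n)
    res = model.fit()
    a, b = res.params
    cov = np.asarray(res.cov_params())

    fitted = stats.norm.cdf(a + b * np.log10(doses))
    with np.errstate(divide="ignore", invalid="ignore"):
        pearson = n * (p - fitted) ** 2 / (fitted * (1.0 - fitted))
    gof = float(np.nansum(pearson))
    return ProbitFit(
        strain=name, intercept=float(a), slope=float(b), cov=cov,
        gof_chi2=gof, gof_df=len(doses) - 2,
    )


def lethal_dose(
    fit: ProbitFit,
    quantile: float = 0.5,
    conf: float = 0.95,
    ci_method: str = "delta",
) -> LD50Result:
    """Lethal dose for a mortality quantile, with a CI on the log10 scale.

    log10(LDq) = (probit(q) - a)/b. ``ci_method="delta"`` (default) applies
    the delta method with gradient (-1/b, -(z - a)/b^2); ``"fieller"`` uses
    Fieller's theorem for the ratio (z - a)/b, which is wider when the slope
    is poorly determined. Both are back-transformed, so bounds stay positive.
    """
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must be in (0, 1)")
    if fit.slope <= 0:
        raise ValueError(
            f"strain {fit.strain!r}: non-positive probit slope ({fit.slope}); "
            "mortality does not increase with dose"
        )
    z = stats.norm.ppf(quantile)
    rho = (z - fit.intercept) / fit.slope
    grad = np.array([-1.0 / fit.slope, -(z - fit.intercept) / fit.slope**2])
    var = float(grad @ fit.cov @ grad)
    se = np.sqrt(max(var, 0.0))
    zc = stats.norm.ppf(0.5 + conf / 2.0)
    if ci_method == "delta":
        lo, hi = rho - zc * se, rho + zc * se
    elif ci_method == "fieller":
        # ratio N/D with N = z - a, D = b
        v_n = float(fit.cov[0, 0])
        v_d = float(fit.cov[1, 1])
        c_nd = float(-fit.cov[0, 1])
        g = zc**2 * v_d / fit.slope**2
        if g >= 1.0:
            raise ValueError(
                f"strain {fit.strain!r}: slope too poorly determined for a "
                f"finite Fieller interval (g = {g:.3f} >= 1)"
            )
        disc = v_n - 2 * rho * c_nd + rho**2 * v_d - g * (v_n - c_nd**2 / v_d)
        half = (zc / fit.slope) * np.sqrt(max(disc, 0.0))
        centre = rho - g * c_nd / v_d
        lo, hi = (centre - half) / (1 - g), (centre + half) / (1 - g)
    else:
        raise ValueError("ci_method must be 'delta' or 'fieller'")
    return LD50Result(
        strain=fit.strain,
        ld50=float(10**rho),
        ci_low=float(10**lo),
        ci_high=float(10**hi),
        log10_ld50=float(rho),
        se_log10=float(se),
    )


def resistance_ratio(
    fit_num: ProbitFit, fit_den: ProbitFit, quantile: float = 0.5, conf: float = 0.95
) -> ResistanceRatio:
    """RR50 = LD50(numerator) / LD50(denominator) with CI and equality test.

    The variance of the log10 ratio is the sum of the two delta-method
    variances (strains are independent assays); the equality test is the
    squared standardized log-ratio against chi-square(1).
    """
    ld_num = lethal_dose(fit_num, quantile, conf)
    ld_den = lethal_dose(fit_den, quantile, conf)
    diff = ld_num.log10_ld50 - ld_den.log10_ld50
    se = float(np.sqrt(ld_num.se_log10**2 + ld_den.se_log10**2))
    zc = stats.norm.ppf(0.5 + conf / 2.0)
    chi2 = (diff / se) ** 2 if se > 0 else float("inf")
    return ResistanceRatio(
        numerator=fit_num.strain,
        denominator=fit_den.strain,
        rr=float(10**diff),
        ci_low=float(10 ** (diff - zc * se)),
        ci_high=float(10 ** (diff + zc * se)),
        chi2=float(chi2),
        df=1,
        pvalue=float(stats.chi2.sf(chi2, 1)),
    )
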
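"""CSV readers with schema validation and the end-to-end orchestration.

Every tabular exchange format is plain CSV with a required header; validation
errors name the offending row (1-based, excluding the header) and column.
``run_all`` drives the whole pipeline — cage fitness fit, bioassay LD50s and
resistance ratios, qPCR copy numbers with the strain linear model, activity
linear model, endpoint proportion tests — and returns one JSON-serialisable
bundle in which every result is traceable to input-file hashes and seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from . import doseresponse, mlfit, popgen, quant
from .popgen import COUNT_COLUMNS

__all__ = ["SchemaError", "SCHEMAS", "read_table", "run_all", "file_sha256"]


class SchemaError(ValueError):
    """A table violates its schema; the message names the row and column."""


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    dtype: type  # int, float or str
    check: Callable[[pd.Series], pd.Series] | None = None  # returns bool mask of bad rows
    message: str = ""


def _nonneg(series: pd.Series) -> pd.Series:
    return series < 0


def _positive(series: pd.Series) -> pd.Series:
    return series < 1


SCHEMAS: dict[str, tuple[ColumnSpec, ...]] = {
    "cages": (
        ColumnSpec("cage", str),
        ColumnSpec("generation", int, _positive, "must be an integer >= 1"),
        ColumnSpec("n_R1R1", int, _nonneg, "must be a non-negative integer"),
        ColumnSpec("n_R1R2", int, _nonneg, "must be a non-negative integer"),
        ColumnSpec("n_R2R2", int, _nonneg, "must be a non-negative integer"),
    ),
    "bioassay": (
        ColumnSpec("strain", str),
        ColumnSpec("dose", float, _nonneg, "must be >= 0"),
        ColumnSpec("n_exposed", int, _positive, "must be an integer >= 1"),
        ColumnSpec("n_dead", int, _nonneg, "must be a non-negative integer"),
        ColumnSpec("replicate", str),
    ),
    "qpcr": (
        ColumnSpec("individual", str),
        ColumnSpec("strain", str),
        ColumnSpec("locus", str),
        ColumnSpec("replicate", int, _positive, "must be an integer >= 1"),
        ColumnSpec("cq", float),
    ),
    "standard_curve": (
        ColumnSpec("locus", str),
        ColumnSpec("log10_dilution", float),
        ColumnSpec("cq", float),
    ),
    "activity": (
        ColumnSpec("individual", str),
        ColumnSpec("strain", str),
        ColumnSpec("sex", str),
        ColumnSpec("plate", str),
        ColumnSpec("activity", float),
    ),
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV table against a named schema.

    Raises :class:`SchemaError` naming the first offending row and column for
    missing columns, untypeable values, or domain violations (negative doses,
    non-integer counts, n_dead > n_exposed, ...).
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; choose from {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")
    specs = SCHEMAS[schema]
    missing = [c.name for c in specs if c.name not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    out = pd.DataFrame(index=df.index)
    for spec in specs:
        raw = df[spec.name]
        if spec.dtype is str:
            out[spec.name] = raw.astype(str)
            continue
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise SchemaError(
                f"{path}: row {row}, column {spec.name!r}: "
                f"cannot parse {raw[bad.idxmax()]!r} as {spec.dtype.__name__}"
            )
        if spec.dtype is int:
            frac = numeric != np.floor(numeric)
            if frac.any():
                row = int(frac.idxmax()) + 1
                raise SchemaError(
                    f"{path}: row {row}, column {spec.name!r}: not an integer"
                )
            numeric = numeric.astype(int)
        if spec.check is not None:
            bad = spec.check(numeric)
            if bad.any():
                row = int(bad.idxmax()) + 1
                raise SchemaError(
                    f"{path}: row {row}, column {spec.name!r}: {spec.message}"
                )
        out[spec.name] = numeric
    if schema == "bioassay":
        bad = out["n_dead"] > out["n_exposed"]
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise SchemaError(f"{path}: row {row}, column 'n_dead': exceeds n_exposed")
    if schema == "cages":
        popgen.validate_cage_table(out)
    return out


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_all(
    cages: pd.DataFrame,
    bioassay: pd.DataFrame,
    qpcr: pd.DataFrame,
    standard_curves: pd.DataFrame,
    activity: pd.DataFrame,
    search: mlfit.SearchConfig | None = None,
    reference_strain: str = "SLAB",
    provenance: Mapping | None = None,
) -> dict:
    """Run every analysis stage and return a single JSON-serialisable bundle.

    Stage failures are re-raised with the stage name prefixed so a pipeline
    error always identifies where it happened.
    """
    bundle: dict = {"provenance": dict(provenance or {})}

    def stage(name: str, fn: Callable[[], dict]) -> None:
        try:
            bundle[name] = fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    def _fit_cages() -> dict:
        est, _ = mlfit.fit(cages, search)
        endpoint = {}
        for cage, grp in cages.groupby("cage"):
            last = grp.loc[grp["generation"].idxmax()]
            counts = [int(last[c]) for c in COUNT_COLUMNS]
            stat, p = popgen.endpoint_binomial_test(*counts)
            endpoint[str(cage)] = {
                "final_generation": int(last["generation"]),
                "p1": popgen.allele_freq_from_counts(*counts),
                "chi2": stat,
                "pvalue": p,
            }
        return {"estimate": est.to_dict(), "endpoint_tests": endpoint}

    def _bioassay() -> dict:
        strains = list(bioassay["strain"].unique())
        fits = {s: doseresponse.fit_probit(bioassay, s) for s in strains}
        ld = {s: doseresponse.lethal_dose(f) for s, f in fits.items()}
        out = {
            s: {
                "intercept": f.intercept, "slope": f.slope,
                "gof_chi2": f.gof_chi2, "gof_df": f.gof_df, "gof_pvalue": f.gof_pvalue,
                "ld50": ld[s].ld50, "ld50_ci": [ld[s].ci_low, ld[s].ci_high],
            }
            for s, f in fits.items()
        }
        ratios = {}
        for s in strains:
            if s == reference_strain or reference_strain not in fits:
                continue
            rr = doseresponse.resistance_ratio(fits[s], fits[reference_strain])
            ratios[f"{s}_vs_{reference_strain}"] = {
                "rr50": rr.rr, "ci": [rr.ci_low, rr.ci_high],
                "chi2": rr.chi2, "df": rr.df, "pvalue": rr.pvalue,
            }
        resistant = [s for s in strains if s != reference_strain]
        if len(resistant) == 2:
            hi = max(resistant, key=lambda s: ld[s].ld50)
            lo = min(resistant, key=lambda s: ld[s].ld50)
            rr = doseresponse.resistance_ratio(fits[hi], fits[lo])
            ratios[f"{hi}_vs_{lo}"] = {
                "rr50": rr.rr, "ci": [rr.ci_low, rr.ci_high],
                "chi2": rr.chi2, "df": rr.df, "pvalue": rr.pvalue,
            }
        return {"strains": out, "resistance_ratios": ratios}

    def _copynumber() -> dict:
        curves = {
            locus: quant.fit_standard_curve(standard_curves, locus)
            for locus in standard_curves["locus"].unique()
        }
        result = quant.copy_number_ratio(qpcr, curves)
        lm = quant.copy_number_lm(result, reference=reference_strain)
        return {
            "curves": {
                l: {"slope": c.slope, "intercept": c.intercept,
                    "efficiency": c.efficiency, "r2": c.r2}
                for l, c in curves.items()
            },
            "per_strain": result.per_strain.to_dict(orient="records"),
            "excluded": list(result.excluded),
            "model": lm.to_dict(),
        }

    def _activity() -> dict:
        lm = quant.activity_lm(activity)
        summary = (
            activity.groupby("strain")["activity"]
            .agg(mean="mean", sd="std", n="size")
            .reset_index()
            .to_dict(orient="records")
        )
        return {"per_strain": summary, "model": lm.to_dict()}

    stage("cages", _fit_cages)
    stage("bioassay", _bioassay)
    stage("copy_number", _copynumber)
    stage("activity", _activity)
    return bundle


def write_bundle(bundle: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n")
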
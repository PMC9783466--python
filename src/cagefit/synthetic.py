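"""Seeded generators emulating the study's four experimental designs.

Every generator is a pure function of a :class:`SyntheticScenario` and a seed,
and each design mirrors the corresponding wet-lab setup:

* **cages** — 3 replicate population cages founded by an F1 cross (all
  R1R2), followed for 11 discrete generations with ~100 second-instar larvae
  genotyped per generation; counts are multinomial draws from the
  deterministic reproduction-selection model's larval frequencies (optional
  Wright-Fisher drift between generations for a finite census size).
* **bioassays** — per strain, 4 replicate cups of 20 larvae at each of 8
  temephos doses spanning 0-0.07 ug/ml plus untreated controls; deaths are
  binomial with a probit dose-mortality response, mixed with control
  mortality by the inverse of Abbott's formula.
* **qPCR** — 10 individuals per strain, both loci (ace-1, ace-2), 3
  technical replicates, Cq from each locus' standard curve plus Gaussian
  cycle noise; tenfold-dilution standard-curve tables from the same curves.
* **activity** — 48 individuals per strain with additive strain, sex and
  plate effects and Gaussian noise, sexes and plates balanced.

Defaults encode the study conditions: true fitness parameters h = -0.605,
s = -0.38 (so w_R1R2 = 1.23 and w_R2R2 = 0.62), copy numbers 1/1/3 for
SLAB/SR/SRQ, LD50s in the paperback 4.6x and 15x resistance-ratio relation,
and activity means 6.3 (SR) vs 10.8 (SRQ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popgen import (
    FitnessParams,
    apply_selection,
    gamete_allele_freqs,
    hwe_genotype_freqs,
)

__all__ = [
    "StrainBioassay",
    "SyntheticScenario",
    "gen_cage_counts",
    "gen_bioassay",
    "gen_qpcr",
    "gen_activity",
]

# fixed per-generator tags so streams are independent of call order
_TAGS = {"cages": 1, "bioassay": 2, "qpcr": 3, "activity": 4}


@dataclass(frozen=True)
class StrainBioassay:
    """True dose-mortality response of one strain (probit on log10 dose)."""

    ld50: float  # ug/ml
    slope: float = 4.0  # probit units per log10 dose
    control_mortality: float = 0.0

    @property
    def intercept(self) -> float:
        return -self.slope * np.log10(self.ld50)


def _default_bioassays() -> dict[str, StrainBioassay]:
    # SLAB anchor chosen so the resistant strains sit at 4.6x and 15x,
    # all within the 0-0.07 ug/ml dose range used in the assays
    return {
        "SLAB": StrainBioassay(ld50=0.0016),
        "SR": StrainBioassay(ld50=0.0016 * 4.6),
        "SRQ": StrainBioassay(ld50=0.0016 * 15.0),
    }


def _default_doses() -> tuple[float, ...]:
    return (0.0, 0.0005, 0.001, 0.002, 0.004, 0.008, 0.016, 0.035, 0.07)


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters for every simulated table, plus the master seed."""

    # cages
    h: float = -0.605
    s: float = -0.38
    n_cages: int = 3
    n_generations: int = 11
    larvae_per_generation: int = 100
    census_size: int | None = None  # None = deterministic transmission (no drift)

    # bioassays
    bioassays: dict[str, StrainBioassay] = field(default_factory=_default_bioassays)
    doses: tuple[float, ...] = field(default_factory=_default_doses)
    n_replicates: int = 4
    larvae_per_cup: int = 20

    # qPCR
    copy_numbers: dict[str, float] = field(
        default_factory=lambda: {"SLAB": 1.0, "SR": 1.0, "SRQ": 3.0}
    )
    n_individuals_qpcr: int = 10
    n_tech_replicates: int = 3
    cq_noise_sd: float = 0.15
    curve_slopes: dict[str, float] = field(
        default_factory=lambda: {"ace-1": -3.3219280948873623, "ace-2": -3.3219280948873623}
    )
    curve_intercepts: dict[str, float] = field(
        default_factory=lambda: {"ace-1": 24.0, "ace-2": 25.0}
    )
    n_dilutions: int = 5  # tenfold series: log10 dilution 0 .. -(n-1)

    # activity
    activity_means: dict[str, float] = field(
        default_factory=lambda: {"SR": 6.3, "SRQ": 10.8}
    )
    activity_sd: float = 1.3
    sex_effect: float = 0.3  # males relative to females
    plate_effects: tuple[float, ...] = (-0.2, -0.1, 0.1, 0.2)
    n_individuals_activity: int = 48

    seed: int = 0

    def fitness(self) -> FitnessParams:
        return FitnessParams(self.h, self.s)


def _rng(scn: SyntheticScenario, stage: str, seed: int | None) -> np.random.Generator:
    master = scn.seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence([int(master), _TAGS[stage]]))


def gen_cage_counts(scn: SyntheticScenario, seed: int | None = None) -> pd.DataFrame:
    """Simulate genotyped larval counts for every cage and generation.

    Genotype counts are multinomial draws (size = larvae genotyped) from the
    model's larval frequencies. With a finite ``census_size`` N, allele
    transmission between generations is binomially resampled (2N gametes,
    Wright-Fisher) before the Hardy-Weinberg expansion; by default
    transmission is deterministic, matching the fitted model.
    """
    rng = _rng(scn, "cages", seed)
    fit = scn.fitness()
    rows = []
    for cage in range(1, scn.n_cages + 1):
        p1 = 0.5
        for gen in range(1, scn.n_generations + 1):
            if scn.census_size is not None:
                n_gametes = 2 * scn.census_size
                p1 = rng.binomial(n_gametes, p1) / n_gametes
            f_larv = hwe_genotype_freqs(p1)
            counts = rng.multinomial(scn.larvae_per_generation, np.asarray(f_larv))
            rows.append(
                {"cage": f"cage{cage}", "generation": gen,
                 "n_R1R1": int(counts[0]), "n_R1R2": int(counts[1]), "n_R2R2": int(counts[2])}
            )
            p1 = gamete_allele_freqs(apply_selection(f_larv, fit))
    return pd.DataFrame(rows)


def gen_bioassay(scn: SyntheticScenario, seed: int | None = None) -> pd.DataFrame:
    """Simulate per-cup death counts for every strain, dose and replicate.

    The death probability at dose d > 0 is c + (1-c) * Phi(a + b*log10(d))
    (control mortality c mixed in by inverting Abbott's correction); at
    dose 0 it is c alone.
    """
    from scipy.stats import norm

    rng = _rng(scn, "bioassay", seed)
    rows = []
    for strain, assay in scn.bioassays.items():
        for dose in scn.doses:
            if dose > 0:
                p_dose = norm.cdf(assay.intercept + assay.slope * np.log10(dose))
                p = assay.control_mortality + (1 - assay.control_mortality) * p_dose
            else:
                p = assay.control_mortality
            for rep in range(1, scn.n_replicates + 1):
                dead = int(rng.binomial(scn.larvae_per_cup, p))
                rows.append(
                    {"strain": strain, "dose": dose, "n_exposed": scn.larvae_per_cup,
                     "n_dead": dead, "replicate": rep}
                )
    return pd.DataFrame(rows)


def gen_qpcr(
    scn: SyntheticScenario, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate Cq tables and tenfold-dilution standard curves for both loci.

    Per individual, the ace-2 relative quantity is 1 and the ace-1 quantity
    equals the strain's true copy number; every well's Cq is the locus curve
    evaluated at log10(quantity) plus Gaussian cycle noise. Returns
    ``(qpcr_table, standard_curve_table)``.
    """
    rng = _rng(scn, "qpcr", seed)
    qpcr_rows, curve_rows = [], []
    for locus in ("ace-1", "ace-2"):
        slope = scn.curve_slopes[locus]
        intercept = scn.curve_intercepts[locus]
        # calibration points lie exactly on the true line: standard curves
        # are high-precision calibrations, so only sample wells carry noise
        for k in range(scn.n_dilutions):
            log10_dil = -float(k)
            curve_rows.append(
                {"locus": locus, "log10_dilution": log10_dil,
                 "cq": intercept + slope * log10_dil}
            )
    for strain, copies in scn.copy_numbers.items():
        for ind in range(1, scn.n_individuals_qpcr + 1):
            name = f"{strain}_{ind:02d}"
            for locus, quantity in (("ace-1", copies), ("ace-2", 1.0)):
                slope = scn.curve_slopes[locus]
                intercept = scn.curve_intercepts[locus]
                mean_cq = intercept + slope * np.log10(quantity)
                for rep in range(1, scn.n_tech_replicates + 1):
                    cq = mean_cq + rng.normal(0.0, scn.cq_noise_sd)
                    qpcr_rows.append(
                        {"individual": name, "strain": strain, "locus": locus,
                         "replicate": rep, "cq": cq}
                    )
    return pd.DataFrame(qpcr_rows), pd.DataFrame(curve_rows)


def gen_activity(scn: SyntheticScenario, seed: int | None = None) -> pd.DataFrame:
    """Simulate enzyme-activity measurements with balanced sexes and plates.

    activity = strain mean + sex effect + plate effect + N(0, sd); within
    each strain, individuals alternate sex and cycle through the plates so
    the design is balanced (no strain-plate or strain-sex confounding).
    """
    rng = _rng(scn, "activity", seed)
    n_plates = len(scn.plate_effects)
    rows = []
    for strain, mean in scn.activity_means.items():
        for ind in range(scn.n_individuals_activity):
            # consecutive F/M pairs walk through the plates, so every plate
            # holds both sexes and both strains (fully crossed design)
            sex = "M" if ind % 2 else "F"
            plate = (ind // 2) % n_plates
            activity = (
                mean
                + (scn.sex_effect if sex == "M" else 0.0)
                + scn.plate_effects[plate]
                + rng.normal(0.0, scn.activity_sd)
            )
            rows.append(
                {"individual": f"{strain}_{ind + 1:02d}", "strain": strain,
                 "sex": sex, "plate": f"plate{plate + 1}", "activity": activity}
            )
    return pd.DataFrame(rows)
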
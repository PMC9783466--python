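"""Deterministic one-locus reproduction-selection model for two resistance alleles.

The model follows the life cycle of a caged mosquito population founded by an
F1 cross between two homozygous strains (100% R1R2 heterozygotes, so the R1
allele starts at frequency 0.5). Each generation, larvae are formed by random
mating (Hardy-Weinberg proportions from the previous generation's gamete pool),
viability selection acts between the larval and adult stages with genotype
fitnesses

    w_R1R1 = 1,   w_R1R2 = 1 + h*s,   w_R2R2 = 1 + s,

and surviving adults contribute gametes for the next generation. There is no
drift: the trajectory is a deterministic function of the dominance coefficient
``h`` and the selection coefficient ``s``, both constrained to [-1, 1].

Observed genotype counts (second-instar larvae, i.e. *before* selection) enter
a multinomial log-likelihood

    L(h, s) = sum_g sum_i n_gi * ln(f_gi)

where ``f_gi`` is the model's larval frequency of genotype ``g`` at generation
``i``. Impossible data (a positive count for a genotype the model predicts at
frequency zero) yield ``-inf`` rather than an exception, so random parameter
search can discard such pairs gracefully.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FitnessParams",
    "GenotypeDist",
    "Trajectory",
    "DegenerateSelectionError",
    "hwe_genotype_freqs",
    "apply_selection",
    "gamete_allele_freqs",
    "simulate_trajectory",
    "larval_frequencies",
    "cage_log_likelihood",
    "equilibrium_frequency",
    "allele_freq_from_counts",
    "endpoint_binomial_test",
    "validate_cage_table",
]

_SUM_TOL = 1e-12

GENOTYPES = ("R1R1", "R1R2", "R2R2")
COUNT_COLUMNS = ("n_R1R1", "n_R1R2", "n_R2R2")


class DegenerateSelectionError(ValueError):
    """All weighted genotype frequencies are zero; selection is undefined."""


@dataclass(frozen=True)
class FitnessParams:
    """Dominance ``h`` and selection coefficient ``s``, both in [-1, 1].

    Fitnesses are relative to the R1R1 homozygote: ``w_R1R2 = 1 + h*s`` and
    ``w_R2R2 = 1 + s``. Within the admissible box all three fitnesses are
    non-negative; a (h, s) pair implying a negative heterozygote fitness is
    rejected outright.
    """

    h: float
    s: float

    def __post_init__(self) -> None:
        if not (-1.0 <= self.h <= 1.0):
            raise ValueError(f"dominance h={self.h} outside [-1, 1]")
        if not (-1.0 <= self.s <= 1.0):
            raise ValueError(f"selection coefficient s={self.s} outside [-1, 1]")
        if 1.0 + self.h * self.s < 0.0:
            raise ValueError(f"heterozygote fitness 1 + h*s = {1 + self.h * self.s} < 0")

    @property
    def fitnesses(self) -> np.ndarray:
        """Genotype fitnesses (w_R1R1, w_R1R2, w_R2R2)."""
        return np.array([1.0, 1.0 + self.h * self.s, 1.0 + self.s])


class GenotypeDist(NamedTuple):
    """Frequencies of (R1R1, R1R2, R2R2); non-negative, summing to 1."""

    f_R1R1: float
    f_R1R2: float
    f_R2R2: float

    def validate(self) -> "GenotypeDist":
        arr = np.asarray(self)
        if np.any(arr < -_SUM_TOL) or np.any(arr > 1 + _SUM_TOL):
            raise ValueError(f"genotype frequencies outside [0, 1]: {self}")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"genotype frequencies sum to {arr.sum()}, not 1")
        return self


@dataclass(frozen=True)
class Trajectory:
    """Per-generation model state.

    ``larval[i]`` holds the genotype distribution of the generation-``i+1``
    larval cohort (generation indices are 1-based: generation 0 is the F1
    adult state, 100% heterozygotes, which is never itself a larval cohort of
    the experiment). ``post_selection`` and ``gamete_p1`` are the matching
    post-selection distributions and gamete R1 frequencies.
    """

    larval: np.ndarray  # shape (n_generations, 3)
    post_selection: np.ndarray  # shape (n_generations, 3)
    gamete_p1: np.ndarray  # shape (n_generations,)

    @property
    def n_generations(self) -> int:
        return self.larval.shape[0]

    def larval_at(self, generation: int) -> GenotypeDist:
        """Larval genotype distribution at a 1-based generation index."""
        if not (1 <= generation <= self.n_generations):
            raise IndexError(f"generation {generation} outside 1..{self.n_generations}")
        return GenotypeDist(*self.larval[generation - 1])


def hwe_genotype_freqs(p1: float) -> GenotypeDist:
    """Hardy-Weinberg genotype frequencies (p1^2, 2*p1*p2, p2^2) from the R1 frequency."""
    if not (0.0 <= p1 <= 1.0):
        raise ValueError(f"allele frequency p1={p1} outside [0, 1]")
    p2 = 1.0 - p1
    return GenotypeDist(p1 * p1, 2.0 * p1 * p2, p2 * p2)


def apply_selection(f: GenotypeDist, fit: FitnessParams) -> GenotypeDist:
    """Viability selection: f'_g = f_g * w_g / sum(f_g * w_g)."""
    weighted = np.asarray(f) * fit.fitnesses
    total = weighted.sum()
    if total <= 0.0:
        raise DegenerateSelectionError(
            f"all weighted genotype frequencies are zero for f={tuple(f)}, "
            f"w={tuple(fit.fitnesses)}"
        )
    return GenotypeDist(*(weighted / total))


def gamete_allele_freqs(f: GenotypeDist) -> float:
    """R1 frequency in the gamete pool: f(R1R1) + f(R1R2)/2."""
    return f.f_R1R1 + 0.5 * f.f_R1R2


def simulate_trajectory(fit: FitnessParams, n_generations: int) -> Trajectory:
    """Iterate reproduction and selection from the all-heterozygote F1 state.

    Generation 0 is the F1 adult cohort (f_R1R2 = 1, gamete p1 = 0.5); for each
    generation 1..n the larval cohort is the Hardy-Weinberg expansion of the
    previous gamete pool, selection acts, and the survivors' gametes seed the
    next generation. Fully deterministic.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    larval = np.empty((n_generations, 3))
    post = np.empty((n_generations, 3))
    gamete = np.empty(n_generations)
    p1 = 0.5  # gametes of the F1 heterozygotes
    for i in range(n_generations):
        f_larv = hwe_genotype_freqs(p1)
        f_post = apply_selection(f_larv, fit)
        p1 = gamete_allele_freqs(f_post)
        larval[i] = f_larv
        post[i] = f_post
        gamete[i] = p1
    return Trajectory(larval=larval, post_selection=post, gamete_p1=gamete)


def larval_frequencies(
    h: np.ndarray, s: np.ndarray, n_generations: int
) -> np.ndarray:
    """Vectorised larval genotype frequencies for many (h, s) pairs at once.

    Returns an array of shape ``(len(h), n_generations, 3)`` equal, row by
    row, to ``simulate_trajectory(FitnessParams(h_k, s_k), n).larval``. Used
    by the random-search fitter, where millions of parameter pairs share the
    same recursion.
    """
    h = np.atleast_1d(np.asarray(h, dtype=float))
    s = np.atleast_1d(np.asarray(s, dtype=float))
    if h.shape != s.shape:
        raise ValueError("h and s must have the same shape")
    w12 = 1.0 + h * s
    w22 = 1.0 + s
    out = np.empty((h.size, n_generations, 3))
    p1 = np.full(h.shape, 0.5)
    for i in range(n_generations):
        p2 = 1.0 - p1
        f11 = p1 * p1
        f12 = 2.0 * p1 * p2
        f22 = p2 * p2
        out[:, i, 0] = f11
        out[:, i, 1] = f12
        out[:, i, 2] = f22
        g11 = f11  # w_R1R1 = 1
        g12 = f12 * w12
        g22 = f22 * w22
        total = g11 + g12 + g22
        p1 = (g11 + 0.5 * g12) / total
    return out


def validate_cage_table(data: pd.DataFrame) -> pd.DataFrame:
    """Check a cage genotype-count table (cage, generation, n_R1R1, n_R1R2, n_R2R2).

    Generation indices must be positive integers, strictly increasing within a
    cage (gaps allowed); every record must have a positive total count.
    """
    required = ["cage", "generation"] + list(COUNT_COLUMNS)
    missing = [c for c in required if c not in data.columns]
    if missing:
        raise ValueError(f"cage table missing columns: {missing}")
    if len(data) == 0:
        raise ValueError("cage table is empty")
    gens = data["generation"].to_numpy()
    if not np.all(gens == gens.astype(int)) or np.any(gens < 1):
        raise ValueError("generation indices must be integers >= 1")
    counts = data[list(COUNT_COLUMNS)].to_numpy()
    if np.any(counts < 0) or not np.all(counts == counts.astype(int)):
        raise ValueError("genotype counts must be non-negative integers")
    if np.any(counts.sum(axis=1) <= 0):
        raise ValueError("every record needs a positive total count")
    for cage, grp in data.groupby("cage"):
        g = grp["generation"].to_numpy()
        if np.any(np.diff(g) <= 0):
            raise ValueError(f"generation indices not strictly increasing in cage {cage!r}")
    return data


def cage_log_likelihood(data: pd.DataFrame, fit: FitnessParams) -> float:
    """Multinomial log-likelihood of cage genotype counts under (h, s).

    All cages share a single trajectory (same founding F1 state and the same
    fitnesses); per-cage contributions are summed over observed generations
    only. A genotype observed with positive count where the model predicts
    zero frequency makes the data impossible and returns ``-inf``.
    """
    data = validate_cage_table(data)
    n_gen = int(data["generation"].max())
    traj = simulate_trajectory(fit, n_gen)
    freqs = traj.larval[data["generation"].to_numpy(int) - 1]  # (n_records, 3)
    counts = data[list(COUNT_COLUMNS)].to_numpy(float)
    with np.errstate(divide="ignore"):
        logf = np.log(freqs)
    if np.any(np.isneginf(logf) & (counts > 0)):
        return float("-inf")
    terms = counts * np.where(counts > 0, logf, 0.0)
    return float(terms.sum())


def equilibrium_frequency(fit: FitnessParams) -> Optional[float]:
    """Internal equilibrium R1 frequency p1* = (w12 - w22) / (2*w12 - w11 - w22).

    Exists only under over- or underdominance (heterozygote fitness strictly
    greatest or strictly least). Returns ``None`` otherwise, including the
    degenerate all-equal case.
    """
    w11, w12, w22 = fit.fitnesses
    denom = 2.0 * w12 - w11 - w22
    if denom == 0.0:
        return None
    over = w12 > w11 and w12 > w22
    under = w12 < w11 and w12 < w22
    if not (over or under):
        return None
    return (w12 - w22) / denom


def allele_freq_from_counts(n_R1R1: int, n_R1R2: int, n_R2R2: int) -> float:
    """R1 allele frequency from genotype counts: (2*n11 + n12) / (2*N)."""
    total = n_R1R1 + n_R1R2 + n_R2R2
    if total <= 0:
        raise ValueError("total genotype count must be positive")
    return (2 * n_R1R1 + n_R1R2) / (2 * total)


def endpoint_binomial_test(
    n_R1R1: int,
    n_R1R2: int,
    n_R2R2: int,
    null_p: float = 0.5,
    continuity: bool = False,
) -> tuple[float, float]:
    """One-sample proportion test of the final R1 allele frequency vs ``null_p``.

    Each genotyped individual contributes two alleles. Returns the chi-square
    statistic (1 df, optional Yates continuity correction) and its two-sided
    p-value.
    """
    total = n_R1R1 + n_R1R2 + n_R2R2
    if total <= 0:
        raise ValueError("total genotype count must be positive")
    n_alleles = 2 * total
    n_r1 = 2 * n_R1R1 + n_R1R2
    expected = n_alleles * null_p
    dev = abs(n_r1 - expected)
    if continuity:
        dev = max(dev - 0.5, 0.0)
    stat = dev**2 / (n_alleles * null_p * (1.0 - null_p))
    pvalue = float(stats.chi2.sf(stat, df=1))
    return float(stat), pvalue
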
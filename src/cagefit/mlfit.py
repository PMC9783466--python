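"""Two-stage random-search maximum-likelihood estimation of (h, s).

The likelihood surface of the reproduction-selection model is cheap to
evaluate but not smooth enough near the admissible-box edges to trust local
optimisers blindly, so estimation uses the simple, robust scheme of drawing
parameter pairs uniformly at random: a first broad stage over the whole
admissible box, then a second, denser stage in a small box around the stage-1
optimum. Support limits for each parameter are the extreme sampled values
whose log-likelihood lies within 1.96 of the maximum (the chi-square(1)/2
profile approximation to a 95% confidence interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .popgen import COUNT_COLUMNS, larval_frequencies, validate_cage_table

__all__ = [
    "SearchConfig",
    "LikelihoodProfile",
    "FitnessEstimate",
    "random_search",
    "support_limits",
    "fit",
]

SUPPORT_DROP = 1.96


@dataclass(frozen=True)
class SearchConfig:
    """Random-search settings.

    ``n_stage1``/``n_stage2`` are the evaluation counts of the broad and the
    refined stage (defaults 100,000 and 1,000,000; ``fast()`` gives a
    10x-smaller desk-scale configuration). ``stage2_halfwidth`` is the
    half-width of the refinement box around the stage-1 optimum, clipped to
    the global bounds. One master seed governs both stages through spawned
    child streams, so changing one stage's count never alters the other
    stage's draws.
    """

    n_stage1: int = 100_000
    n_stage2: int = 1_000_000
    bounds_h: tuple[float, float] = (-1.0, 1.0)
    bounds_s: tuple[float, float] = (-1.0, 1.0)
    stage2_halfwidth: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stage1 < 1 or self.n_stage2 < 1:
            raise ValueError("evaluation counts must be >= 1")
        for lo, hi in (self.bounds_h, self.bounds_s):
            if not (-1.0 <= lo < hi <= 1.0):
                raise ValueError(f"bounds ({lo}, {hi}) must be ordered within [-1, 1]")
        if self.stage2_halfwidth <= 0:
            raise ValueError("stage2_halfwidth must be positive")

    @classmethod
    def fast(cls, seed: int = 0, **kwargs) -> "SearchConfig":
        """Desk-scale configuration: 10,000 + 100,000 evaluations."""
        kwargs.setdefault("n_stage1", 10_000)
        kwargs.setdefault("n_stage2", 100_000)
        return cls(seed=seed, **kwargs)


@dataclass
class LikelihoodProfile:
    """Pooled sampled points (h, s, logL) from both search stages."""

    h: np.ndarray
    s: np.ndarray
    logL: np.ndarray
    best_index: int = field(init=False)

    def __post_init__(self) -> None:
        finite = np.isfinite(self.logL)
        if not finite.any():
            raise ValueError("no sampled parameter pair has finite likelihood")
        # first occurrence wins ties, deterministically
        self.best_index = int(np.argmax(np.where(finite, self.logL, -np.inf)))

    @property
    def max_logL(self) -> float:
        return float(self.logL[self.best_index])

    def support_mask(self, drop: float = SUPPORT_DROP) -> np.ndarray:
        return self.logL >= self.max_logL - drop

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"h": self.h, "s": self.s, "logL": self.logL})


@dataclass(frozen=True)
class FitnessEstimate:
    """ML point estimate with per-parameter support limits.

    Fitness estimates are reported on the scale of the paper's
    parametrization: ``w_R1R2 = 1 + h*s`` and ``w_R2R2 = 1 + s``; support
    limits for the fitnesses are the extremes of the corresponding
    transformed values over the near-maximal sampled cloud.
    """

    h: float
    s: float
    max_logL: float
    support_h: tuple[float, float]
    support_s: tuple[float, float]
    support_w_R1R2: tuple[float, float]
    support_w_R2R2: tuple[float, float]

    @property
    def w_R1R2(self) -> float:
        return 1.0 + self.h * self.s

    @property
    def w_R2R2(self) -> float:
        return 1.0 + self.s

    def to_dict(self) -> dict:
        return {
            "h": self.h,
            "s": self.s,
            "w_R1R1": 1.0,
            "w_R1R2": self.w_R1R2,
            "w_R2R2": self.w_R2R2,
            "max_logL": self.max_logL,
            "support": {
                "h": list(self.support_h),
                "s": list(self.support_s),
                "w_R1R2": list(self.support_w_R1R2),
                "w_R2R2": list(self.support_w_R2R2),
            },
        }


def _batch_log_likelihood(
    h: np.ndarray, s: np.ndarray, generations: np.ndarray, counts: np.ndarray
) -> np.ndarray:
    """Log-likelihood of the cage counts for every (h, s) pair.

    ``generations`` (1-based) and ``counts`` (n_records, 3) describe all
    observed records pooled across cages; the deterministic trajectory is
    shared, so cages simply add their multinomial terms.
    """
    n_gen = int(generations.max())
    freqs = larval_frequencies(h, s, n_gen)  # (n_pairs, n_gen, 3)
    f_obs = freqs[:, generations - 1, :]  # (n_pairs, n_records, 3)
    observed = counts[None, :, :] > 0
    with np.errstate(divide="ignore"):
        logf = np.where(observed, np.log(np.where(f_obs > 0, f_obs, 1.0)), 0.0)
    logL = (counts[None, :, :] * logf).sum(axis=(1, 2))
    impossible = (observed & (f_obs == 0.0)).any(axis=(1, 2))
    logL[impossible] = -np.inf
    return logL


def _extract_records(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    data = validate_cage_table(data)
    generations = data["generation"].to_numpy(int)
    counts = data[list(COUNT_COLUMNS)].to_numpy(float)
    return generations, counts


def random_search(
    data: pd.DataFrame,
    n: int,
    bounds_h: tuple[float, float],
    bounds_s: tuple[float, float],
    rng: np.random.Generator,
) -> LikelihoodProfile:
    """Evaluate the cage likelihood at ``n`` uniform draws from the given box."""
    generations, counts = _extract_records(data)
    h = rng.uniform(*bounds_h, size=n)
    s = rng.uniform(*bounds_s, size=n)
    # evaluate in chunks: the (pairs x records x genotypes) intermediates
    # would otherwise dominate memory at millions of evaluations
    chunk = 65_536
    logL = np.empty(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        logL[start:stop] = _batch_log_likelihood(
            h[start:stop], s[start:stop], generations, counts
        )
    return LikelihoodProfile(h=h, s=s, logL=logL)


def support_limits(
    values: np.ndarray, logL: np.ndarray, drop: float = SUPPORT_DROP
) -> tuple[float, float]:
    """Profile support interval over a sampled cloud, one parameter axis.

    Returns the min and max of ``values`` among points whose log-likelihood is
    within ``drop`` of the sampled maximum. With a single qualifying point the
    interval is degenerate at that point.
    """
    logL = np.asarray(logL, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no sampled points")
    finite = np.isfinite(logL)
    if not finite.any():
        raise ValueError("no finite log-likelihoods")
    best = logL[finite].max()
    mask = finite & (logL >= best - drop)
    sel = values[mask]
    return float(sel.min()), float(sel.max())


def fit(data: pd.DataFrame, cfg: Optional[SearchConfig] = None) -> tuple[FitnessEstimate, LikelihoodProfile]:
    """Two-stage random-search ML fit of (h, s) to cage genotype counts.

    Stage 1 explores the full bounds; stage 2 redraws within a
    ``stage2_halfwidth`` box centred on the stage-1 optimum (clipped to the
    global bounds). The estimate is the argmax over the pooled cloud, and the
    support limits come from the pooled cloud too, so stage-2 refinement can
    only sharpen, never lose, the stage-1 optimum.
    """
    cfg = cfg or SearchConfig()
    ss = np.random.SeedSequence(cfg.seed)
    rng1, rng2 = (np.random.default_rng(child) for child in ss.spawn(2))

    stage1 = random_search(data, cfg.n_stage1, cfg.bounds_h, cfg.bounds_s, rng1)
    h0 = stage1.h[stage1.best_index]
    s0 = stage1.s[stage1.best_index]
    w = cfg.stage2_halfwidth
    box_h = (max(cfg.bounds_h[0], h0 - w), min(cfg.bounds_h[1], h0 + w))
    box_s = (max(cfg.bounds_s[0], s0 - w), min(cfg.bounds_s[1], s0 + w))
    stage2 = random_search(data, cfg.n_stage2, box_h, box_s, rng2)

    profile = LikelihoodProfile(
        h=np.concatenate([stage1.h, stage2.h]),
        s=np.concatenate([stage1.s, stage2.s]),
        logL=np.concatenate([stage1.logL, stage2.logL]),
    )
    i = profile.best_index
    h_hat, s_hat = float(profile.h[i]), float(profile.s[i])
    estimate = FitnessEstimate(
        h=h_hat,
        s=s_hat,
        max_logL=profile.max_logL,
        support_h=support_limits(profile.h, profile.logL),
        support_s=support_limits(profile.s, profile.logL),
        support_w_R1R2=support_limits(1.0 + profile.h * profile.s, profile.logL),
        support_w_R2R2=support_limits(1.0 + profile.s, profile.logL),
    )
    return estimate, profile
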
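"""Per-unit exponential tuning fits, synthetic regeneration, thresholding.

Each unit's visual tuning and memory sensitivity is summarized by a
three-parameter exponential model of the expected spike count in the
analysis window::

    y(x; M) = A_M * exp(-alpha * x)

where x is the image's rank on the unit's tuning curve (0 = best image),
M the presentation condition with separate amplitudes A_N (novel) and A_R
(repeated), and alpha >= 0 a shared decay constant capturing selectivity.
Parameters maximize the Poisson likelihood of the observed window counts.
For fixed alpha the optimal amplitudes have the closed form
A_M = sum(k_M) / sum(exp(-alpha x)), so the fit reduces to a 1-D bounded
profile-likelihood optimization over alpha.

The thresholding operation sets the tail of each tuning curve (the worst-
ranked ``N`` fraction of images) to a constant floor — by default the
repeated-curve value at the cutoff rank, for both conditions — removing
both selectivity and memory information from the tail.  Sweeping the
threshold fraction quantifies the trade-off between destroying
memorability correlation and destroying memory information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ._rng import substream
from .classify import cv_performance
from .screen import Pseudopopulation, window_rates
from .vigor import gmfr, memorability_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "TuningFit",
    "ThresholdSpec",
    "PopulationFit",
    "rank_images",
    "fit_tuning",
    "fit_population",
    "apply_threshold",
    "predicted_counts",
    "synthesize_from_fits",
    "threshold_sweep",
]

Y_FLOOR = 1e-8  # rate floor inside the log-likelihood
ALPHA_MAX = 2.0  # upper bound of the decay constant (per rank)


@dataclass(frozen=True)
class TuningFit:
    """Fitted exponential tuning parameters of one unit.

    Amplitudes are expected spike *counts* in the analysis window at
    rank 0; alpha is the per-rank decay constant.
    """

    A_N: float
    A_R: float
    alpha: float
    converged: bool
    loglik: float = np.nan

    def __post_init__(self) -> None:
        if self.A_N < 0 or self.A_R < 0 or self.alpha < 0:
            raise ValueError("amplitudes and alpha must be non-negative")

    def predict(self, ranks: np.ndarray, condition: str) -> np.ndarray:
        A = self.A_N if condition == "novel" else self.A_R
        return A * np.exp(-self.alpha * np.asarray(ranks, dtype=float))


@dataclass(frozen=True)
class ThresholdSpec:
    """Fraction of the ranked tuning curve to flatten (from the worst end).

    fraction = 0 leaves the curve untouched; fraction = 1 flattens it
    entirely.  cutoff_rank(n) = floor((1 - fraction) * n): ranks >= cutoff
    are modified.
    """

    fraction: float
    mode: str = "flat"  # "flat": repeated value AT cutoff; "per_rank": own repeated value

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.mode not in ("flat", "per_rank"):
            raise ValueError("mode must be 'flat' or 'per_rank'")

    def cutoff_rank(self, n_images: int) -> int:
        return int(np.floor((1.0 - self.fraction) * n_images))


@dataclass
class PopulationFit:
    """Tuning fits plus per-unit image rankings for a pseudopopulation."""

    fits: list[TuningFit]
    ranks: np.ndarray  # (U, P) rank of each pseudoimage on each unit's curve
    memorability: np.ndarray  # (P,)
    window: tuple[float, float]


def rank_images(novel_counts: np.ndarray, repeated_counts: np.ndarray
                ) -> np.ndarray:
    """Tuning ranks from observed counts, averaged across presentations.

    Rank 0 is the image with the highest novel/repeated-averaged count;
    ties break by image index order (deterministic).  Returns the rank of
    each image.
    """
    avg = 0.5 * (np.asarray(novel_counts, dtype=float)
                 + np.asarray(repeated_counts, dtype=float))
    order = np.lexsort((np.arange(len(avg)), -avg))
    ranks = np.empty(len(avg), dtype=int)
    ranks[order] = np.arange(len(avg))
    return ranks


def fit_tuning(novel_counts: np.ndarray, repeated_counts: np.ndarray,
               ranks: np.ndarray) -> TuningFit:
    """Poisson maximum-likelihood fit of y(x; M) = A_M exp(-alpha x).

    Counts are non-negative integers per image and condition; alpha is
    shared across conditions.  All-zero counts give A = 0 with alpha
    unidentifiable (flagged converged=False).
    """
    kn = np.asarray(novel_counts, dtype=float)
    kr = np.asarray(repeated_counts, dtype=float)
    x = np.asarray(ranks, dtype=float)
    if np.any(kn < 0) or np.any(kr < 0):
        raise ValueError("counts must be non-negative")
    Kn, Kr = kn.sum(), kr.sum()
    if Kn == 0 and Kr == 0:
        logger.warning("all-zero counts: amplitudes 0, alpha unidentifiable")
        return TuningFit(0.0, 0.0, 0.0, converged=False, loglik=0.0)
    sum_kx = float(kn @ x + kr @ x)

    def neg_profile_ll(alpha: float) -> float:
        S = np.exp(-alpha * x).sum()
        ll = -alpha * sum_kx
        for K in (Kn, Kr):
            if K > 0:
                A = K / S
                ll += K * np.log(max(A, Y_FLOOR)) - K
        return -ll

    res = minimize_scalar(neg_profile_ll, bounds=(0.0, ALPHA_MAX),
                          method="bounded", options={"xatol": 1e-10})
    alpha = float(res.x)
    S = np.exp(-alpha * x).sum()
    ll_terms = 0.0
    yN, yR = (Kn / S) * np.exp(-alpha * x), (Kr / S) * np.exp(-alpha * x)
    ll_terms = float(np.sum(kn * np.log(np.maximum(yN, Y_FLOOR)) - yN)
                     + np.sum(kr * np.log(np.maximum(yR, Y_FLOOR)) - yR))
    return TuningFit(A_N=float(Kn / S), A_R=float(Kr / S), alpha=alpha,
                     converged=bool(res.success), loglik=ll_terms)


def poisson_loglik(fit: TuningFit, novel_counts, repeated_counts, ranks) -> float:
    """Poisson log-likelihood (up to the k! constant) of counts under a fit."""
    x = np.asarray(ranks, dtype=float)
    ll = 0.0
    for k, cond in ((np.asarray(novel_counts, float), "novel"),
                    (np.asarray(repeated_counts, float), "repeated")):
        y = np.maximum(fit.predict(x, cond), Y_FLOOR)
        ll += float(np.sum(k * np.log(y) - y))
    return ll


def fit_population(pop: Pseudopopulation,
                   window: tuple[float, float] = (100.0, 500.0)) -> PopulationFit:
    """Rank images and fit the tuning model for every unit."""
    sl_counts = window_rates(pop.counts, pop.bin_edges, window)
    # back to raw window counts (window_rates returns spikes/s)
    duration_s = _window_duration_s(pop.bin_edges, window)
    counts = np.rint(sl_counts * duration_s).astype(int)
    fits, ranks = [], np.zeros((pop.n_units, pop.n_pseudoimages), dtype=int)
    for u in range(pop.n_units):
        ranks[u] = rank_images(counts[u, :, 0], counts[u, :, 1])
        fits.append(fit_tuning(counts[u, :, 0], counts[u, :, 1], ranks[u]))
    return PopulationFit(fits=fits, ranks=ranks,
                         memorability=pop.memorability, window=tuple(window))


def _window_duration_s(bin_edges, window) -> float:
    from .screen import window_slice
    sl = window_slice(bin_edges, window)
    return float(bin_edges[sl.stop] - bin_edges[sl.start]) / 1000.0


def apply_threshold(fit: TuningFit, ranks: np.ndarray, spec: ThresholdSpec
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Predicted (novel, repeated) counts after the threshold modification.

    Ranks at or beyond the cutoff have both curves replaced by the
    repeated-curve value at the cutoff rank (mode="flat", the default), so
    the tail carries neither selectivity nor memory information.
    mode="per_rank" instead replaces both curves by each rank's own
    repeated value (tail keeps tuning but loses memory).
    """
    x = np.asarray(ranks)
    yN = fit.predict(x, "novel")
    yR = fit.predict(x, "repeated")
    n = len(x)
    cutoff = spec.cutoff_rank(n)
    tail = x >= cutoff
    if spec.mode == "flat":
        floor = float(fit.A_R * np.exp(-fit.alpha * cutoff))
        yN = np.where(tail, floor, yN)
        yR = np.where(tail, floor, yR)
    else:
        yN = np.where(tail, yR, yN)
    return yN, yR


def predicted_counts(popfit: PopulationFit, spec: ThresholdSpec | None = None
                     ) -> np.ndarray:
    """Expected (U, P, 2) window counts under the (optionally thresholded) fits."""
    U, P = popfit.ranks.shape
    y = np.zeros((U, P, 2))
    for u, fit in enumerate(popfit.fits):
        if spec is None:
            y[u, :, 0] = fit.predict(popfit.ranks[u], "novel")
            y[u, :, 1] = fit.predict(popfit.ranks[u], "repeated")
        else:
            y[u, :, 0], y[u, :, 1] = apply_threshold(fit, popfit.ranks[u], spec)
    if np.any(y < 0):
        raise ValueError("negative predicted rate")
    return y


def synthesize_from_fits(popfit: PopulationFit, seed: int = 0,
                         threshold: ThresholdSpec | None = None
                         ) -> Pseudopopulation:
    """Poisson-resample a synthetic pseudopopulation from the fitted curves.

    Each unit/image/condition count is drawn Poisson(y(x; M)); memorability
    labels carry over from the source images.  The result is a single-bin
    pseudopopulation spanning the fit window.
    """
    y = predicted_counts(popfit, threshold)
    rng = substream(seed, "synthesize_from_fits")
    counts = rng.poisson(y)[..., None]  # (U, P, 2, 1)
    mb_bin = np.clip((popfit.memorability * 10).astype(int), 0, 9)
    return Pseudopopulation(
        unit_ids=[f"synth{u:04d}" for u in range(y.shape[0])],
        counts=counts.astype(np.int64),
        bin_edges=np.asarray(popfit.window, dtype=float),
        memorability=popfit.memorability,
        mb_bin=mb_bin,
        n_back=np.zeros(y.shape[1], dtype=int),
    )


def threshold_sweep(popfit: PopulationFit, fractions: Sequence[float],
                    n_folds: int = 10, seed: int = 0, n_boot: int = 1000,
                    mode: str = "flat") -> pd.DataFrame:
    """Memorability correlation and FLD memory accuracy vs threshold fraction.

    For each fraction a thresholded population is synthesized (the Poisson
    stream is shared across fractions, so fraction 0 reproduces the
    unthresholded population exactly for the same seed) and analyzed for
    (a) the repeated-condition memorability-GMFR correlation with a
    bootstrap CI and (b) cross-validated FLD novel/repeated accuracy.
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    rng_boot = substream(seed, "threshold_sweep_boot")
    P = popfit.ranks.shape[1]
    boot_idx = rng_boot.integers(0, P, size=(n_boot, P))
    rows = []
    for frac in fractions:
        spec = ThresholdSpec(float(frac), mode=mode)
        pop = synthesize_from_fits(popfit, seed=seed, threshold=spec)
        table = gmfr(pop, popfit.window)
        res = memorability_correlation(table, "repeated")
        x, yv = table.memorability, table.repeated
        xb, yb = x[boot_idx], yv[boot_idx]
        xc = xb - xb.mean(axis=1, keepdims=True)
        yc = yb - yb.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rb = (xc * yc).sum(axis=1) / denom
        rb = rb[np.isfinite(rb)]
        lo, hi = (np.quantile(rb, [0.025, 0.975]) if rb.size
                  else (np.nan, np.nan))
        cv = cv_performance(pop, "fld", popfit.window, n_folds, seed)
        rows.append({"fraction": float(frac), "r_repeated": res.r,
                     "r_ci_low": float(lo), "r_ci_high": float(hi),
                     "fld_accuracy": cv.mean, "fld_sd": cv.sd})
    return pd.DataFrame(rows)
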
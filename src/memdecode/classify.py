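"""Linear memory decoders: RS and FLD classifiers, d', cross-validation.

A population response vector x (one spike count per unit) is classified
novel or repeated by the sign of f(x) = w . x - b, with the bias set by the
class-mean midpoint rule b = 0.5 * w . (mu_novel + mu_repeated).  Two weight
choices are central:

* the RS (repetition suppression) classifier weights every unit equally,
  w = (1, 1, ..., 1) — a pure population-vigor threshold;
* the FLD classifier uses the Fisher linear discriminant with the
  off-diagonal covariance terms set to zero (too few trials to estimate
  them), w_i = (mu_n,i - mu_r,i) / avg-variance_i, which weights each unit
  in proportion to its d'.

Cross-validation keeps each pseudoimage's novel/repeated pair in the same
fold, with folds stratified by memorability bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .screen import Pseudopopulation, shuffle_alignment, window_rates

logger = logging.getLogger(__name__)

__all__ = [
    "LinearClassifier",
    "UnitMemoryStats",
    "CVResult",
    "unit_dprime",
    "fld_weights",
    "rs_weights",
    "decide",
    "decision_values",
    "make_folds",
    "cv_performance",
    "decoding_timecourse",
    "ranked_fld",
]

VAR_FLOOR_FRACTION = 1e-6  # variance floor relative to the mean unit variance


@dataclass
class LinearClassifier:
    """f(x) = w . x - b with training class summaries."""

    w: np.ndarray
    b: float
    mu_novel: np.ndarray | None = None
    mu_repeated: np.ndarray | None = None
    pooled_var: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)


@dataclass
class UnitMemoryStats:
    """Per-unit sensitivity to memory.

    Positive d' = repetition suppression (the unit fires less on the
    repeated presentation).
    """

    dprime: np.ndarray
    n_zero_sd: int = 0


@dataclass
class CVResult:
    """Cross-validated classification accuracy."""

    fold_accuracy: np.ndarray
    novel_accuracy: float
    repeated_accuracy: float

    @property
    def mean(self) -> float:
        return float(self.fold_accuracy.mean())

    @property
    def sd(self) -> float:
        return float(self.fold_accuracy.std(ddof=1)) if len(self.fold_accuracy) > 1 else 0.0


# ---------------------------------------------------------------------------
# unit statistics and weights
# ---------------------------------------------------------------------------

def _window_counts(pop: Pseudopopulation, window) -> np.ndarray:
    """(U, P, 2) spike-count rates for the window (spikes/s)."""
    return window_rates(pop.counts, pop.bin_edges, window)


def unit_dprime(pop: Pseudopopulation, window=(300.0, 500.0)) -> UnitMemoryStats:
    """d' = (mean novel - mean repeated) / pooled SD per unit.

    Pooled SD = sqrt((var_novel + var_repeated) / 2).  Units with zero
    pooled SD get d' = 0 (logged).
    """
    if pop.n_pseudoimages < 2:
        raise ValueError("need at least 2 pseudoimages")
    r = _window_counts(pop, window)
    mu_n, mu_r = r[:, :, 0].mean(axis=1), r[:, :, 1].mean(axis=1)
    pooled = np.sqrt((r[:, :, 0].var(axis=1, ddof=1)
                      + r[:, :, 1].var(axis=1, ddof=1)) / 2.0)
    zero = pooled == 0
    if zero.any():
        logger.warning("%d units with zero pooled SD get d'=0", int(zero.sum()))
    d = np.where(zero, 0.0, (mu_n - mu_r) / np.where(zero, 1.0, pooled))
    return UnitMemoryStats(dprime=d, n_zero_sd=int(zero.sum()))


def _fit_linear(w: np.ndarray, Xn: np.ndarray, Xr: np.ndarray,
                pooled_var: np.ndarray | None = None) -> LinearClassifier:
    mu_n, mu_r = Xn.mean(axis=0), Xr.mean(axis=0)
    b = 0.5 * float(w @ (mu_n + mu_r))
    return LinearClassifier(w=w, b=b, mu_novel=mu_n, mu_repeated=mu_r,
                            pooled_var=pooled_var)


def fld_weights(Xn: np.ndarray, Xr: np.ndarray) -> LinearClassifier:
    """Diagonal-covariance Fisher discriminant from training responses.

    Xn, Xr: (n_pseudoimages, n_units) novel and repeated response vectors.
    w_i = (mu_n,i - mu_r,i) / sigma_bar^2_i with sigma_bar^2 the
    two-condition average variance (floored at a small epsilon); zero-
    variance units receive weight 0.
    """
    mu_n, mu_r = Xn.mean(axis=0), Xr.mean(axis=0)
    var = 0.5 * (Xn.var(axis=0, ddof=1) + Xr.var(axis=0, ddof=1))
    zero = var == 0
    if zero.any():
        logger.warning("%d zero-variance units get weight 0", int(zero.sum()))
    floor = VAR_FLOOR_FRACTION * max(var.mean(), 1e-300)
    w = np.where(zero, 0.0, (mu_n - mu_r) / np.maximum(var, floor))
    return _fit_linear(w, Xn, Xr, pooled_var=var)


def rs_weights(Xn: np.ndarray, Xr: np.ndarray) -> LinearClassifier:
    """All-ones (population vigor) classifier with midpoint bias."""
    n_units = Xn.shape[1]
    if n_units < 1:
        raise ValueError("need at least one unit")
    return _fit_linear(np.ones(n_units), Xn, Xr)


def decision_values(clf: LinearClassifier, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(clf.w):
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {len(clf.w)} units")
    return X @ clf.w - clf.b


def decide(clf: LinearClassifier, X: np.ndarray) -> np.ndarray:
    """Classify response vectors: f(x) > 0 -> novel, f(x) <= 0 -> repeated.

    The tie f(x) = 0 goes to "repeated" (a rule is needed for integer
    counts; ties are measure-zero for real-valued rates).
    """
    f = decision_values(clf, X)
    return np.where(f > 0, "novel", "repeated")


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def make_folds(pop: Pseudopopulation, n_folds: int, seed: int) -> np.ndarray:
    """Fold id per pseudoimage, stratified by memorability bin.

    A pseudoimage's novel and repeated presentations always share a fold.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = substream(seed, "cv_folds")
    folds = np.zeros(pop.n_pseudoimages, dtype=int)
    start = rng.integers(0, n_folds)
    order = []
    for bin_id in np.unique(pop.mb_bin):
        idx = np.nonzero(pop.mb_bin == bin_id)[0]
        order.extend(rng.permutation(idx))
    for j, p in enumerate(order):
        folds[p] = (start + j) % n_folds
    return folds


def _classifier_factory(spec):
    if callable(spec):
        return spec
    if spec == "fld":
        return fld_weights
    if spec == "rs":
        return rs_weights
    raise ValueError(f"unknown classifier spec {spec!r}")


def cv_performance(pop: Pseudopopulation, classifier="fld",
                   window=(300.0, 500.0), n_folds: int = 10, seed: int = 0,
                   shuffle_alignment_flag: bool = False) -> CVResult:
    """Cross-validated novel/repeated decoding accuracy.

    With ``shuffle_alignment_flag`` the pseudopopulation's alignment by
    memorability is broken (per-unit image permutation) before decoding,
    removing the memorability confound.
    """
    if shuffle_alignment_flag:
        pop = shuffle_alignment(pop, seed)
    fit = _classifier_factory(classifier)
    r = _window_counts(pop, window)  # (U, P, 2)
    Xn, Xr = r[:, :, 0].T, r[:, :, 1].T  # (P, U)
    folds = make_folds(pop, n_folds, seed)
    accs, novel_hits, rep_hits, n_test = [], 0, 0, 0
    for k in range(n_folds):
        test = folds == k
        if test.sum() == 0:
            continue
        clf = fit(Xn[~test], Xr[~test])
        pred_n = decide(clf, Xn[test]) == "novel"
        pred_r = decide(clf, Xr[test]) == "repeated"
        accs.append((pred_n.sum() + pred_r.sum()) / (2.0 * test.sum()))
        novel_hits += pred_n.sum()
        rep_hits += pred_r.sum()
        n_test += test.sum()
    return CVResult(fold_accuracy=np.asarray(accs),
                    novel_accuracy=novel_hits / n_test,
                    repeated_accuracy=rep_hits / n_test)


def decoding_timecourse(pop: Pseudopopulation, classifier="fld",
                        window_len: float = 150.0, step: float = 20.0,
                        n_folds: int = 10, seed: int = 0,
                        shuffle_alignment_flag: bool = False) -> pd.DataFrame:
    """cv_performance in sliding windows across the recorded bins."""
    if shuffle_alignment_flag:
        pop = shuffle_alignment(pop, seed)
    edges = pop.bin_edges
    rows = []
    t0 = edges[0]
    while t0 + window_len <= edges[-1] + 1e-9:
        res = cv_performance(pop, classifier, (t0, t0 + window_len),
                             n_folds, seed)
        rows.append({"t_start": t0, "t_end": t0 + window_len,
                     "accuracy": res.mean, "sd": res.sd,
                     "novel_accuracy": res.novel_accuracy,
                     "repeated_accuracy": res.repeated_accuracy})
        t0 += step
    return pd.DataFrame(rows)


def ranked_fld(pop: Pseudopopulation, window=(300.0, 500.0),
               removal_fractions=(0.0, 0.1, 0.25, 0.5, 0.75),
               n_folds: int = 10, seed: int = 0,
               remove_from: str = "top") -> pd.DataFrame:
    """FLD accuracy after removing units ranked by their training weights.

    Within each CV fold, units are ranked by the signed FLD weight computed
    on the training data only; a fraction is removed from the chosen end
    ("top" = most positive weight = most repetition-suppressed, "bottom" =
    most negative = repetition-enhanced), and weights and threshold are
    recomputed on the remaining units before testing.
    """
    if remove_from not in ("top", "bottom"):
        raise ValueError("remove_from must be 'top' or 'bottom'")
    fractions = np.asarray(sorted(removal_fractions), dtype=float)
    if np.any((fractions < 0) | (fractions >= 1.0)):
        raise ValueError("removal fractions must lie in [0, 1)")
    r = _window_counts(pop, window)
    Xn, Xr = r[:, :, 0].T, r[:, :, 1].T
    n_units = Xn.shape[1]
    folds = make_folds(pop, n_folds, seed)
    acc = np.zeros((len(fractions), n_folds))
    for k in range(n_folds):
        test = folds == k
        rank_clf = fld_weights(Xn[~test], Xr[~test])
        order = np.argsort(rank_clf.w)  # ascending: most enhanced first
        for i, frac in enumerate(fractions):
            n_remove = int(round(frac * n_units))
            if n_remove >= n_units:
                raise ValueError("cannot remove all units")
            keep = order[:n_units - n_remove] if remove_from == "top" \
                else order[n_remove:]
            keep = np.sort(keep)
            clf = fld_weights(Xn[~test][:, keep], Xr[~test][:, keep])
            pred_n = decide(clf, Xn[test][:, keep]) == "novel"
            pred_r = decide(clf, Xr[test][:, keep]) == "repeated"
            acc[i, k] = (pred_n.sum() + pred_r.sum()) / (2.0 * test.sum())
    return pd.DataFrame({"fraction_removed": fractions,
                         "accuracy": acc.mean(axis=1),
                         "sd": acc.std(axis=1, ddof=1)})
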
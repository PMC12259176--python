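"""The RS-MB plane: rotated decoders, PQ, and behavior prediction.

Memory and memorability both modulate population vigor, so a pure
population-vigor (RS) decoder is confounded by memorability: highly
memorable repeated images fire vigorously and get misclassified as novel,
the opposite of behavior.  The fix explored here rotates the decoding axis
within the (non-orthogonal) plane spanned by

* the RS axis, the normalized all-ones vector 1-hat, and
* the MB axis, the unit vector along the prototype difference
  w_MB = mu_high-memorability - mu_low-memorability,

using the family::

    W(theta) = (cos(theta) - cot(gamma) sin(theta)) 1-hat
             + (csc(gamma) sin(theta)) w-hat_MB

where gamma is the angle between the axes.  W(theta) is unit norm, makes
angle theta with 1-hat, and W(gamma + 90 deg) is the memorability-blind
direction.  The prediction-quality statistic PQ = 1 - delta_theta / 90
measures the alignment between the slope of decoded accuracy vs
memorability and the slope of behavioral accuracy vs memorability
(delta_theta is the angular difference of the two regression slopes,
reflected to [0, 90]); PQ is 1 for perfectly aligned slopes and 0 for
perpendicular ones.  Slopes are fit on accuracies as fractions in [0, 1]
against memorability bin centers in [0, 1], which keeps the two axes on
comparable scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import LinearClassifier, _window_counts, decide, make_folds
from .screen import Pseudopopulation
from .syndata import ChoiceSet, MemImage, TrialSpec

logger = logging.getLogger(__name__)

__all__ = [
    "PlaneGeometry",
    "PQResult",
    "BehaviorPrediction",
    "mb_weights",
    "plane_gamma",
    "rotated_weights",
    "project_plane",
    "predict_behavior",
    "behavior_by_quartile",
    "pq",
    "rescale_predictions",
    "theta_sweep",
]


@dataclass(frozen=True)
class PlaneGeometry:
    """Unit basis vectors of the RS-MB plane and the angle between them."""

    one_hat: np.ndarray
    mb_hat: np.ndarray
    gamma_deg: float


@dataclass(frozen=True)
class PQResult:
    """Slope alignment between behavior and a decoder's predictions."""

    behavior_slope_novel: float
    behavior_slope_repeated: float
    predicted_slope_novel: float
    predicted_slope_repeated: float
    delta_theta_novel: float
    delta_theta_repeated: float
    pq_novel: float
    pq_repeated: float
    pq: float  # mean of the two conditions


@dataclass
class BehaviorPrediction:
    """Rescaled per-quartile predicted percent correct."""

    predicted_pct: np.ndarray  # rescaled, clamped to [0, 100]
    behavior_pct: np.ndarray
    factor: float
    clamped: np.ndarray  # bool flags


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def mb_weights(Xn: np.ndarray, Xr: np.ndarray, memorability: np.ndarray,
               presentations: str = "pooled") -> LinearClassifier:
    """Prototype memorability classifier from a training split.

    w = mean response to the top 50% of memorability scores minus the mean
    response to the bottom 50% (median split on the training scores);
    presentations pooled over novel and repeated by default ("novel" /
    "repeated" restrict to one).  Bias from the midpoint rule between the
    high and low prototypes.
    """
    memorability = np.asarray(memorability, dtype=float)
    if np.all(memorability == memorability[0]):
        raise ValueError("all memorability scores identical: median split undefined")
    med = np.median(memorability)
    high = memorability > med
    low = ~high
    if not high.any() or not low.any():
        # ties at the median: break by rank
        order = np.argsort(memorability, kind="stable")
        high = np.zeros(len(memorability), dtype=bool)
        high[order[len(order) // 2:]] = True
        low = ~high
    if presentations == "pooled":
        stack_high = np.vstack([Xn[high], Xr[high]])
        stack_low = np.vstack([Xn[low], Xr[low]])
    elif presentations == "novel":
        stack_high, stack_low = Xn[high], Xn[low]
    elif presentations == "repeated":
        stack_high, stack_low = Xr[high], Xr[low]
    else:
        raise ValueError("presentations must be pooled/novel/repeated")
    mu_h, mu_l = stack_high.mean(axis=0), stack_low.mean(axis=0)
    w = mu_h - mu_l
    b = 0.5 * float(w @ (mu_h + mu_l))
    return LinearClassifier(w=w, b=b, mu_novel=mu_h, mu_repeated=mu_l)


def plane_gamma(w_rs: np.ndarray, w_mb: np.ndarray) -> PlaneGeometry:
    """Angle gamma between the RS and MB axes, with unit basis vectors."""
    w_rs = np.asarray(w_rs, dtype=float)
    w_mb = np.asarray(w_mb, dtype=float)
    n_rs, n_mb = np.linalg.norm(w_rs), np.linalg.norm(w_mb)
    if n_rs == 0 or n_mb == 0:
        raise ValueError("zero vector cannot define the plane")
    one_hat, mb_hat = w_rs / n_rs, w_mb / n_mb
    cosg = float(np.clip(one_hat @ mb_hat, -1.0, 1.0))
    gamma = float(np.degrees(np.arccos(cosg)))
    if gamma < 1e-6 or gamma > 180 - 1e-6:
        raise ValueError("RS and MB axes are collinear: plane degenerate")
    return PlaneGeometry(one_hat=one_hat, mb_hat=mb_hat, gamma_deg=gamma)


def rotated_weights(theta_deg: float, geom: PlaneGeometry) -> np.ndarray:
    """W(theta): unit-norm decoder at angle theta from the RS axis.

    theta = 0 returns 1-hat; theta = gamma returns w-hat_MB.
    """
    th = np.radians(theta_deg)
    g = np.radians(geom.gamma_deg)
    a = np.cos(th) - np.sin(th) / np.tan(g)
    c = np.sin(th) / np.sin(g)
    return a * geom.one_hat + c * geom.mb_hat


# ---------------------------------------------------------------------------
# plane projections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EllipseSpec:
    """One-standard-deviation contour of a projected point group."""

    group: tuple
    center: np.ndarray
    axis_lengths: np.ndarray  # sqrt of covariance eigenvalues, major first
    angle_deg: float
    n: int


def project_plane(pop: Pseudopopulation, geom: PlaneGeometry,
                  window=(100.0, 500.0), rotate_view: float = 45.0
                  ) -> tuple[pd.DataFrame, list[EllipseSpec]]:
    """Project responses onto the (oblique) RS-MB plane coordinates.

    The plane spanned by 1-hat and w-hat_MB is given an orthonormal basis
    (first axis along 1-hat), so in-plane distances are faithful; the view
    is then rotated by ``rotate_view`` degrees for display.  Groups are
    novelty x memorability quartile (8 groups); each group with >= 3
    points gets a 1-SD covariance ellipse from the eigen-decomposition.
    """
    r = _window_counts(pop, window)  # (U, P, 2)
    g = np.radians(geom.gamma_deg)
    # Gram-Schmidt: e1 along RS, e2 the in-plane direction orthogonal to it
    e1 = geom.one_hat
    e2 = (geom.mb_hat - np.cos(g) * e1) / np.sin(g)
    rot = np.radians(rotate_view)
    R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
    q = np.quantile(pop.memorability, [0.25, 0.5, 0.75])
    quartile = np.digitize(pop.memorability, q)
    rows = []
    for cond_idx, cond in enumerate(("novel", "repeated")):
        X = r[:, :, cond_idx].T  # (P, U)
        proj = np.stack([X @ e1, X @ e2], axis=1)
        coords = (R @ proj.T).T
        for p in range(X.shape[0]):
            rows.append({"condition": cond, "quartile": int(quartile[p]),
                         "memorability": pop.memorability[p],
                         "c1": coords[p, 0], "c2": coords[p, 1]})
    df = pd.DataFrame(rows)
    ellipses = []
    for (cond, qt), grp in df.groupby(["condition", "quartile"]):
        if len(grp) < 3:
            logger.warning("group (%s, q%d) has <3 points: no ellipse", cond, qt)
            continue
        pts = grp[["c1", "c2"]].to_numpy()
        cov = np.cov(pts.T)
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        ellipses.append(EllipseSpec(
            group=(cond, int(qt)), center=pts.mean(axis=0),
            axis_lengths=np.sqrt(np.maximum(vals, 0.0)),
            angle_deg=float(np.degrees(np.arctan2(vecs[1, 0], vecs[0, 0]))),
            n=len(grp)))
    return df, ellipses


# ---------------------------------------------------------------------------
# behavior prediction and PQ
# ---------------------------------------------------------------------------

def predict_behavior(Xn: np.ndarray, Xr: np.ndarray, memorability: np.ndarray,
                     clf: LinearClassifier,
                     quartile_boundaries: np.ndarray) -> np.ndarray:
    """Fraction of held-out pseudoimages classified correctly per quartile.

    Returns an array of shape (4, 2): accuracy per memorability quartile
    for the novel (column 0) and repeated (column 1) presentations.
    """
    quartile = np.digitize(memorability, quartile_boundaries)
    out = np.full((4, 2), np.nan)
    pred_n = decide(clf, Xn) == "novel"
    pred_r = decide(clf, Xr) == "repeated"
    for qt in range(4):
        sel = quartile == qt
        if not sel.any():
            raise ValueError(f"memorability quartile {qt} is empty")
        out[qt, 0] = pred_n[sel].mean()
        out[qt, 1] = pred_r[sel].mean()
    return out


def behavior_by_quartile(choices: ChoiceSet, sequence: list[TrialSpec],
                         image_set: list[MemImage],
                         quartile_boundaries: np.ndarray) -> np.ndarray:
    """Observed percent-correct-by-quartile, shape (4, 2), as fractions."""
    mem = {im.image_id: im.memorability for im in image_set}
    m = np.array([mem[tr.image_id] for tr in sequence])
    is_rep = np.array([tr.novelty == "repeated" for tr in sequence])
    quartile = np.digitize(m, quartile_boundaries)
    out = np.full((4, 2), np.nan)
    for qt in range(4):
        for c, sel_cond in enumerate((~is_rep, is_rep)):
            sel = (quartile == qt) & sel_cond
            if sel.any():
                out[qt, c] = choices.correct[sel].mean()
    return out


def _slope_angle_deg(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope = float(np.polyfit(x, y, 1)[0])
    return slope, float(np.degrees(np.arctan(slope)))


def pq(bin_centers: np.ndarray, behavior: np.ndarray,
       predicted: np.ndarray) -> PQResult:
    """Prediction quality PQ = 1 - delta_theta / 90 between two slope fits.

    ``behavior`` and ``predicted`` have shape (n_bins, 2) with columns
    (novel, repeated), accuracies as fractions.  Least-squares lines are
    fit per condition; the angular difference of the slopes is reflected
    into [0, 90] (slopes 180 degrees apart are equivalent) and averaged
    over conditions.
    """
    bin_centers = np.asarray(bin_centers, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if len(bin_centers) < 2:
        raise ValueError("need at least 2 bins")
    slopes_b, slopes_p, dthetas, pqs = [], [], [], []
    for c in range(2):
        sb, ab = _slope_angle_deg(bin_centers, behavior[:, c])
        sp, ap = _slope_angle_deg(bin_centers, predicted[:, c])
        d = abs(ab - ap)
        if d > 90.0:
            d = 180.0 - d
        slopes_b.append(sb)
        slopes_p.append(sp)
        dthetas.append(d)
        pqs.append(1.0 - d / 90.0)
    return PQResult(
        behavior_slope_novel=slopes_b[0], behavior_slope_repeated=slopes_b[1],
        predicted_slope_novel=slopes_p[0], predicted_slope_repeated=slopes_p[1],
        delta_theta_novel=dthetas[0], delta_theta_repeated=dthetas[1],
        pq_novel=pqs[0], pq_repeated=pqs[1],
        pq=float(np.mean(pqs)))


def rescale_predictions(predicted_pct: np.ndarray, behavior_pct: np.ndarray
                        ) -> BehaviorPrediction:
    """Single multiplicative rescaling of predictions toward behavior.

    factor = argmin_c sum((c * pred - behavior)^2) = sum(p*b) / sum(p^2)
    (does not change the slope sign); rescaled values above 100% are
    clamped to 100 with flags.
    """
    p = np.asarray(predicted_pct, dtype=float)
    b = np.asarray(behavior_pct, dtype=float)
    denom = float(np.sum(p * p))
    if denom == 0:
        raise ValueError("all-zero predictions cannot be rescaled")
    factor = float(np.sum(p * b) / denom)
    scaled = factor * p
    clamped = scaled > 100.0
    return BehaviorPrediction(predicted_pct=np.minimum(scaled, 100.0),
                              behavior_pct=b, factor=factor, clamped=clamped)


# ---------------------------------------------------------------------------
# theta sweep
# ---------------------------------------------------------------------------

def theta_sweep(pop: Pseudopopulation, behavior: np.ndarray,
                window=(100.0, 500.0), theta_grid: np.ndarray | None = None,
                n_folds: int = 10, seed: int = 0,
                presentations: str = "pooled") -> dict:
    """Sweep rotated decoders W(theta) over the RS-MB plane.

    ``behavior`` is the (4, 2) per-quartile behavioral accuracy (fractions,
    columns novel/repeated).  For each theta in the grid (default 0..179
    in 1-degree steps), the decoder is trained per cross-validation fold
    (MB prototype and bias from training data only), held-out pseudoimages
    are classified, per-quartile prediction accuracies are aggregated over
    folds, and PQ against behavior plus overall memory accuracy are
    recorded.  Returns the per-theta table, the best-PQ theta (ties broken
    toward orthogonality to the MB axis), and the full-data plane geometry.
    """
    if theta_grid is None:
        # (-90, 90]: every line of the plane once, each with the polarity
        # closest to the RS axis (W . 1-hat >= 0).  Sweeping this domain
        # from one end to the other passes MB, RS, and the memorability-
        # blind direction in a single arc.
        theta_grid = np.arange(-89.0, 91.0, 1.0)
    theta_grid = np.asarray(theta_grid, dtype=float)
    step = float(np.median(np.diff(np.sort(theta_grid)))) if len(theta_grid) > 1 else 0.0
    if theta_grid.max() - theta_grid.min() + step < 179.5:
        logger.warning("theta grid spans less than 180 degrees; "
                       "sweep may miss the peak")
    r = _window_counts(pop, window)
    Xn, Xr = r[:, :, 0].T, r[:, :, 1].T
    n_units = Xn.shape[1]
    one = np.ones(n_units)
    quartile_boundaries = np.quantile(pop.memorability, [0.25, 0.5, 0.75])
    quartile = np.digitize(pop.memorability, quartile_boundaries)
    folds = make_folds(pop, n_folds, seed)
    nT = len(theta_grid)
    hits = np.zeros((nT, 4, 2))
    totals = np.zeros((nT, 4, 2))
    correct_all = np.zeros(nT)
    total_all = 0.0
    for k in range(n_folds):
        test = folds == k
        if not test.any():
            continue
        mb = mb_weights(Xn[~test], Xr[~test], pop.memorability[~test],
                        presentations=presentations)
        geom_k = plane_gamma(one, mb.w)
        th = np.radians(theta_grid)
        g = np.radians(geom_k.gamma_deg)
        a = np.cos(th) - np.sin(th) / np.tan(g)
        c = np.sin(th) / np.sin(g)
        W = np.outer(geom_k.one_hat, a) + np.outer(geom_k.mb_hat, c)  # (U, nT)
        mu_n = Xn[~test].mean(axis=0)
        mu_r = Xr[~test].mean(axis=0)
        b = 0.5 * (mu_n + mu_r) @ W  # (nT,)
        fn = Xn[test] @ W - b  # (n_test, nT)
        fr = Xr[test] @ W - b
        pred_n = fn > 0  # correct when decoded novel
        pred_r = fr <= 0  # correct when decoded repeated
        qt_test = quartile[test]
        for qt in range(4):
            sel = qt_test == qt
            hits[:, qt, 0] += pred_n[sel].sum(axis=0)
            hits[:, qt, 1] += pred_r[sel].sum(axis=0)
            totals[:, qt, 0] += sel.sum()
            totals[:, qt, 1] += sel.sum()
        correct_all += pred_n.sum(axis=0) + pred_r.sum(axis=0)
        total_all += 2.0 * test.sum()
    acc_by_qt = hits / totals  # (nT, 4, 2)
    accuracy = correct_all / total_all
    centers = _quartile_centers(pop.memorability, quartile_boundaries)
    results = []
    for i, theta in enumerate(theta_grid):
        res = pq(centers, behavior, acc_by_qt[i])
        results.append({"theta_deg": float(theta), "pq_novel": res.pq_novel,
                        "pq_repeated": res.pq_repeated, "pq": res.pq,
                        "accuracy": float(accuracy[i])})
    table = pd.DataFrame(results)
    geom = plane_gamma(one, mb_weights(Xn, Xr, pop.memorability,
                                       presentations=presentations).w)
    best = table["pq"].to_numpy()
    best_idx = np.flatnonzero(best == best.max())
    if len(best_idx) > 1:
        ortho = (geom.gamma_deg + 90.0) % 180.0
        best_idx = [best_idx[np.argmin(np.abs(theta_grid[best_idx] - ortho))]]
    best_theta = float(theta_grid[int(best_idx[0])])
    return {"table": table, "best_theta": best_theta, "geometry": geom,
            "accuracy_by_quartile": acc_by_qt, "bin_centers": centers}


def _quartile_centers(memorability: np.ndarray, boundaries: np.ndarray
                      ) -> np.ndarray:
    quartile = np.digitize(memorability, boundaries)
    return np.array([memorability[quartile == qt].mean() for qt in range(4)])
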
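"""Unit/session inclusion filters and pseudopopulation assembly.

Units recorded in separate sessions cannot be analyzed as a simultaneous
population, so sessions are concatenated into a *pseudopopulation*: trials
are aligned across sessions into "pseudoimages" that share a memorability
bin and an n-back stratum, each cell holding one real image's novel and
repeated presentations for one unit.  Before assembly, units must pass a
responsiveness screen (paired t-test of post- vs pre-stimulus counts) and
sessions a baseline-stability screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from ._rng import substream
from .syndata import SessionRecording

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenReport",
    "Pseudopopulation",
    "window_slice",
    "window_rates",
    "responsiveness_filter",
    "stability_filter",
    "apply_screen",
    "assemble_pseudopopulation",
    "shuffle_alignment",
]


def window_slice(bin_edges: np.ndarray, window: tuple[float, float]) -> slice:
    """Indices of bins fully contained in [window[0], window[1]) ms."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must have positive duration")
    starts, ends = bin_edges[:-1], bin_edges[1:]
    inside = np.nonzero((starts >= lo - 1e-9) & (ends <= hi + 1e-9))[0]
    if inside.size == 0:
        raise ValueError(f"window {window} contains no complete bins")
    return slice(int(inside[0]), int(inside[-1]) + 1)


def window_rates(counts: np.ndarray, bin_edges: np.ndarray,
                 window: tuple[float, float]) -> np.ndarray:
    """Sum counts over the window and convert to spikes/s (last axis = bins)."""
    sl = window_slice(bin_edges, window)
    duration_s = float(bin_edges[sl.stop] - bin_edges[sl.start]) / 1000.0
    return counts[..., sl].sum(axis=-1) / duration_s


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenReport:
    """Outcome of the unit responsiveness and session stability screens."""

    unit_pvalues: np.ndarray | None = None
    include: np.ndarray | None = None  # per-unit flags
    session_stable: bool | None = None
    fold_change: float | None = None
    baseline_p: float | None = None
    n_excluded_units: int = 0
    reasons: dict = field(default_factory=dict)


def responsiveness_filter(session: SessionRecording,
                          post_window: tuple[float, float] = (50.0, 350.0),
                          pre_window: tuple[float, float] = (-300.0, 0.0),
                          alpha: float = 0.10) -> ScreenReport:
    """Include units whose post-stimulus rate differs from baseline.

    Per unit, a paired two-sided t-test compares the post-window against the
    pre-window firing rate across all trials; units with p < alpha are
    included.  Degenerate units (zero-variance differences) get p = 1.
    """
    post = window_rates(session.counts, session.bin_edges, post_window)
    pre = window_rates(session.counts, session.bin_edges, pre_window)
    pvals = np.ones(session.n_units)
    for u in range(session.n_units):
        diff = post[u] - pre[u]
        if np.allclose(diff.std(), 0.0):
            # degenerate: constant difference -> p = 1 when flat (excluded),
            # p = 0 when a nonzero shift on every trial (perfect responder)
            pvals[u] = 1.0 if np.allclose(diff.mean(), 0.0) else 0.0
            logger.debug("unit %s: zero-variance pre/post difference, p=%g",
                         session.unit_ids[u], pvals[u])
            continue
        pvals[u] = stats.ttest_rel(post[u], pre[u]).pvalue
    include = pvals < alpha
    return ScreenReport(unit_pvalues=pvals, include=include,
                        n_excluded_units=int((~include).sum()),
                        reasons={"responsiveness": int((~include).sum())})


def stability_filter(session: SessionRecording,
                     baseline_window: tuple[float, float] = (-500.0, 0.0),
                     fold_limit: float = 2.0,
                     baseline_alpha: float = 0.01) -> ScreenReport:
    """Session-level stability screen on pre-stimulus baseline rates.

    Fails if (a) the overall baseline rate in the first fifth of trials
    differs from the last fifth by more than ``fold_limit``, or (b) baseline
    rates preceding novel vs repeated images differ (two-sided t-test at
    ``baseline_alpha``).
    """
    novelty = np.array([tr.novelty for tr in session.trials])
    if (novelty == "novel").sum() < 2 or (novelty == "repeated").sum() < 2:
        raise ValueError("need at least 2 trials of each novelty")
    base = window_rates(session.counts, session.bin_edges, baseline_window)
    per_trial = base.mean(axis=0)  # mean over units
    fifth = max(len(per_trial) // 5, 1)
    first, last = per_trial[:fifth].mean(), per_trial[-fifth:].mean()
    eps = 1e-12
    fold = (max(first, last) + eps) / (min(first, last) + eps)
    p = stats.ttest_ind(per_trial[novelty == "novel"],
                        per_trial[novelty == "repeated"]).pvalue
    stable = (fold <= fold_limit) and (p >= baseline_alpha)
    reasons = {}
    if fold > fold_limit:
        reasons["baseline_fold_change"] = fold
    if p < baseline_alpha:
        reasons["baseline_novelty_difference"] = p
    return ScreenReport(session_stable=bool(stable), fold_change=float(fold),
                        baseline_p=float(p), reasons=reasons)


def apply_screen(session: SessionRecording, report: ScreenReport) -> SessionRecording:
    """Return a copy of the session keeping only the included units."""
    keep = np.asarray(report.include, dtype=bool)
    return replace(session,
                   unit_ids=[uid for uid, k in zip(session.unit_ids, keep) if k],
                   counts=session.counts[keep])


# ---------------------------------------------------------------------------
# pseudopopulation
# ---------------------------------------------------------------------------

@dataclass
class Pseudopopulation:
    """Units x pseudoimages x {novel, repeated} x time-bins spike counts.

    Axis 2 index 0 is the novel presentation, index 1 the repeated one.
    ``memorability`` is the representative score of each pseudoimage (mean
    of the contributing real images); ``n_back`` the shared n-back stratum.
    """

    unit_ids: list[str]
    counts: np.ndarray  # (U, P, 2, B)
    bin_edges: np.ndarray
    memorability: np.ndarray  # (P,)
    mb_bin: np.ndarray  # (P,) int
    n_back: np.ndarray  # (P,) int
    unit_session: np.ndarray | None = None  # (U,) session index per unit
    source_images: np.ndarray | None = None  # (S, P) contributing image ids

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.memorability = np.asarray(self.memorability, dtype=float)
        if self.counts.ndim != 4 or self.counts.shape[2] != 2:
            raise ValueError("counts must have shape (units, pseudoimages, 2, bins)")
        if self.counts.shape[1] != len(self.memorability):
            raise ValueError("memorability length must match pseudoimage count")

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_pseudoimages(self) -> int:
        return self.counts.shape[1]


def _eligible_pairs(session: SessionRecording):
    """Complete on-target (novel, repeated) trial-index pairs per image."""
    novel_idx: dict[str, int] = {}
    pairs = []
    for t, tr in enumerate(session.trials):
        if tr.novelty == "novel":
            novel_idx[tr.image_id] = t
        elif tr.on_target and tr.image_id in novel_idx:
            pairs.append((tr.image_id, novel_idx[tr.image_id], t, tr.n_back))
    return pairs


def assemble_pseudopopulation(sessions: Sequence[SessionRecording],
                              mb_bins: int = 10,
                              seed: int = 0,
                              drop_empty_strata: bool = False) -> Pseudopopulation:
    """Concatenate sessions into an aligned pseudopopulation.

    Image pairs are stratified by (memorability bin, n-back level); within
    each stratum the pseudoimage count is the minimum eligible count across
    sessions, with excess pairs dropped uniformly at random (seeded).  A
    stratum empty in some session is an error unless ``drop_empty_strata``.
    """
    if not sessions:
        raise ValueError("need at least one session")
    edges0 = sessions[0].bin_edges
    for s in sessions[1:]:
        if not np.allclose(s.bin_edges, edges0):
            raise ValueError("sessions must share bin edges")
    rng = substream(seed, "assemble")
    bin_edges_mb = np.linspace(0.0, 1.0, mb_bins + 1)

    def mb_bin_of(score: float) -> int:
        return min(int(np.searchsorted(bin_edges_mb, score, side="right") - 1),
                   mb_bins - 1)

    per_session = []
    all_strata: set[tuple[int, int]] = set()
    for s in sessions:
        strata: dict[tuple[int, int], list] = {}
        for image_id, i_nov, i_rep, nb in _eligible_pairs(s):
            key = (mb_bin_of(s.memorability[image_id]), nb)
            strata.setdefault(key, []).append((image_id, i_nov, i_rep))
        per_session.append(strata)
        all_strata.update(strata)

    stratum_counts = {}
    for key in sorted(all_strata):
        counts = [len(st.get(key, ())) for st in per_session]
        c = min(counts)
        if c == 0:
            if drop_empty_strata:
                continue
            raise ValueError(f"stratum {key} empty in at least one session")
        stratum_counts[key] = c
    if not stratum_counts:
        raise ValueError("no stratum is populated in every session")

    # choose which pairs each session contributes, seeded
    chosen = [{} for _ in sessions]
    for key, c in stratum_counts.items():
        for k, strata in enumerate(per_session):
            pool = strata[key]
            idx = rng.permutation(len(pool))[:c]
            chosen[k][key] = [pool[i] for i in idx]

    n_p = sum(stratum_counts.values())
    n_bins = len(edges0) - 1
    unit_ids, unit_session = [], []
    for k, s in enumerate(sessions):
        unit_ids.extend(f"s{k}_{uid}" for uid in s.unit_ids)
        unit_session.extend([k] * s.n_units)

    counts = np.zeros((len(unit_ids), n_p, 2, n_bins), dtype=sessions[0].counts.dtype)
    memorability = np.zeros(n_p)
    mb_bin = np.zeros(n_p, dtype=int)
    n_back = np.zeros(n_p, dtype=int)
    source = np.empty((len(sessions), n_p), dtype=object)
    p = 0
    for key in sorted(stratum_counts):
        for j in range(stratum_counts[key]):
            scores = []
            u0 = 0
            for k, s in enumerate(sessions):
                image_id, i_nov, i_rep = chosen[k][key][j]
                counts[u0:u0 + s.n_units, p, 0] = s.counts[:, i_nov]
                counts[u0:u0 + s.n_units, p, 1] = s.counts[:, i_rep]
                scores.append(s.memorability[image_id])
                source[k, p] = image_id
                u0 += s.n_units
            memorability[p] = float(np.mean(scores))
            mb_bin[p], n_back[p] = key
            p += 1
    return Pseudopopulation(unit_ids=unit_ids, counts=counts, bin_edges=edges0,
                            memorability=memorability, mb_bin=mb_bin,
                            n_back=n_back,
                            unit_session=np.asarray(unit_session),
                            source_images=source)


def shuffle_alignment(pop: Pseudopopulation, seed: int = 0) -> Pseudopopulation:
    """Break the across-unit memorability alignment of the pseudopopulation.

    Within each unit independently, the assignment of real images to
    pseudoimages is permuted (novel/repeated pairs travel together), so
    every pseudoimage becomes a random collection of images and the
    memorability labels no longer align with any unit's responses.
    """
    rng = substream(seed, "shuffle_alignment")
    counts = pop.counts.copy()
    for u in range(pop.n_units):
        perm = rng.permutation(pop.n_pseudoimages)
        counts[u] = pop.counts[u, perm]
    return replace(pop, counts=counts)
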
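"""Seeded synthetic data for single-exposure visual familiarity experiments.

This module generates the raw material the analysis pipeline consumes:

* a set of images, each carrying a *memorability* score in [0, 1] — the
  image-intrinsic probability of being correctly remembered;
* a two-presentation trial sequence in which every image is shown exactly
  twice (once novel, once repeated) with controlled n-back gaps;
* heterogeneous visually tuned units whose evoked rate may scale with
  memorability ("ITC-like") or not ("HC-like"), with repetition suppression
  whose magnitude grows with memorability in both configurations;
* Poisson spike counts in time bins for every unit x trial;
* behavioral choices whose accuracy increases with memorability for
  repeated images.

The generative model
--------------------
Each unit has a private ranking of the images (its tuning curve).  The
expected *novel* evoked rate of unit *u* for image *i* with memorability
``m`` is::

    evoked_novel = peak_amplitude * exp(-selectivity * rank_u(i))
                   * (1 + memorability_gain * (m - 0.5))

On the repeated presentation, from ``memory_onset`` onward, the evoked rate
is multiplied by a suppression factor::

    evoked_rep = s_b ** (1 + kappa * (m - 0.5))
                 * evoked_novel * (evoked_novel / ref_u) ** (e - 1)

where ``s_b`` is ``suppression_base``, ``e`` is ``suppression_exponent``
(1 = proportional suppression, >1 = supra-proportional: vigorous responses
are suppressed by a larger fraction), ``kappa`` is
``suppression_memorability_coupling`` (lets suppression deepen with
memorability even when the vigor gain is zero, the HC-like regime), and
``ref_u`` is the unit's mean novel evoked rate at m = 0.5 (a per-unit
normalisation that keeps ``e`` dimensionless).  Under both stock configs the
suppression magnitude (novel - repeated expected rate) is non-decreasing in
memorability.

All randomness flows from one root seed through named sub-streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from ._rng import substream

__all__ = [
    "MemImage",
    "TrialSpec",
    "NBackSpec",
    "UnitParams",
    "RegionConfig",
    "SessionRecording",
    "BehaviorParams",
    "ChoiceSet",
    "gen_images",
    "gen_sequence",
    "gen_units",
    "simulate_session",
    "simulate_behavior",
    "itc_like",
    "hc_like",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MemImage:
    """An image with a memorability score in [0, 1]."""

    image_id: str
    memorability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.memorability <= 1.0:
            raise ValueError(f"memorability {self.memorability} outside [0, 1]")


@dataclass(frozen=True)
class TrialSpec:
    """One trial of the sequence: which image, novel or repeated, what gap.

    ``n_back`` is the number of trials since the image's novel presentation
    (defined for repeated trials only).  ``on_target`` records whether that
    gap was allocated from the target n-back distribution or is a filler.
    """

    trial_index: int
    image_id: str
    novelty: str  # "novel" | "repeated"
    n_back: int | None = None
    on_target: bool | None = None

    def __post_init__(self) -> None:
        if self.novelty not in ("novel", "repeated"):
            raise ValueError(f"novelty must be novel/repeated, got {self.novelty!r}")
        if self.novelty == "repeated" and (self.n_back is None or self.n_back < 1):
            raise ValueError("repeated trials require a positive n_back")
        if self.novelty == "novel" and self.n_back is not None:
            raise ValueError("novel trials carry no n_back")


@dataclass(frozen=True)
class NBackSpec:
    """Target distribution of novel-to-repeat gaps.

    The core levels are uniform with ``base_count`` realized trials each;
    the two extreme levels receive half that frequency.  Gaps needed to
    fill the sequence that were not allocated from this distribution are
    emitted with ``on_target=False`` and are excluded from analysis.
    """

    levels: tuple[int, ...] = (1, 2, 4, 8, 32, 48, 64, 192)
    base_count: int = 30
    half_extremes: bool = True
    off_target_policy: str = "nearest"

    def __post_init__(self) -> None:
        levels = tuple(int(v) for v in self.levels)
        if any(v <= 0 for v in levels):
            raise ValueError("n-back levels must be positive")
        if list(levels) != sorted(set(levels)):
            raise ValueError("n-back levels must be strictly increasing")
        if self.base_count < 1:
            raise ValueError("base_count must be >= 1")
        object.__setattr__(self, "levels", levels)

    def target_counts(self) -> dict[int, int]:
        counts = {}
        for lvl in self.levels:
            extreme = self.half_extremes and lvl in (self.levels[0], self.levels[-1])
            counts[lvl] = self.base_count // 2 if extreme else self.base_count
        return counts

    def relative_frequency(self) -> dict[int, float]:
        counts = self.target_counts()
        total = sum(counts.values())
        return {k: v / total for k, v in counts.items()}


@dataclass(frozen=True)
class UnitParams:
    """Ground-truth generative parameters of one unit."""

    baseline_rate: float  # spikes/s
    peak_amplitude: float  # spikes/s at rank 0, m = 0.5
    selectivity: float  # tuning-curve decay constant per rank
    memorability_gain: float  # evoked-rate scaling with (m - 0.5)
    suppression_base: float  # fraction of evoked rate kept on repeats, in (0, 1]
    suppression_exponent: float  # 1 = proportional suppression, >1 supra-proportional
    response_latency: float  # ms after stimulus onset at which evoked rate starts
    memory_onset: float  # ms after onset at which suppression starts
    image_rank_map: Mapping[str, int]  # image_id -> tuning rank (0 = best)
    suppression_memorability_coupling: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.suppression_base <= 1.0:
            raise ValueError("suppression_base must lie in (0, 1]")
        for name in ("baseline_rate", "peak_amplitude", "selectivity"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.suppression_exponent < 1.0:
            raise ValueError("suppression_exponent must be >= 1")
        ranks = sorted(self.image_rank_map.values())
        if ranks != list(range(len(ranks))):
            raise ValueError("image_rank_map must be a bijection onto 0..n-1")


@dataclass(frozen=True)
class RegionConfig:
    """Distributions over unit parameters plus the recording geometry.

    ``distributions`` maps UnitParams field names to distribution specs
    (see :func:`sample_distribution`).  The stock configs are built by
    :func:`itc_like` and :func:`hc_like`.
    """

    name: str
    distributions: Mapping[str, Mapping]
    bin_width: float = 20.0  # ms
    trial_window: tuple[float, float] = (-500.0, 800.0)  # ms relative to onset
    stimulus_duration: float = 500.0  # ms
    evoked_end: float = 600.0  # ms; evoked rate active on [latency, evoked_end)

    def bin_edges(self) -> np.ndarray:
        t0, t1 = self.trial_window
        n = int(round((t1 - t0) / self.bin_width))
        return t0 + self.bin_width * np.arange(n + 1)


@dataclass
class SessionRecording:
    """Binned spike counts for one recording session.

    counts has shape (n_units, n_trials, n_bins); bin_edges is in ms
    relative to stimulus onset, half-open bins [t, t + width).
    """

    unit_ids: list[str]
    trials: list[TrialSpec]
    counts: np.ndarray
    bin_edges: np.ndarray
    memorability: dict[str, float] = field(default_factory=dict)
    n_clipped_rates: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        u, t, b = self.counts.shape
        if u != len(self.unit_ids) or t != len(self.trials) or b != len(self.bin_edges) - 1:
            raise ValueError("counts dimensions inconsistent with unit/trial/bin counts")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if not np.issubdtype(self.counts.dtype, np.integer) or np.any(self.counts < 0):
            raise ValueError("counts must be non-negative integers")

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class BehaviorParams:
    """Logistic choice model for the novel/repeated report.

    P(report repeated | repeated) = expit(repeated_intercept
        + memorability_slope * (m - 0.5)
        - nback_slope * (log2(n_back) - 2))
    P(report novel | novel) = expit(novel_intercept
        - novel_memorability_slope * (m - 0.5))

    Slopes must be non-negative so that hit rate is monotone increasing in
    memorability and decreasing in n-back, and the novel correct-rejection
    rate is non-increasing in memorability.
    """

    repeated_intercept: float = 1.8
    memorability_slope: float = 4.0
    nback_slope: float = 0.3
    novel_intercept: float = 2.5
    novel_memorability_slope: float = 0.5

    def __post_init__(self) -> None:
        for name in ("memorability_slope", "nback_slope", "novel_memorability_slope"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (monotonicity contract)")

    def p_correct(self, novelty: str, m: float, n_back: int | None) -> float:
        if novelty == "repeated":
            z = (self.repeated_intercept
                 + self.memorability_slope * (m - 0.5)
                 - self.nback_slope * (math.log2(max(n_back, 1)) - 2.0))
        else:
            z = self.novel_intercept - self.novel_memorability_slope * (m - 0.5)
        return float(expit(z))


@dataclass
class ChoiceSet:
    """Per-trial behavioral choices aligned with a trial sequence."""

    choice: list[str]  # "novel" | "repeated"
    correct: np.ndarray  # bool per trial

    def __post_init__(self) -> None:
        self.correct = np.asarray(self.correct, dtype=bool)
        if len(self.choice) != len(self.correct):
            raise ValueError("choice and correct must have equal length")


# ---------------------------------------------------------------------------
# distribution specs
# ---------------------------------------------------------------------------

def sample_distribution(spec, rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw samples from a small declarative distribution spec.

    A spec is either a number (degenerate distribution) or a mapping with a
    ``name`` key: uniform(low, high), normal(mean, sd) with optional
    low/high truncation by clipping-free resampling, lognormal(mean, sigma)
    of the underlying normal, gamma(mean, shape), beta(a, b), or
    constant(value).
    """
    if isinstance(spec, (int, float)):
        return np.full(size, float(spec))
    name = spec["name"]
    if name == "constant":
        return np.full(size, float(spec["value"]))
    if name == "uniform":
        return rng.uniform(spec["low"], spec["high"], size)
    if name == "beta":
        return rng.beta(spec["a"], spec["b"], size)
    if name == "gamma":
        shape = spec.get("shape", 4.0)
        return rng.gamma(shape, spec["mean"] / shape, size)
    if name == "lognormal":
        return rng.lognormal(spec["mean"], spec["sigma"], size)
    if name == "normal":
        x = rng.normal(spec["mean"], spec["sd"], size)
        lo = spec.get("low", -np.inf)
        hi = spec.get("high", np.inf)
        bad = (x < lo) | (x > hi)
        while np.any(bad):  # resample out-of-bound draws (truncation)
            x[bad] = rng.normal(spec["mean"], spec["sd"], int(bad.sum()))
            bad = (x < lo) | (x > hi)
        return x
    raise ValueError(f"unknown distribution {name!r}")


def _distribution_support(spec) -> tuple[float, float]:
    if isinstance(spec, (int, float)):
        return float(spec), float(spec)
    name = spec["name"]
    if name == "constant":
        return float(spec["value"]), float(spec["value"])
    if name == "uniform":
        return float(spec["low"]), float(spec["high"])
    if name == "beta":
        return 0.0, 1.0
    if name == "normal":
        return float(spec.get("low", -np.inf)), float(spec.get("high", np.inf))
    return 0.0, np.inf


# ---------------------------------------------------------------------------
# stock region configurations
# ---------------------------------------------------------------------------

def itc_like(**overrides) -> RegionConfig:
    """High-level visual cortex regime: vigor scales with memorability.

    Evoked rate carries a positive memorability gain, and repetition
    suppression is modestly supra-proportional (exponent 1.2), so more
    vigorous (more memorable) responses are suppressed by a slightly larger
    fraction.
    """
    dists = {
        "baseline_rate": {"name": "gamma", "mean": 5.0, "shape": 4.0},
        "peak_amplitude": {"name": "gamma", "mean": 20.0, "shape": 4.0},
        "selectivity": {"name": "uniform", "low": 0.01, "high": 0.03},
        "memorability_gain": {"name": "normal", "mean": 0.8, "sd": 0.8},
        "suppression_base": {"name": "normal", "mean": 0.80, "sd": 0.12,
                             "low": 0.3, "high": 1.0},
        "suppression_exponent": 1.2,
        "suppression_memorability_coupling": {"name": "normal", "mean": 1.6,
                                              "sd": 1.0},
        "response_latency": {"name": "normal", "mean": 100.0, "sd": 15.0, "low": 40.0},
        "memory_onset": {"name": "normal", "mean": 150.0, "sd": 25.0, "low": 60.0},
    }
    dists.update(overrides)
    return RegionConfig(name="ITC-like", distributions=dists)


def hc_like(**overrides) -> RegionConfig:
    """Hippocampus-like regime: memory without memorability vigor.

    The memorability gain is centered at zero (population vigor does not
    track memorability), yet suppression still deepens with memorability
    through the coupling term, so the isolated memory signal remains larger
    for more memorable images.
    """
    dists = {
        "baseline_rate": {"name": "gamma", "mean": 3.0, "shape": 4.0},
        "peak_amplitude": {"name": "gamma", "mean": 8.0, "shape": 4.0},
        "selectivity": {"name": "uniform", "low": 0.01, "high": 0.03},
        "memorability_gain": {"name": "normal", "mean": 0.0, "sd": 0.1},
        "suppression_base": {"name": "normal", "mean": 0.855, "sd": 0.04,
                             "low": 0.4, "high": 1.0},
        "suppression_exponent": 1.0,
        "suppression_memorability_coupling": 0.2,
        "response_latency": {"name": "normal", "mean": 110.0, "sd": 20.0, "low": 40.0},
        "memory_onset": {"name": "normal", "mean": 160.0, "sd": 30.0, "low": 60.0},
    }
    dists.update(overrides)
    return RegionConfig(name="HC-like", distributions=dists)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_images(n: int, score_distribution=None, seed: int = 0) -> list[MemImage]:
    """Draw *n* images with i.i.d. memorability scores.

    Default distribution is uniform(0, 1).  The spec must be supported on
    [0, 1].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if score_distribution is None:
        score_distribution = {"name": "uniform", "low": 0.0, "high": 1.0}
    lo, hi = _distribution_support(score_distribution)
    if lo < 0.0 or hi > 1.0:
        raise ValueError("score distribution must be supported on [0, 1]")
    rng = substream(seed, "images")
    scores = sample_distribution(score_distribution, rng, n)
    width = len(str(n - 1))
    return [MemImage(f"img{i:0{width}d}", float(s)) for i, s in enumerate(scores)]


def gen_sequence(images: Sequence[MemImage], nback_spec: NBackSpec,
                 seed: int = 0) -> list[TrialSpec]:
    """Build a two-presentation sequence matching target n-back counts.

    Every image appears exactly twice (novel then repeated).  Target
    n-backs are allocated stochastically but realized exactly; gaps that
    exist only to keep the sequence contiguous are emitted with
    ``on_target=False``.  Raises if the image set is too small.
    """
    rng = substream(seed, "sequence")
    remaining = dict(nback_spec.target_counts())
    image_pool = list(rng.permutation(len(images)))
    schedule: dict[int, tuple[int, int, bool]] = {}  # pos -> (img_idx, n_back, on_target)
    trials: list[TrialSpec] = []
    t = 0

    def next_image() -> int:
        if not image_pool:
            raise ValueError("not enough images for the requested n-back targets")
        return image_pool.pop()

    while True:
        pending = sum(remaining.values())
        if t not in schedule and pending == 0 and not schedule:
            break
        if t in schedule:
            img_idx, n_back, on_target = schedule.pop(t)
            trials.append(TrialSpec(t, images[img_idx].image_id, "repeated",
                                    n_back=n_back, on_target=on_target))
            t += 1
            continue
        placed = False
        if pending:
            feasible = [lvl for lvl, c in remaining.items()
                        if c > 0 and (t + lvl) not in schedule]
            if feasible:
                weights = np.array([remaining[lvl] for lvl in feasible], dtype=float)
                lvl = int(rng.choice(feasible, p=weights / weights.sum()))
                img_idx = next_image()
                trials.append(TrialSpec(t, images[img_idx].image_id, "novel"))
                schedule[t + lvl] = (img_idx, lvl, True)
                remaining[lvl] -= 1
                t += 1
                placed = True
        if placed:
            continue
        if not schedule:
            break
        # filler: plug the hole with an off-target pair at the nearest free gap
        gap = 1
        while (t + gap) in schedule:
            gap += 1
        img_idx = next_image()
        trials.append(TrialSpec(t, images[img_idx].image_id, "novel"))
        schedule[t + gap] = (img_idx, gap, False)
        t += 1
    return trials


def gen_units(config: RegionConfig, n_units: int, image_set: Sequence[MemImage],
              seed: int = 0) -> list[UnitParams]:
    """Sample unit parameters from the region config distributions.

    Each unit receives an independent random permutation of the image set
    as its tuning ranking.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if len(image_set) == 0:
        raise ValueError("image set must be non-empty")
    rng = substream(seed, "units")
    cols = {}
    scalar_fields = ["baseline_rate", "peak_amplitude", "selectivity",
                     "memorability_gain", "suppression_base",
                     "suppression_exponent", "response_latency", "memory_onset",
                     "suppression_memorability_coupling"]
    for name in scalar_fields:
        spec = config.distributions.get(name, 0.0)
        cols[name] = sample_distribution(spec, rng, n_units)
    cols["baseline_rate"] = np.maximum(cols["baseline_rate"], 0.0)
    cols["peak_amplitude"] = np.maximum(cols["peak_amplitude"], 0.0)
    cols["selectivity"] = np.maximum(cols["selectivity"], 0.0)
    image_ids = [im.image_id for im in image_set]
    units = []
    for u in range(n_units):
        perm = rng.permutation(len(image_ids))
        rank_map = {image_ids[i]: int(r) for r, i in enumerate(perm)}
        units.append(UnitParams(
            baseline_rate=float(cols["baseline_rate"][u]),
            peak_amplitude=float(cols["peak_amplitude"][u]),
            selectivity=float(cols["selectivity"][u]),
            memorability_gain=float(cols["memorability_gain"][u]),
            suppression_base=float(np.clip(cols["suppression_base"][u], 1e-9, 1.0)),
            suppression_exponent=float(max(cols["suppression_exponent"][u], 1.0)),
            response_latency=float(max(cols["response_latency"][u], 0.0)),
            memory_onset=float(max(cols["memory_onset"][u], 0.0)),
            image_rank_map=rank_map,
            suppression_memorability_coupling=float(
                cols["suppression_memorability_coupling"][u]),
        ))
    return units


def unit_evoked_rates(unit: UnitParams, image_set: Sequence[MemImage]
                      ) -> tuple[np.ndarray, np.ndarray, int]:
    """Expected (novel, repeated) evoked rates in spikes/s for every image.

    These are the pre-noise generative rates on top of baseline, after
    response latency (novel) and memory onset (repeated).  The third return
    value counts images whose memorability gain drove the pre-floor rate
    negative (clipped to zero).
    """
    ranks = np.array([unit.image_rank_map[im.image_id] for im in image_set])
    m = np.array([im.memorability for im in image_set])
    gain = 1.0 + unit.memorability_gain * (m - 0.5)
    n_clipped = int(np.sum(gain < 0))
    evoked_novel = unit.peak_amplitude * np.exp(-unit.selectivity * ranks) \
        * np.maximum(gain, 0.0)
    # per-unit reference: mean novel evoked at m = 0.5
    x = np.arange(len(image_set))
    ref = unit.peak_amplitude * float(np.mean(np.exp(-unit.selectivity * x)))
    base = unit.suppression_base ** (
        1.0 + unit.suppression_memorability_coupling * (m - 0.5))
    base = np.clip(base, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(evoked_novel > 0, evoked_novel / max(ref, 1e-300), 0.0)
        factor = base * rel ** (unit.suppression_exponent - 1.0)
    factor = np.clip(factor, 0.0, 1.0)
    return evoked_novel, evoked_novel * factor, n_clipped


def expected_rates(unit: UnitParams, image: MemImage,
                   n_images: int | None = None) -> tuple[float, float]:
    """Scalar convenience wrapper around :func:`unit_evoked_rates`."""
    full = [image] if image.image_id in unit.image_rank_map else []
    if not full:
        raise KeyError(image.image_id)
    # evaluate in the context of the unit's whole image set so that the
    # per-unit reference rate is well defined
    images = [MemImage(iid, image.memorability if iid == image.image_id else 0.5)
              for iid in unit.image_rank_map]
    ev_n, ev_r, _ = unit_evoked_rates(unit, images)
    idx = [i for i, im in enumerate(images) if im.image_id == image.image_id][0]
    return float(ev_n[idx]), float(ev_r[idx])


def simulate_session(units: Sequence[UnitParams], sequence: Sequence[TrialSpec],
                     image_set: Sequence[MemImage], config: RegionConfig,
                     seed: int = 0) -> SessionRecording:
    """Draw Poisson spike counts for every unit x trial x time bin."""
    images = {im.image_id: im for im in image_set}
    for tr in sequence:
        if tr.image_id not in images:
            raise ValueError(f"trial references unknown image {tr.image_id}")
    rng = substream(seed, "spikes")
    edges = config.bin_edges()
    starts = edges[:-1]
    widths = np.diff(edges)
    n_units, n_trials, n_bins = len(units), len(sequence), len(starts)
    counts = np.zeros((n_units, n_trials, n_bins), dtype=np.int64)
    n_clipped = 0
    image_index = {im.image_id: i for i, im in enumerate(image_set)}
    trial_img = np.array([image_index[tr.image_id] for tr in sequence])
    trial_rep = np.array([tr.novelty == "repeated" for tr in sequence])
    for u, unit in enumerate(units):
        # rate templates per trial: baseline everywhere, evoked on [latency, evoked_end)
        evoked_mask = (starts >= unit.response_latency) & (starts < config.evoked_end)
        memory_mask = evoked_mask & (starts >= unit.memory_onset)
        ev_n, ev_r, clipped = unit_evoked_rates(unit, image_set)
        n_clipped += clipped
        ev_early = ev_n[trial_img]
        ev_late = np.where(trial_rep, ev_r[trial_img], ev_n[trial_img])
        rates = np.full((n_trials, n_bins), unit.baseline_rate)
        rates[:, evoked_mask & ~memory_mask] += ev_early[:, None]
        rates[:, memory_mask] += ev_late[:, None]
        np.maximum(rates, 0.0, out=rates)
        counts[u] = rng.poisson(rates * (widths / 1000.0))
    return SessionRecording(
        unit_ids=[f"u{u:04d}" for u in range(n_units)],
        trials=list(sequence),
        counts=counts,
        bin_edges=edges,
        memorability={im.image_id: im.memorability for im in image_set},
        n_clipped_rates=n_clipped,
    )


def simulate_behavior(sequence: Sequence[TrialSpec], image_set: Sequence[MemImage],
                      behavior_params: BehaviorParams | None = None,
                      seed: int = 0) -> ChoiceSet:
    """Draw a novel/repeated report for every trial of the sequence."""
    params = behavior_params or BehaviorParams()
    mem = {im.image_id: im.memorability for im in image_set}
    rng = substream(seed, "behavior")
    choices, correct = [], []
    for tr in sequence:
        p = params.p_correct(tr.novelty, mem[tr.image_id], tr.n_back)
        is_correct = bool(rng.random() < p)
        if is_correct:
            choices.append(tr.novelty)
        else:
            choices.append("repeated" if tr.novelty == "novel" else "novel")
        correct.append(is_correct)
    return ChoiceSet(choice=choices, correct=np.asarray(correct))
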
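"""Synthetic-data generator: sequence invariants, Poisson statistics, behavior."""

from collections import Counter

import numpy as np
import pytest

from memdecode import syndata as sd


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

class TestGenImages:
    def test_degenerate_distribution(self):
        images = sd.gen_images(4, {"name": "constant", "value": 0.5}, seed=0)
        assert [im.memorability for im in images] == [0.5] * 4
        assert len({im.image_id for im in images}) == 4

    def test_uniform_mean_law_of_large_numbers(self):
        images = sd.gen_images(10_000, seed=0)
        assert abs(np.mean([im.memorability for im in images]) - 0.5) < 0.01

    def test_determinism(self):
        a = sd.gen_images(50, seed=3)
        b = sd.gen_images(50, seed=3)
        assert [im.memorability for im in a] == [im.memorability for im in b]

    @pytest.mark.parametrize("bad", [
        {"n": 0},
        {"n": 5, "score_distribution": {"name": "uniform", "low": -0.2, "high": 1.0}},
        {"n": 5, "score_distribution": {"name": "constant", "value": 1.5}},
    ])
    def test_rejects_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            sd.gen_images(bad.get("n", 5), bad.get("score_distribution"), seed=0)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def check_sequence_invariants(sequence):
    """Exactly-twice, novel-before-repeated, gap-consistency."""
    occur = Counter(tr.image_id for tr in sequence)
    assert all(c == 2 for c in occur.values())
    novel_at = {}
    for tr in sequence:
        if tr.novelty == "novel":
            assert tr.image_id not in novel_at
            novel_at[tr.image_id] = tr.trial_index
        else:
            assert tr.trial_index - novel_at[tr.image_id] == tr.n_back


class TestGenSequence:
    def test_half_frequency_extremes_realized_exactly(self):
        # core levels get the base count, the extreme levels half of it
        images = sd.gen_images(200, seed=1)
        spec = sd.NBackSpec(levels=(1, 2, 4, 8), base_count=30)
        seq = sd.gen_sequence(images, spec, seed=1)
        on = Counter(tr.n_back for tr in seq
                     if tr.novelty == "repeated" and tr.on_target)
        assert on[1] == 15 and on[2] == 30 and on[4] == 30 and on[8] == 15

    def test_smallest_sequence(self):
        images = sd.gen_images(1, seed=0)
        spec = sd.NBackSpec(levels=(1,), base_count=1, half_extremes=False)
        seq = sd.gen_sequence(images, spec, seed=0)
        assert [tr.novelty for tr in seq] == ["novel", "repeated"]
        assert seq[1].n_back == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_invariants_across_seeds(self, seed):
        images = sd.gen_images(120, seed=seed)
        spec = sd.NBackSpec(levels=(1, 2, 4, 8, 16), base_count=16)
        seq = sd.gen_sequence(images, spec, seed=seed)
        check_sequence_invariants(seq)

    def test_infeasible_target_raises(self):
        images = sd.gen_images(3, seed=0)
        spec = sd.NBackSpec(levels=(1, 2, 4), base_count=10)
        with pytest.raises(ValueError, match="not enough images"):
            sd.gen_sequence(images, spec, seed=0)


# ---------------------------------------------------------------------------
# units
# ---------------------------------------------------------------------------

class TestGenUnits:
    def test_region_config_contracts(self):
        images = sd.gen_images(50, seed=0)
        hc = sd.gen_units(sd.hc_like(), 500, images, seed=0)
        gains = [u.memorability_gain for u in hc]
        assert abs(np.mean(gains)) < 3 * np.std(gains) / np.sqrt(len(gains)) + 0.02
        itc = sd.gen_units(sd.itc_like(), 500, images, seed=0)
        assert np.mean([u.memorability_gain for u in itc]) > 0.3
        assert np.mean([1 - u.suppression_base for u in itc]) > 0.05

    def test_determinism_and_rank_bijection(self):
        images = sd.gen_images(30, seed=0)
        a = sd.gen_units(sd.itc_like(), 2, images, seed=5)
        b = sd.gen_units(sd.itc_like(), 2, images, seed=5)
        assert a == b
        for u in a:
            assert sorted(u.image_rank_map.values()) == list(range(30))

    def test_empty_image_set_raises(self):
        with pytest.raises(ValueError):
            sd.gen_units(sd.itc_like(), 3, [], seed=0)


# ---------------------------------------------------------------------------
# spike simulation
# ---------------------------------------------------------------------------

class TestSimulateSession:
    def test_baseline_only_poisson_mean(self):
        # baseline 5 sp/s, no evoked response: expected 2.5 spikes per 500 ms
        images = sd.gen_images(200, seed=0)
        spec = sd.NBackSpec(levels=(1, 2), base_count=50, half_extremes=False)
        seq = sd.gen_sequence(images, spec, seed=0)
        cfg = sd.itc_like(baseline_rate=5.0, peak_amplitude=0.0)
        units = sd.gen_units(cfg, 40, images, seed=0)
        session = sd.simulate_session(units, seq, images, cfg, seed=0)
        rates = session.counts[..., :].sum(axis=2)  # per unit x trial
        # restrict to a 500 ms window
        from memdecode.screen import window_rates
        w = window_rates(session.counts, session.bin_edges, (0.0, 500.0))
        mean_count = w.mean() * 0.5  # spikes per 500 ms
        assert mean_count == pytest.approx(2.5, rel=0.02)

    def test_no_modulation_limit(self):
        images = sd.gen_images(30, seed=0)
        cfg = sd.itc_like(memorability_gain=0.0, suppression_base=1.0,
                          suppression_exponent=1.0)
        unit = sd.gen_units(cfg, 1, images, seed=0)[0]
        ev_n, ev_r, _ = sd.unit_evoked_rates(unit, images)
        np.testing.assert_allclose(ev_n, ev_r)

    def test_poisson_dispersion(self):
        images = sd.gen_images(100, seed=0)
        spec = sd.NBackSpec(levels=(1,), base_count=50, half_extremes=False)
        seq = sd.gen_sequence(images, spec, seed=0)
        cfg = sd.itc_like(baseline_rate=20.0, peak_amplitude=0.0)
        units = sd.gen_units(cfg, 100, images, seed=0)
        session = sd.simulate_session(units, seq, images, cfg, seed=0)
        counts = session.counts.sum(axis=2).ravel()  # fixed-rate totals
        assert 0.95 < counts.var() / counts.mean() < 1.05

    def test_counts_are_nonnegative_integers(self, itc_bundle):
        counts = itc_bundle["session"].counts
        assert np.issubdtype(counts.dtype, np.integer)
        assert counts.min() >= 0


class TestGenerativeStructure:
    """Pre-noise invariants of the expected-rate model."""

    @pytest.mark.parametrize("region", ["itc", "hc"])
    def test_suppression_magnitude_nondecreasing_in_memorability(self, region):
        cfg = sd.itc_like() if region == "itc" else sd.hc_like()
        scores = np.linspace(0.05, 0.95, 10)
        images = [sd.MemImage(f"i{k}", s) for k, s in enumerate(scores)]
        units = sd.gen_units(cfg, 200, images, seed=4)
        supp = np.zeros(len(images))
        for u in units:
            ev_n, ev_r, _ = sd.unit_evoked_rates(u, images)
            supp += ev_n - ev_r
        supp /= len(units)
        assert np.all(np.diff(supp) > -1e-9)

    def test_positive_gain_gives_positive_memorability_rate_correlation(self):
        scores = np.linspace(0.05, 0.95, 20)
        images = [sd.MemImage(f"i{k}", s) for k, s in enumerate(scores)]
        units = sd.gen_units(sd.itc_like(), 300, images, seed=4)
        pop_rate = np.zeros(len(images))
        for u in units:
            ev_n, _, _ = sd.unit_evoked_rates(u, images)
            pop_rate += u.baseline_rate + ev_n
        assert np.corrcoef(scores, pop_rate)[0, 1] > 0.9


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

class TestSimulateBehavior:
    @pytest.fixture(scope="class")
    def long_task(self):
        images = sd.gen_images(5000, seed=6)
        spec = sd.NBackSpec(levels=(2, 4, 8), base_count=1600,
                            half_extremes=False)
        return images, sd.gen_sequence(images, spec, seed=6)

    def test_null_memorability_coefficient_flat_hit_rate(self, long_task):
        images, seq = long_task
        params = sd.BehaviorParams(memorability_slope=0.0,
                                   novel_memorability_slope=0.0)
        choices = sd.simulate_behavior(seq, images, params, seed=6)
        mem = {im.image_id: im.memorability for im in images}
        rep = [i for i, tr in enumerate(seq) if tr.novelty == "repeated"]
        m = np.array([mem[seq[i].image_id] for i in rep])
        hit = choices.correct[rep].astype(float)
        slope = np.polyfit(m, hit, 1)[0]
        se = np.std(hit) / (np.std(m) * np.sqrt(len(rep)))
        assert abs(slope) < 3 * se

    def test_deterministic_ceiling(self):
        images = sd.gen_images(20, seed=0)
        spec = sd.NBackSpec(levels=(1, 2), base_count=5, half_extremes=False)
        seq = sd.gen_sequence(images, spec, seed=0)
        params = sd.BehaviorParams(repeated_intercept=60.0, novel_intercept=60.0,
                                   memorability_slope=0.0, nback_slope=0.0,
                                   novel_memorability_slope=0.0)
        choices = sd.simulate_behavior(seq, images, params, seed=0)
        assert choices.correct.all()

    def test_positive_coefficient_quartile_ordering(self, long_task):
        images, seq = long_task
        choices = sd.simulate_behavior(seq, images, seed=6)
        mem = {im.image_id: im.memorability for im in images}
        rep = [i for i, tr in enumerate(seq) if tr.novelty == "repeated"]
        m = np.array([mem[seq[i].image_id] for i in rep])
        hit = choices.correct[rep]
        top = hit[m >= np.quantile(m, 0.75)].mean()
        bottom = hit[m <= np.quantile(m, 0.25)].mean()
        assert top > bottom

    def test_correct_flag_consistency(self, itc_bundle):
        choices = sd.simulate_behavior(itc_bundle["sequence"],
                                       itc_bundle["images"], seed=1)
        for tr, choice, correct in zip(itc_bundle["sequence"], choices.choice,
                                       choices.correct):
            assert correct == (choice == tr.novelty)

    def test_monotonicity_contract_enforced(self):
        with pytest.raises(ValueError):
            sd.BehaviorParams(memorability_slope=-1.0)
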
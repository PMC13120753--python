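import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from depfuse.feature_encoding import (
    Codebook,
    align_windows,
    encode_session,
    hash_text_encoder,
    learn_codebook,
    quantize,
)
from depfuse.session_model import (
    FrameSeries,
    Labels,
    LeakageError,
    Session,
    Transcript,
    Utterance,
)


def _frame_session(last_time, dt=0.5, split="train"):
    times = np.arange(0.0, last_time, dt)
    fs = FrameSeries("mfcc", times, np.zeros((len(times), 2)), ["a", "b"])
    return Session("s", split, Transcript([]), {"mfcc": fs}, Labels())


class TestAlignWindows:
    def test_exact_tiling(self):
        # frames spanning [0, 9.0) at window 3.0 -> 3 windows
        s = _frame_session(9.0)
        assert len(align_windows(s, 3.0)) == 3

    def test_partial_final_window_kept(self):
        s = _frame_session(7.5)
        windows = align_windows(s, 3.0)
        assert len(windows) == 3
        assert windows[-1].start == 6.0

    def test_no_timestamps_gives_zero_windows(self):
        s = Session("s", "train",
                    Transcript([Utterance("agent", 0, 1, "hi")]), {}, Labels())
        # agent-only transcript with participant filter: nothing to place
        assert align_windows(s, 3.0, include_agent=False) == []
        assert len(align_windows(s, 3.0, include_agent=True)) == 1

    @given(last=st.floats(0.3, 50.0), dt=st.floats(0.05, 1.0),
           w=st.floats(0.5, 5.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_every_frame_in_exactly_one_window(self, last, dt, w):
        s = _frame_session(last, dt)
        windows = align_windows(s, w)
        n = s.channels["mfcc"].n
        seen = np.zeros(n, dtype=int)
        for win in windows:
            i0, i1 = win.frame_ranges["mfcc"]
            seen[i0:i1] += 1
        assert (seen == 1).all()

    def test_utterance_assigned_by_start_time(self):
        t = Transcript([Utterance("participant", 2.9, 5.0, "spans boundary")])
        s = Session("s", "train", t, {}, Labels())
        windows = align_windows(s, 3.0)
        assert windows[0].utterance_indices == [0]


class TestCodebook:
    def test_two_separated_clouds(self, rng):
        lo = rng.normal(0.0, 0.05, (200, 3))
        hi = rng.normal(5.0, 0.05, (200, 3))
        times = np.arange(400) * 0.01
        fs = FrameSeries("gaze", times, np.concatenate([lo, hi]),
                         ["x", "y", "z"])
        s = Session("s", "train", Transcript([]), {"gaze": fs}, Labels())
        cb = learn_codebook([s], "gaze", k=2, seed=0)
        means = sorted(cb.centroids[:, 0])
        assert abs(means[0] - 0.0) < 0.1 and abs(means[1] - 5.0) < 0.1

    def test_k1_is_pooled_mean(self, rng):
        vals = rng.normal(size=(50, 4))
        fs = FrameSeries("pose", np.arange(50) * 0.1, vals,
                         [f"p{i}" for i in range(4)])
        s = Session("s", "train", Transcript([]), {"pose": fs}, Labels())
        cb = learn_codebook([s], "pose", k=1, seed=0)
        np.testing.assert_allclose(cb.centroids[0], vals.mean(axis=0), atol=1e-6)

    def test_dev_session_raises_leakage(self):
        s = _frame_session(5.0, split="dev")
        with pytest.raises(LeakageError):
            learn_codebook([s], "mfcc", k=2, seed=0)

    def test_too_few_frames(self):
        s = _frame_session(1.0)  # 2 frames
        with pytest.raises(ValueError, match="< k"):
            learn_codebook([s], "mfcc", k=10, seed=0)

    def test_trained_on_records_sources(self):
        s = _frame_session(5.0)
        cb = learn_codebook([s], "mfcc", k=2, seed=0)
        assert cb.trained_on == ["s"]

    def test_json_round_trip(self, tmp_path):
        cb = Codebook("au", 3, np.arange(6.0).reshape(3, 2), ["a"])
        cb.save(tmp_path / "cb.json")
        back = Codebook.load(tmp_path / "cb.json")
        assert back.channel == "au" and back.k == 3
        np.testing.assert_allclose(back.centroids, cb.centroids)


class TestQuantize:
    def test_one_hot_when_all_frames_near_centroid_zero(self):
        cb = Codebook("mfcc", 3, np.array([[0.0], [10.0], [20.0]]))
        hist = quantize(np.full((7, 1), 0.5), cb)
        np.testing.assert_allclose(hist, [1.0, 0.0, 0.0])

    def test_dimension_mismatch_names_both(self):
        cb = Codebook("mfcc", 2, np.zeros((2, 3)))
        with pytest.raises(ValueError, match="2 != codebook dim 3"):
            quantize(np.zeros((4, 2)), cb)

    def test_empty_input_gives_zero_vector(self):
        cb = Codebook("mfcc", 4, np.zeros((4, 2)))
        np.testing.assert_array_equal(quantize(np.empty((0, 2)), cb),
                                      np.zeros(4))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_exhaustive_nearest_centroid(self, seed):
        r = np.random.default_rng(seed)
        frames = r.normal(size=(50, 3))
        centroids = r.normal(size=(4, 3))
        cb = Codebook("gaze", 4, centroids)
        # brute-force oracle: explicit loops, lowest index on ties
        counts = np.zeros(4)
        for f in frames:
            dists = [np.sqrt(((f - c) ** 2).sum()) for c in centroids]
            counts[int(np.argmin(dists))] += 1
        np.testing.assert_allclose(quantize(frames, cb), counts / counts.sum(),
                                   atol=1e-12)
        assert abs(quantize(frames, cb).sum() - 1.0) < 1e-9


class TestHashEncoder:
    def test_sentence_of_repeated_token_equals_word_vector(self):
        enc = hash_text_encoder(8, 8, seed=3)
        np.testing.assert_allclose(enc.embed_sentence("a a"),
                                   enc.embed_words("a")[0])

    def test_different_seeds_differ(self):
        a = hash_text_encoder(8, 8, seed=1).embed_words("mood")[0]
        b = hash_text_encoder(8, 8, seed=2).embed_words("mood")[0]
        assert not np.allclose(a, b)

    def test_deterministic_across_instances(self):
        a = hash_text_encoder(16, 16, seed=7).embed_sentence("feeling low today")
        b = hash_text_encoder(16, 16, seed=7).embed_sentence("feeling low today")
        np.testing.assert_array_equal(a, b)

    def test_projected_sentence_dim(self):
        enc = hash_text_encoder(8, 5, seed=0)
        assert enc.embed_sentence("hello there").shape == (5,)


class TestEncodeSession:
    def test_windows_match_alignment(self, tiny_cohort, tiny_encoders):
        sessions, _ = tiny_cohort
        codebooks, encoder = tiny_encoders
        s = sessions[0]
        seq = encode_session(s, codebooks, encoder)
        assert seq.n_windows == len(align_windows(s, 3.0))

    def test_histogram_normalisation_invariant(self, tiny_cohort, tiny_encoders):
        sessions, _ = tiny_cohort
        codebooks, encoder = tiny_encoders
        seq = encode_session(sessions[1], codebooks, encoder)
        for ch, h in seq.histograms.items():
            sums = h[seq.hist_mask[ch]].sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_empty_transcript_sets_text_masks(self, tiny_encoders):
        codebooks, encoder = tiny_encoders
        times = np.arange(0.0, 6.0, 0.5)
        fs = FrameSeries("mfcc", times, np.zeros((len(times), 39)),
                         [f"m{i}" for i in range(39)])
        s = Session("notext", "train", Transcript([]), {"mfcc": fs}, Labels())
        seq = encode_session(s, codebooks, encoder)
        assert not seq.sent_mask.any() and not seq.word_mask.any()
        assert seq.hist_mask["mfcc"].all()

    def test_bit_identical_across_runs(self, tiny_cohort, tiny_encoders):
        sessions, _ = tiny_cohort
        codebooks, encoder = tiny_encoders
        a = encode_session(sessions[2], codebooks, encoder)
        b = encode_session(sessions[2], codebooks,
                           hash_text_encoder(32, 32, seed=42))
        np.testing.assert_array_equal(a.sent_emb, b.sent_emb)
        np.testing.assert_array_equal(a.word_emb, b.word_emb)
        for ch in a.histograms:
            np.testing.assert_array_equal(a.histograms[ch], b.histograms[ch])

    def test_missing_codebook_for_present_channel(self, tiny_cohort, tiny_encoders):
        sessions, _ = tiny_cohort
        _, encoder = tiny_encoders
        with pytest.raises(ValueError, match="no codebook"):
            encode_session(sessions[0], {}, encoder)
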
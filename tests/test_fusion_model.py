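import numpy as np
import pytest

from depfuse._autodiff import Tensor
from depfuse.fusion_model import (
    BudgetError,
    FusionConfig,
    FusionModel,
    STREAMS,
    UninformativeInputError,
    assemble_streams,
    count_parameters,
)
from depfuse.feature_encoding import encode_session


def tiny_config(**kw):
    defaults = dict(d_model=4, n_heads=1, head_hidden=3, dropout=0.0, seed=5,
                    stream_dims={"sentence": 3, "word": 3, "audio": 4,
                                 "visual": 5})
    defaults.update(kw)
    return FusionConfig(**defaults)


def np_attention(params, prefix, Q_in, K_in, q_mask, k_mask, n_heads):
    """Brute-force reference multi-head attention in plain numpy."""
    d = Q_in.shape[1]
    dh = d // n_heads
    get = lambda n: params[f"{prefix}_{n}"].data
    out = np.zeros_like(Q_in)
    if not k_mask.any() or not q_mask.any():
        return out
    Q = Q_in @ get("Wq") + get("bq")
    K = K_in @ get("Wk") + get("bk")
    V = K_in @ get("Wv") + get("bv")
    ctx = np.zeros_like(Q_in)
    for h in range(n_heads):
        sl = slice(h * dh, (h + 1) * dh)
        scores = Q[:, sl] @ K[:, sl].T / np.sqrt(dh)
        scores[:, ~k_mask] = -np.inf
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        A = e / e.sum(axis=1, keepdims=True)
        ctx[:, sl] = A @ V[:, sl]
    out = ctx @ get("Wo") + get("bo")
    out[~q_mask] = 0.0
    return out


def np_forward(model, streams):
    """Independent end-to-end reference of the full fusion pipeline."""
    cfg = model.config
    params = model.params
    proj, masks = {}, {}
    for stream in STREAMS:
        X, m = streams[stream]
        mu_sd = model.scaler.get(stream) if model.scaler else None
        if mu_sd and mu_sd[0] is not None:
            X = (X - mu_sd[0]) / mu_sd[1]
        X = X * m[:, None]
        e = X @ params[f"proj_{stream}_W"].data + params[f"proj_{stream}_b"].data
        proj[stream] = e * m[:, None]
        masks[stream] = m
    ctx = {}
    for stream in STREAMS:
        x = proj[stream]
        for layer in range(cfg.n_self_layers):
            x = np_attention(params, f"self_{stream}_{layer}", x, x,
                             masks[stream], masks[stream], cfg.n_heads)
        ctx[stream] = x
    sm = masks["sentence"].astype(float)[:, None]
    wm = masks["word"].astype(float)[:, None]
    text = (ctx["sentence"] * sm + ctx["word"] * wm) / np.maximum(sm + wm, 1.0)
    tmask = masks["sentence"] | masks["word"]
    comps = [(text, tmask), (ctx["audio"], masks["audio"]),
             (ctx["visual"], masks["visual"])]
    for stream in ("audio", "visual"):
        ca = np_attention(params, f"cross_{stream}", text, ctx[stream],
                          tmask, masks[stream], cfg.n_heads)
        comps.append((ca, tmask & masks[stream].any()))
    cm = np.stack([m.astype(float) for _, m in comps])
    count = cm.sum(axis=0)
    num = sum(c * m[:, None] for (c, _), m in zip(comps, cm))
    per_window = num / np.maximum(count, 1.0)[:, None]
    valid = count > 0
    pooled = per_window[valid].mean(axis=0)
    h = np.maximum(pooled @ params["trunk_W"].data + params["trunk_b"].data, 0)
    outs = []
    for head in ("cls", "reg"):
        a = np.maximum(h @ params[f"{head}_W1"].data + params[f"{head}_b1"].data, 0)
        outs.append(((a @ params[f"{head}_w2"].data
                      + params[f"{head}_b2"].data) * cfg.output_gain).item())
    return np.array(outs)


def random_streams(cfg, n, rng, mask_prob=0.0):
    streams = {}
    for stream in STREAMS:
        X = rng.normal(size=(n, cfg.stream_dims[stream]))
        m = rng.random(n) >= mask_prob
        streams[stream] = (X, m)
    return streams


def randomize(model, rng, scale=0.3):
    for p in model.params.values():
        p.data = rng.normal(0, scale, p.shape)


class TestAttention:
    def test_single_unmasked_key_returns_its_value_projection(self, rng):
        model = FusionModel(tiny_config())
        X = rng.normal(size=(1, 4))
        out = model._attention("self_audio_0", Tensor(X), Tensor(X),
                               np.array([True]), np.array([True]))
        p = model.params
        expected = (X @ p["self_audio_0_Wv"].data + p["self_audio_0_bv"].data) \
            @ p["self_audio_0_Wo"].data + p["self_audio_0_bo"].data
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        model = FusionModel(tiny_config(n_heads=2, d_model=4))
        X = rng.normal(size=(3, 4))
        mask = np.array([True, True, True])
        out = model._attention("self_word_0", Tensor(X), Tensor(X), mask, mask)
        ref = np_attention(model.params, "self_word_0", X, X, mask, mask, 2)
        np.testing.assert_allclose(out.data, ref, atol=1e-9)

    def test_identical_inputs_get_identical_outputs(self, rng):
        model = FusionModel(tiny_config())
        row = rng.normal(size=4)
        X = np.stack([row, rng.normal(size=4), row])
        mask = np.ones(3, dtype=bool)
        out = model._attention("self_visual_0", Tensor(X), Tensor(X),
                               mask, mask).data
        np.testing.assert_allclose(out[0], out[2], atol=1e-12)

    def test_attention_rows_sum_to_one_over_unmasked_keys(self, rng):
        model = FusionModel(tiny_config(n_heads=2))
        X = rng.normal(size=(5, 4))
        mask = np.array([True, False, True, True, False])
        _, attn = model._attention("self_sentence_0", Tensor(X), Tensor(X),
                                   mask, mask, return_attn=True)
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-12)
        assert np.all(attn[:, :, ~mask] == 0.0)

    def test_cross_attention_fully_masked_keys_gives_zero(self, rng):
        model = FusionModel(tiny_config())
        T = rng.normal(size=(2, 4))
        N = rng.normal(size=(2, 4))
        out = model._attention("cross_audio", Tensor(T), Tensor(N),
                               np.array([True, True]),
                               np.array([False, False]))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_cross_attention_single_key_matches_oracle(self, rng):
        model = FusionModel(tiny_config())
        T = rng.normal(size=(3, 4))
        N = rng.normal(size=(1, 4))
        tm = np.ones(3, dtype=bool)
        km = np.ones(1, dtype=bool)
        out = model._attention("cross_visual", Tensor(T), Tensor(N), tm, km)
        ref = np_attention(model.params, "cross_visual", T, N, tm, km, 1)
        np.testing.assert_allclose(out.data, ref, atol=1e-9)
        # every text query attends to the single nonverbal window
        p = model.params
        vproj = (N @ p["cross_visual_Wv"].data + p["cross_visual_bv"].data) \
            @ p["cross_visual_Wo"].data + p["cross_visual_bo"].data
        np.testing.assert_allclose(out.data, np.repeat(vproj, 3, axis=0),
                                   atol=1e-9)


class TestForward:
    def test_zero_weights_give_half_probability_and_zero_score(self, rng):
        model = FusionModel(tiny_config())
        for p in model.params.values():
            p.data = np.zeros_like(p.data)
        pred = model.predict(random_streams(model.config, 3, rng))
        assert pred.p_depression == pytest.approx(0.5)
        assert pred.phq8_raw == pytest.approx(0.0)

    def test_probability_always_in_unit_interval(self, rng):
        model = FusionModel(tiny_config())
        for _ in range(100):
            randomize(model, rng, scale=1.0)
            pred = model.predict(random_streams(model.config, 4, rng))
            assert 0.0 <= pred.p_depression <= 1.0
            assert 0.0 <= pred.phq8_estimate <= 24.0

    def test_full_forward_matches_numpy_oracle(self, rng):
        model = FusionModel(tiny_config(d_model=4, n_heads=1))
        for seed in range(10):
            r = np.random.default_rng(seed)
            randomize(model, r)
            streams = random_streams(model.config, 2, r, mask_prob=0.2)
            if not any(m.any() for _, m in streams.values()):
                continue
            out = model.forward(model.project_streams(streams)).data
            ref = np_forward(model, streams)
            np.testing.assert_allclose(out, ref, atol=1e-6)

    def test_forward_invariant_to_masked_slot_values(self, rng):
        model = FusionModel(tiny_config())
        randomize(model, rng)
        streams = random_streams(model.config, 5, rng, mask_prob=0.4)
        if not any(m.any() for _, m in streams.values()):
            pytest.skip("degenerate draw")
        base = model.predict(streams)
        fuzzed = {}
        for stream, (X, m) in streams.items():
            X2 = X.copy()
            X2[~m] = rng.normal(size=X2[~m].shape) * 100.0
            fuzzed[stream] = (X2, m)
        pert = model.predict(fuzzed)
        assert base.p_depression == pytest.approx(pert.p_depression, abs=1e-12)
        assert base.phq8_raw == pytest.approx(pert.phq8_raw, abs=1e-9)

    def test_all_streams_masked_is_uninformative(self, rng):
        model = FusionModel(tiny_config())
        streams = {s: (np.zeros((3, d)), np.zeros(3, dtype=bool))
                   for s, d in model.config.stream_dims.items()}
        with pytest.raises(UninformativeInputError):
            model.forward(model.project_streams(streams))

    def test_dim_mismatch_names_stream(self, rng):
        model = FusionModel(tiny_config())
        streams = random_streams(model.config, 2, rng)
        X, m = streams["audio"]
        streams["audio"] = (np.hstack([X, X]), m)
        with pytest.raises(ValueError, match="audio"):
            model.project_streams(streams)


class TestGradients:
    def test_backward_matches_finite_differences(self, tiny_cohort,
                                                 tiny_encoders, rng):
        sessions, _ = tiny_cohort
        codebooks, encoder = tiny_encoders
        seq = encode_session(sessions[0], codebooks, encoder)
        streams = assemble_streams(seq)
        dims = {"sentence": encoder.d_s, "word": encoder.d_w,
                "audio": 16, "visual": 24}
        model = FusionModel(FusionConfig(d_model=8, n_heads=2, head_hidden=4,
                                         dropout=0.0, seed=1,
                                         stream_dims=dims))
        randomize(model, rng, scale=0.2)

        def scalar_loss():
            out = model.forward(model.project_streams(streams))
            return (out * Tensor(np.array([0.7, 0.3]))).sum()

        loss = scalar_loss()
        for p in model.params.values():
            p.grad = None
        loss.backward()
        checked = 0
        for name, p in model.params.items():
            flat = p.data.ravel()
            for i in rng.choice(flat.size, size=min(2, flat.size),
                                replace=False):
                old = flat[i]
                flat[i] = old + 1e-6
                lp = float(scalar_loss().data)
                flat[i] = old - 1e-6
                lm = float(scalar_loss().data)
                flat[i] = old
                num = (lp - lm) / 2e-6
                ana = p.grad.ravel()[i] if p.grad is not None else 0.0
                assert num == pytest.approx(ana, abs=2e-5), name
                checked += 1
        assert checked > 50


class TestParameterCount:
    def test_minimal_config_matches_closed_form(self):
        cfg = FusionConfig(d_model=1, n_heads=1, n_self_layers=0,
                           head_hidden=1, dropout=0.0,
                           stream_dims={s: 1 for s in STREAMS})
        d, h = 1, 1
        projections = 4 * (1 * d + d)
        cross = 2 * 4 * (d * d + d)
        trunk = d * d + d
        heads = 2 * ((d * h + h) + (h * 1 + 1))
        assert count_parameters(cfg) == projections + cross + trunk + heads

    def test_default_config_under_budget(self):
        assert count_parameters(FusionConfig()) < 1_000_000

    def test_count_strictly_increases_with_width(self):
        small = count_parameters(FusionConfig(d_model=32))
        large = count_parameters(FusionConfig(d_model=64))
        assert large > small

    def test_budget_error_carries_count(self):
        cfg = FusionConfig(parameter_budget=10)
        with pytest.raises(BudgetError, match="exceed budget 10"):
            count_parameters(cfg)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = FusionModel(tiny_config())
        randomize(model, rng)
        model.scaler = {s: (np.zeros(d), np.ones(d))
                        for s, d in model.config.stream_dims.items()}
        streams = random_streams(model.config, 3, rng)
        before = model.predict(streams)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        back = FusionModel.load(path)
        after = back.predict(streams)
        assert before.p_depression == pytest.approx(after.p_depression)
        assert before.phq8_raw == pytest.approx(after.phq8_raw)
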
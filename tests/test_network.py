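import dataclasses

import numpy as np
import pytest

import prcrs.network as network_mod
from prcrs.autograd import softmax
from prcrs.network import ConfigurationError, ModelConfig, PrcrsModel, init_model, sequence_loss
from prcrs.training import Adam


def small_cfg(**kw):
    base = dict(n_features=6, d_model=8, n_heads=2, n_blocks_per_level=1,
                unet_depth=1, dropout=0.0, seed=3)
    base.update(kw)
    return ModelConfig(**base)


def test_init_deterministic_and_scales_at_init():
    a, b = init_model(small_cfg()), init_model(small_cfg())
    for name in a.params:
        np.testing.assert_array_equal(a.params[name].data, b.params[name].data)
    scales = [p for n, p in a.params.items() if n.endswith(".scale")]
    assert scales and all((s.data == 1.0).all() for s in scales)


def test_dmodel_head_divisibility_enforced():
    with pytest.raises(ConfigurationError):
        ModelConfig(d_model=63, n_heads=4)


def test_even_conv_kernel_rejected():
    with pytest.raises(ConfigurationError):
        ModelConfig(conv_kernel=8)


@pytest.mark.parametrize("t", [1, 5, 17])
@pytest.mark.parametrize("depth", [0, 1, 2])
def test_temporal_length_preserved(t, depth):
    m = init_model(small_cfg(unet_depth=depth))
    x = np.random.default_rng(0).standard_normal((2, t, 6))
    out = m.forward(x)
    assert out.shape == (2, t, 2)


def test_full_length_sweep_depths():
    rng = np.random.default_rng(1)
    for depth in (0, 1, 2):
        m = init_model(small_cfg(unet_depth=depth))
        for t in range(1, 65, 7):
            assert m.forward(rng.standard_normal((1, t, 6))).shape == (1, t, 2)


def test_softmax_rows_normalised():
    m = init_model(small_cfg())
    x = np.random.default_rng(2).standard_normal((2, 8, 6))
    probs = softmax(m.forward(x), axis=-1).data
    np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)
    assert ((probs >= 0) & (probs <= 1)).all()


def test_feature_count_mismatch_rejected():
    m = init_model(small_cfg())
    with pytest.raises(ValueError):
        m.forward(np.zeros((1, 4, 7)))


def test_padded_positions_do_not_affect_real_days():
    """Masked forward equals forward on the truncated sequence."""
    m = init_model(small_cfg())
    rng = np.random.default_rng(3)
    x = rng.standard_normal((1, 9, 6))
    pad = np.zeros((1, 9))
    pad[0, :5] = 1.0
    garbled = x.copy()
    garbled[0, 5:] = 1e3
    out_masked = m.forward(garbled, pad).data[0, :5]
    out_trunc = m.forward(x[:, :5, :]).data[0]
    np.testing.assert_allclose(out_masked, out_trunc, atol=1e-10)


def test_causality_no_future_leakage():
    """Prediction for day t is unchanged by edits to any later day."""
    for depth in (0, 1, 2):
        m = init_model(small_cfg(unet_depth=depth))
        rng = np.random.default_rng(4)
        x = rng.standard_normal((1, 12, 6))
        base = m.forward(x).data[0]
        x2 = x.copy()
        x2[0, 7:] += 5.0
        mod = m.forward(x2).data[0]
        np.testing.assert_array_equal(base[:7], mod[:7])
        assert np.abs(base[7:] - mod[7:]).max() > 0


def test_batch_invariance():
    """Forward on a batch equals stacked per-sequence forwards."""
    m = init_model(small_cfg())
    rng = np.random.default_rng(5)
    seqs = [rng.standard_normal((7, 6)) for _ in range(3)]
    batch_out = m.forward(np.stack(seqs)).data
    for i, s in enumerate(seqs):
        single = m.forward(s[None]).data[0]
        np.testing.assert_allclose(batch_out[i], single, atol=1e-5)


def test_mfcf_zeroed_branches_reduce_to_layernorm():
    """With all sub-module weights zeroed, each residual step is LN(x)."""
    m = init_model(small_cfg(unet_depth=0, scale_init=1.0))
    prefix = "encoder.bottleneck.block0"
    for name, p in m.params.items():
        if name.startswith(prefix) and not (
            name.endswith("ln_gamma") or name.endswith("ln_beta") or name.endswith(".scale")
        ):
            p.data[:] = 0.0
    rng = np.random.default_rng(6)
    x = rng.standard_normal((1, 5, 8))
    from prcrs.autograd import Tensor, layer_norm

    out = m.mfcf_block(Tensor(x), prefix, np.ones((1, 5)))
    ref = Tensor(x)
    for sub in ("mha", "ffn1", "conv", "ffn2"):
        ref = layer_norm(ref, m.params[f"{prefix}.{sub}.ln_gamma"], m.params[f"{prefix}.{sub}.ln_beta"])
    np.testing.assert_allclose(out.data, ref.data, atol=1e-12)


def test_exactly_one_layernorm_per_sublayer(monkeypatch):
    """Post-LN only: 4 LayerNorm calls per MFCF block, none elsewhere."""
    calls = []
    real_ln = network_mod.layer_norm

    def counting_ln(*args, **kw):
        calls.append(1)
        return real_ln(*args, **kw)

    monkeypatch.setattr(network_mod, "layer_norm", counting_ln)
    cfg = small_cfg(unet_depth=1, n_blocks_per_level=2)
    m = init_model(cfg)
    m.forward(np.zeros((1, 6, 6)))
    n_blocks = cfg.n_blocks_per_level * (2 * cfg.unet_depth + 1)
    assert len(calls) == 4 * n_blocks


def test_predict_proba_range_and_symmetry():
    m = init_model(small_cfg())
    p = m.predict_proba(np.random.default_rng(7).standard_normal((9, 6)))
    assert ((p >= 0) & (p <= 1)).all()
    # symmetric logits -> probability 0.5
    m.params["head.w"].data[:] = 0.0
    m.params["head.b"].data[:] = 0.0
    p = m.predict_proba(np.zeros((4, 6)))
    np.testing.assert_allclose(p, 0.5, atol=1e-12)
    # saturated logits
    m.params["head.b"].data[:] = [-10.0, 10.0]
    assert (m.predict_proba(np.zeros((4, 6))) > 0.999).all()


def test_nonfinite_input_rejected():
    m = init_model(small_cfg())
    x = np.zeros((1, 4, 6))
    x[0, 1, 2] = np.nan
    with pytest.raises(ValueError):
        m.forward(x)


def test_gradient_flow_to_every_trainable_parameter():
    m = init_model(small_cfg())
    rng = np.random.default_rng(8)
    batch = rng.standard_normal((3, 7, 6))
    labels = rng.integers(0, 2, (3, 7))
    loss = sequence_loss(m, batch, labels, np.ones((3, 7)), np.ones((3, 7)))
    loss.backward()
    dead = [n for n, p in m.params.items() if p.grad is None or not np.abs(p.grad).sum() > 0]
    # positional embeddings beyond the batch length legitimately get no signal
    dead = [n for n in dead if n != "embedding.pos"]
    assert dead == []
    assert np.abs(m.params["embedding.pos"].grad[:7]).sum() > 0


def test_freeze_unknown_group_rejected():
    m = init_model(small_cfg())
    with pytest.raises(KeyError):
        m.freeze({"blokc3"})


def test_freeze_all_groups_bitwise_invariant_after_training():
    m = init_model(small_cfg())
    m.freeze(m.parameter_groups().keys())
    before = m.state_dict()
    opt = Adam(m, lr=0.1)
    rng = np.random.default_rng(9)
    for _ in range(10):
        batch = rng.standard_normal((2, 5, 6))
        labels = rng.integers(0, 2, (2, 5))
        opt.zero_grad()
        loss = sequence_loss(m, batch, labels, np.ones((2, 5)), np.ones((2, 5)))
        loss.backward()
        opt.step()
    after = m.state_dict()
    for name in before:
        np.testing.assert_array_equal(before[name], after[name])


def test_unfrozen_training_changes_parameters():
    m = init_model(small_cfg())
    before = m.state_dict()
    opt = Adam(m, lr=0.01)
    rng = np.random.default_rng(10)
    batch = rng.standard_normal((2, 5, 6))
    labels = rng.integers(0, 2, (2, 5))
    loss = sequence_loss(m, batch, labels, np.ones((2, 5)), np.ones((2, 5)))
    loss.backward()
    opt.step()
    changed = any(not np.array_equal(before[n], m.params[n].data) for n in before)
    assert changed


def test_checkpoint_round_trip(tmp_path):
    m = init_model(small_cfg())
    m.save(tmp_path / "ckpt")
    back = PrcrsModel.load(tmp_path / "ckpt")
    x = np.random.default_rng(11).standard_normal((1, 6, 6))
    np.testing.assert_array_equal(m.forward(x).data, back.forward(x).data)


def test_unet_depth_zero_equals_block_stack():
    """depth-0 forward is just embedding + the bottleneck MFCF stack + head."""
    m = init_model(small_cfg(unet_depth=0, n_blocks_per_level=2))
    rng = np.random.default_rng(12)
    x = rng.standard_normal((1, 6, 6))
    from prcrs.autograd import Tensor

    p = m.params
    mask = np.ones((1, 6))
    h = (Tensor(x) @ p["embedding.w"] + p["embedding.b"] + p["embedding.pos"][:6]) * Tensor(mask[:, :, None])
    for b in range(2):
        h = m.mfcf_block(h, f"encoder.bottleneck.block{b}", mask)
    manual = (h @ p["head.w"] + p["head.b"]).data
    np.testing.assert_allclose(m.forward(x).data, manual, atol=1e-12)
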
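"""Distance-biased attention backbone: featurization and invariances."""

import copy
import math

import numpy as np
import pytest

from ddgformer import BackboneConfig, GraphTransformerBackbone
from ddgformer.graphformer import (categorize_distance, cross_entropy,
                                   default_bandwidths, pretrain_loss,
                                   rbf_encode)
from ddgformer.microenv import build_masked_microenv
from ddgformer.synthetic import SyntheticSpec, make_helix_structure
from ddgformer.structure_io import assign_partial_charges, compute_sasa
from tests.conftest import rigid_motion


# -- RBF / categorical featurization --------------------------------------

def test_rbf_zero_distance_is_one_everywhere():
    out = rbf_encode(np.zeros((3, 3)), default_bandwidths())
    assert np.allclose(out, 1.0)


def test_rbf_monotone_decreasing_per_channel():
    d = np.array([[0.0, 1.0, 2.0, 5.0, 10.0]])
    out = rbf_encode(d, default_bandwidths())
    assert np.all(np.diff(out[0], axis=0) < 0)


def test_rbf_matches_closed_form():
    rng = np.random.default_rng(0)
    D = rng.uniform(0, 20, size=(7, 7))
    bw = default_bandwidths()
    out = rbf_encode(D, bw)
    for k, s in enumerate(bw):
        assert np.allclose(out[..., k], np.exp(-D ** 2 / (2 * s ** 2)),
                           atol=1e-9)


def test_rbf_rejects_nonpositive_bandwidth():
    with pytest.raises(ValueError):
        rbf_encode(np.zeros((2, 2)), [1.0, -1.0])


def test_categorize_zero_in_first_bin_and_one_hot():
    D = np.array([[0.0, 2.2, 2.3], [4.0, 8.0, 9.0], [1.0, 5.0, 100.0]])
    out = categorize_distance(D, (2.2, 4.0, 8.0))
    assert np.allclose(out.sum(axis=-1), 1.0)
    assert out[0, 0, 0] == 1           # zero -> first bin
    assert out[0, 1, 0] == 1           # boundary -> lower bin (closed right)
    assert out[0, 2, 1] == 1
    assert out[1, 0, 1] == 1           # 4.0 at boundary -> bin 2? no: lower
    assert out[1, 1, 2] == 1           # 8.0 -> third bin
    assert out[1, 2, 3] == 1           # beyond last boundary
    assert out[2, 2, 3] == 1


# -- attention bias --------------------------------------------------------

def test_zero_bias_weights_reduce_to_unbiased_attention(desk_backbone, env):
    model = copy.deepcopy(desk_backbone)
    base = model.forward_tokens(env).data
    for block in model.blocks:
        for attn in (block.attn1, block.attn2):
            attn.bias_proj.weight.data[:] = 0.0
            attn.bias_proj.bias.data[:] = 0.0
            pf = model.pair_features(env.distances)
            assert np.allclose(attn.attention_bias(pf).data, 0.0)
    biased = model.forward_tokens(env).data
    assert not np.allclose(base, biased)   # bias was doing something


def test_attention_bias_matches_manual_concat_matmul(desk_backbone):
    rng = np.random.default_rng(4)
    D = rng.uniform(0, 15, size=(5, 5))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0)
    attn = desk_backbone.blocks[0].attn1
    pf = desk_backbone.pair_features(D)
    got = attn.attention_bias(pf).data          # (Head, 5, 5)

    cfg = desk_backbone.config
    manual_feats = np.concatenate(
        [rbf_encode(D, cfg.rbf_bandwidths),
         categorize_distance(D, cfg.class_boundaries)], axis=-1)
    W, b = attn.bias_proj.weight.data, attn.bias_proj.bias.data
    manual = manual_feats @ W + b               # (5, 5, Head)
    assert np.abs(got - manual.transpose(2, 0, 1)).max() < 1e-9


def test_bias_permutation_consistency(desk_backbone):
    rng = np.random.default_rng(5)
    D = rng.uniform(0, 15, size=(6, 6))
    perm = rng.permutation(6)
    attn = desk_backbone.blocks[0].attn1
    b1 = attn.attention_bias(desk_backbone.pair_features(D)).data
    b2 = attn.attention_bias(
        desk_backbone.pair_features(D[np.ix_(perm, perm)])).data
    assert np.allclose(b1[:, perm][:, :, perm], b2)


# -- backbone forward -------------------------------------------------------

def _permuted(env, perm):
    env2 = copy.deepcopy(env)
    env2.elements = env.elements[perm]
    env2.phys = env.phys[perm]
    env2.coords = env.coords[perm]
    env2.distances = env.distances[np.ix_(perm, perm)]
    env2.pool_mask = env.pool_mask[perm]
    return env2


def test_token_permutation_equivariance(desk_backbone, env):
    perm = np.random.default_rng(1).permutation(env.n_tokens)
    out = desk_backbone.forward_tokens(env).data
    out_p = desk_backbone.forward_tokens(_permuted(env, perm)).data
    assert np.abs(out[perm] - out_p).max() < 1e-9


def test_likelihoods_permutation_invariant(desk_backbone, env):
    perm = np.random.default_rng(2).permutation(env.n_tokens)
    p1 = desk_backbone.predict_masked_aa(env).probs
    p2 = desk_backbone.predict_masked_aa(_permuted(env, perm)).probs
    assert np.abs(p1 - p2).max() < 1e-9


def test_se3_invariance_over_random_rigid_motions(desk_backbone, helix):
    """Outputs identical to 1e-5 under 100 random rotations+translations."""
    env = build_masked_microenv(helix, "A", 10)
    ref = desk_backbone.predict_masked_aa(env).probs
    rng = np.random.default_rng(42)
    worst = 0.0
    for _ in range(100):
        Q, t = rigid_motion(rng)
        moved = copy.deepcopy(helix)
        for a in moved.atoms:
            a.coords = Q @ a.coords + t
        env2 = build_masked_microenv(moved, "A", 10)
        worst = max(worst,
                    np.abs(desk_backbone.predict_masked_aa(env2).probs
                           - ref).max())
    assert worst < 1e-5


def test_outputs_finite_under_fuzzing(desk_backbone):
    """No NaN/Inf over randomized environments."""
    from ddgformer.microenv import Microenvironment, pairwise_distances, pooling_mask
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(3, 40))
        coords = rng.uniform(-8, 8, size=(n, 3))
        env = Microenvironment(
            center=np.zeros(3), elements=rng.integers(0, 7, size=n),
            phys=rng.normal(scale=rng.uniform(0.1, 50), size=(n, 2)),
            coords=coords, distances=pairwise_distances(coords),
            pool_mask=pooling_mask(coords, np.zeros(3)), label_aa="A")
        if not env.pool_mask.any():
            continue
        probs = desk_backbone.predict_masked_aa(env).probs
        assert np.isfinite(probs).all()
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)


def test_duplicated_pool_tokens_leave_prediction_unchanged(desk_backbone, env):
    """Mean pooling: replicating every token (and pair features) is a no-op."""
    env2 = copy.deepcopy(env)
    n = env.n_tokens
    idx = np.concatenate([np.arange(n), np.arange(n)])
    env2.elements = env.elements[idx]
    env2.phys = env.phys[idx]
    env2.coords = env.coords[idx]
    env2.distances = env.distances[np.ix_(idx, idx)]
    env2.pool_mask = env.pool_mask[idx]
    p1 = desk_backbone.predict_masked_aa(env).probs
    p2 = desk_backbone.predict_masked_aa(env2).probs
    assert np.abs(p1 - p2).max() < 1e-9


def test_empty_pool_is_an_error(desk_backbone, env):
    env2 = copy.deepcopy(env)
    env2.pool_mask = np.zeros_like(env.pool_mask)
    with pytest.raises(ValueError, match="pool"):
        desk_backbone.predict_masked_aa(env2)


# -- losses and config ------------------------------------------------------

def test_pretrain_loss_closed_forms():
    uniform = np.full(20, 1 / 20)
    assert pretrain_loss(uniform, "A") == pytest.approx(math.log(20),
                                                        abs=1e-9)
    onehot = np.zeros(20)
    onehot[0] = 1.0
    assert pretrain_loss(onehot, "A") == 0.0
    with pytest.raises(KeyError):
        pretrain_loss(uniform, "X")


def test_batch_mean_loss_equals_loop_oracle(desk_backbone):
    from ddgformer.synthetic import make_pretrain_toy
    envs = make_pretrain_toy(n_envs=6, seed=1)
    losses = [float(cross_entropy(desk_backbone.masked_aa_logits(e),
                                  e.label_aa).data) for e in envs]
    batch = sum(losses) / len(losses)
    oracle = 0.0
    for e in envs:
        p = desk_backbone.predict_masked_aa(e).probs
        oracle += pretrain_loss(p, e.label_aa)
    assert batch == pytest.approx(oracle / len(envs), abs=1e-9)


def test_config_validation_and_parameter_budget():
    with pytest.raises(ValueError):
        BackboneConfig(token_dim=30, n_heads=8)
    with pytest.raises(ValueError):
        BackboneConfig(class_boundaries=(4.0, 2.0, 8.0))
    full = GraphTransformerBackbone(BackboneConfig(), seed=0)
    assert abs(full.n_parameters() - 1.2e6) / 1.2e6 < 0.05


def test_checkpoint_roundtrip_bit_exact(tmp_path, desk_backbone, env):
    desk_backbone.save(tmp_path / "model.npz")
    back = GraphTransformerBackbone.load(tmp_path / "model.npz")
    for (k1, p1), (k2, p2) in zip(desk_backbone.named_parameters(),
                                  back.named_parameters()):
        assert k1 == k2
        assert np.array_equal(p1.data, p2.data)
    assert np.array_equal(desk_backbone.predict_masked_aa(env).probs,
                          back.predict_masked_aa(env).probs)
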
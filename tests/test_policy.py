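import numpy as np
import pytest

from fragrl.assembly import decompose
from fragrl.fragmentation import fragment_from_smiles
from fragrl.nn import Tensor
from fragrl.policy import (
    TransformerParams,
    actor_forward,
    critic_forward,
    embed_state,
    sample_action,
    transformer_encode,
)

from oracles import transformer_block_oracle


@pytest.fixture()
def states(library, fixture_molecules):
    return [decompose(s, library, frozen=True) for s in fixture_molecules[:8]]


class TestEmbedState:
    def test_sequence_lengths(self, states, fragment_tree, tiny_params):
        for st in states:
            frag_toks, scaf_toks = embed_state(st, fragment_tree, tiny_params)
            assert frag_toks.shape == (len(st.fragments), tiny_params.d_f)
            n_scaffold = sum(st.scaffold_mask)
            if n_scaffold:
                assert scaf_toks.shape == (n_scaffold, tiny_params.d_f)

    def test_deterministic(self, states, fragment_tree, library):
        p1 = TransformerParams(len(library), fragment_tree.code_length, seed=3,
                               heads=1, blocks=1, d_f=8, d_p=4)
        p2 = TransformerParams(len(library), fragment_tree.code_length, seed=3,
                               heads=1, blocks=1, d_f=8, d_p=4)
        a, _ = embed_state(states[0], fragment_tree, p1)
        b, _ = embed_state(states[0], fragment_tree, p2)
        np.testing.assert_array_equal(a.data, b.data)

    def test_missing_code_raises(self, states, fragment_tree, tiny_params):
        broken = type(fragment_tree)(root=fragment_tree.root, codes={})
        with pytest.raises(KeyError):
            embed_state(states[0], broken, tiny_params)


class TestTransformerEncode:
    def test_attention_rows_sum_to_one(self, states, fragment_tree, tiny_params):
        frag_toks, _ = embed_state(states[0], fragment_tree, tiny_params)
        enc = transformer_encode(frag_toks, tiny_params)
        for weights in enc.attention:
            np.testing.assert_allclose(weights.sum(axis=-1),
                                       np.ones(weights.shape[0]), atol=1e-9)

    def test_single_token_attention_is_value_projection(self, library, fragment_tree):
        params = TransformerParams(len(library), fragment_tree.code_length,
                                   heads=1, blocks=1, d_f=4, d_p=2, seed=0)
        x = np.random.default_rng(1).normal(size=(1, 4))
        enc = transformer_encode(Tensor(x), params)
        # with one key the softmax is forced to 1, so A = V = x Wv
        P = params.params
        assert enc.attention[0].shape == (1, 1)
        np.testing.assert_allclose(enc.attention[0], [[1.0]])
        # and the block output is the deterministic ln/ffn pipeline of that
        oracle = transformer_block_oracle(
            x,
            P["frag.block0.head0.WQ"].data, P["frag.block0.head0.WK"].data,
            P["frag.block0.head0.WV"].data, P["frag.block0.WO"].data,
            P["frag.block0.W1"].data, P["frag.block0.b1"].data,
            P["frag.block0.W2"].data, P["frag.block0.b2"].data,
            P["frag.block0.ln1.g"].data, P["frag.block0.ln1.b"].data,
            P["frag.block0.ln2.g"].data, P["frag.block0.ln2.b"].data,
            d_p=2,
        )
        np.testing.assert_allclose(enc.fragment_features.data, oracle, atol=1e-10)

    def test_matches_hand_arithmetic_tiny_weights(self, library, fragment_tree):
        # H=1, d_f=4, d_p=2, two tokens, hand-set weights
        params = TransformerParams(len(library), fragment_tree.code_length,
                                   heads=1, blocks=1, d_f=4, d_p=2, seed=0)
        P = params.params
        rng = np.random.default_rng(8)
        hand = {}
        for name, shape in [
            ("frag.block0.head0.WQ", (4, 2)), ("frag.block0.head0.WK", (4, 2)),
            ("frag.block0.head0.WV", (4, 2)), ("frag.block0.WO", (2, 4)),
            ("frag.block0.W1", (4, 16)), ("frag.block0.b1", (16,)),
            ("frag.block0.W2", (16, 4)), ("frag.block0.b2", (4,)),
        ]:
            hand[name] = rng.normal(size=shape).round(2)
            P[name].data = hand[name]
        x = np.array([[0.5, -1.0, 2.0, 0.0], [1.0, 1.0, -1.0, 0.25]])
        got = transformer_encode(Tensor(x), params).fragment_features.data
        want = transformer_block_oracle(
            x, hand["frag.block0.head0.WQ"], hand["frag.block0.head0.WK"],
            hand["frag.block0.head0.WV"], hand["frag.block0.WO"],
            hand["frag.block0.W1"], hand["frag.block0.b1"],
            hand["frag.block0.W2"], hand["frag.block0.b2"],
            P["frag.block0.ln1.g"].data, P["frag.block0.ln1.b"].data,
            P["frag.block0.ln2.g"].data, P["frag.block0.ln2.b"].data,
            d_p=2,
        )
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_empty_sequence_errors(self, tiny_params):
        with pytest.raises(ValueError):
            transformer_encode(None, tiny_params)

    def test_outputs_finite(self, states, fragment_tree, tiny_params):
        for st in states:
            frag_toks, _ = embed_state(st, fragment_tree, tiny_params)
            enc = transformer_encode(frag_toks, tiny_params)
            assert np.all(np.isfinite(enc.fragment_features.data))


class TestActorForward:
    def test_position_probs_normalized(self, states, fragment_tree, tiny_params, library):
        for st in states:
            dist = actor_forward(st, fragment_tree, tiny_params, library)
            assert dist.position_probs.sum() == pytest.approx(1.0, abs=1e-6)
            np.testing.assert_allclose(dist.replacement_probs.sum(axis=1),
                                       np.ones(len(st.fragments)), atol=1e-6)

    def test_masked_replacements_exactly_zero(self):
        from fragrl.fragmentation import build_fragment_library, pairwise_similarity
        from fragrl.tree import build_balanced_tree

        lib = build_fragment_library(["Cc1ccccc1", "CCc1ccccc1"])
        zero_attach = lib.add(fragment_from_smiles("c1ccsc1"))
        tree = build_balanced_tree(lib, pairwise_similarity(lib))
        params = TransformerParams(len(lib), tree.code_length,
                                   heads=2, blocks=1, d_f=16, d_p=8, seed=7)
        st = decompose("Cc1ccccc1", lib, frozen=True)
        dist = actor_forward(st, tree, params, lib)
        # every position here has one bond; the 0-attachment thiophene is masked
        assert np.all(dist.replacement_probs[:, zero_attach] == 0.0)

    def test_deterministic_across_runs(self, states, fragment_tree, library):
        kw = dict(heads=2, blocks=1, d_f=16, d_p=8, seed=5)
        d1 = actor_forward(states[0], fragment_tree,
                           TransformerParams(len(library), fragment_tree.code_length, **kw),
                           library)
        d2 = actor_forward(states[0], fragment_tree,
                           TransformerParams(len(library), fragment_tree.code_length, **kw),
                           library)
        np.testing.assert_array_equal(d1.position_probs, d2.position_probs)
        np.testing.assert_array_equal(d1.replacement_probs, d2.replacement_probs)

    def test_no_nans_anywhere(self, states, fragment_tree, tiny_params, library):
        for st in states:
            dist = actor_forward(st, fragment_tree, tiny_params, library)
            assert np.all(np.isfinite(dist.position_probs))
            assert np.all(np.isfinite(dist.replacement_probs))


class TestCriticForward:
    def test_finite_on_fixture_states(self, states, fragment_tree, tiny_params):
        for st in states:
            assert np.isfinite(critic_forward(st, fragment_tree, tiny_params).value)

    def test_deterministic(self, states, fragment_tree, library):
        kw = dict(heads=1, blocks=1, d_f=8, d_p=4, seed=2)
        v1 = critic_forward(states[0], fragment_tree,
                            TransformerParams(len(library), fragment_tree.code_length, **kw))
        v2 = critic_forward(states[0], fragment_tree,
                            TransformerParams(len(library), fragment_tree.code_length, **kw))
        assert v1.value == v2.value


class TestSampleAction:
    def test_point_mass(self, rng):
        from fragrl.policy import ActionDistribution

        dist = ActionDistribution(
            position_t=Tensor(np.array([0.0, 1.0])),
            replacement_t=Tensor(np.array([[1.0, 0.0], [0.0, 1.0]])),
        )
        for _ in range(10):
            assert sample_action(dist, rng) == (1, 1)

    def test_reproducible_under_seed(self, states, fragment_tree, tiny_params, library):
        dist = actor_forward(states[0], fragment_tree, tiny_params, library)
        a = [sample_action(dist, np.random.default_rng(9)) for _ in range(20)]
        b = [sample_action(dist, np.random.default_rng(9)) for _ in range(20)]
        assert a == b

    def test_empirical_frequencies_within_3_sigma(self):
        from fragrl.policy import ActionDistribution

        p = 0.3
        dist = ActionDistribution(
            position_t=Tensor(np.array([1.0])),
            replacement_t=Tensor(np.array([[p, 1 - p]])),
        )
        n = 10_000
        rng = np.random.default_rng(123)
        hits = sum(sample_action(dist, rng)[1] == 0 for _ in range(n))
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(hits - n * p) < 3 * sigma


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, library, fragment_tree, tiny_params, states):
        path = tmp_path / "policy.ckpt"
        tiny_params.save(str(path))
        loaded = TransformerParams.load(str(path))
        d1 = actor_forward(states[0], fragment_tree, tiny_params, library)
        d2 = actor_forward(states[0], fragment_tree, loaded, library)
        np.testing.assert_array_equal(d1.position_probs, d2.position_probs)
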
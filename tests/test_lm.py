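import numpy as np
import pytest
from sklearn.base import clone

import protrep as P
from protrep import lm as L
from protrep.errors import TokenizationError


@pytest.fixture(scope="module")
def tiny_records():
    rng = np.random.default_rng(2)
    letters = list(P.CANONICAL_AA)
    return [P.ProteinRecord(f"p{i}", "".join(rng.choice(letters, size=rng.integers(5, 30))))
            for i in range(12)]


class TestConfig:
    def test_embedding_dim_is_twice_hidden(self):
        assert P.LanguageModelConfig(hidden_units=1024).embedding_dim == 2048
        assert P.LanguageModelConfig(hidden_units=64).embedding_dim == 128

    @pytest.mark.parametrize("kw", [dict(num_layers=0), dict(hidden_units=0),
                                    dict(max_sequence_length=0), dict(learning_rate=0.0),
                                    dict(warmup_steps=-1)])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            P.LanguageModelConfig(**kw)


class TestTokenize:
    def test_length_preserved_under_cap(self, tiny_lm_config):
        toks = P.tokenize(P.ProteinRecord("p", "MKV"), tiny_lm_config)
        assert len(toks) == 3

    def test_long_sequence_clipped_to_cap(self):
        cfg = P.LanguageModelConfig(max_sequence_length=1500)
        seq = "".join(np.random.default_rng(0).choice(list(P.CANONICAL_AA), size=1600))
        assert len(P.tokenize(P.ProteinRecord("p", seq), cfg)) == 1500

    def test_ambiguity_letter_gets_dedicated_token(self, tiny_lm_config):
        toks = P.tokenize(P.ProteinRecord("p", "MXV"), tiny_lm_config)
        assert toks[1] == tiny_lm_config.vocabulary.index("X")

    def test_unknown_character_names_position(self, tiny_lm_config):
        with pytest.raises(TokenizationError, match=r"'\*' at position 3"):
            P.tokenize(P.ProteinRecord("p", "MK*V"), tiny_lm_config)


class TestEce:
    def test_uniform_model_scores_alphabet_size(self, tiny_lm_config, tiny_records):
        assert P.ece(P.uniform_lm(tiny_lm_config), tiny_records) == pytest.approx(20.0)

    def test_fixed_output_head_matches_hand_computed_cross_entropy(self, tiny_lm_config):
        # zero LSTM weights force h = 0, so logits = output bias: a fixed,
        # position-independent distribution we can cross-check by hand
        model = P.uniform_lm(tiny_lm_config)
        rng = np.random.default_rng(4)
        bf = rng.normal(size=20)
        bb = rng.normal(size=20)
        model.parameters["fwd_bout"] = bf
        model.parameters["bwd_bout"] = bb
        records = [P.ProteinRecord("a", "MKV"), P.ProteinRecord("b", "GA")]

        def logsoft(b):
            return b - np.log(np.exp(b - b.max()).sum()) - b.max()

        aa = {c: i for i, c in enumerate(P.CANONICAL_AA)}
        nll = []
        for rec in records:
            s = rec.sequence
            nll += [-logsoft(bf)[aa[c]] for c in s[1:]]       # next-residue targets
            nll += [-logsoft(bb)[aa[c]] for c in s[::-1][1:]]  # previous-residue targets
        expected = np.exp(np.mean(nll))
        assert P.ece(model, records) == pytest.approx(expected, rel=1e-10)

    def test_invariant_under_permutation(self, tiny_lm_config, tiny_records):
        model = P.untrained_lm(tiny_lm_config)
        a = P.ece(model, tiny_records)
        b = P.ece(model, tiny_records[::-1])
        assert a == pytest.approx(b, rel=1e-12)
        assert a >= 1.0

    def test_untrained_near_alphabet_size(self, tiny_lm_config, tiny_records):
        value = P.ece(P.untrained_lm(tiny_lm_config), tiny_records)
        assert 1.0 <= value == pytest.approx(20.0, rel=0.05)

    def test_all_length_one_rejected(self, tiny_lm_config):
        with pytest.raises(ValueError, match="length"):
            P.ece(P.uniform_lm(tiny_lm_config), [P.ProteinRecord("p", "M")])


class TestGradients:
    def test_backprop_matches_finite_differences(self, tiny_lm_config):
        cfg = tiny_lm_config
        rng = np.random.default_rng(2)
        letters = list(P.CANONICAL_AA) + ["X"]
        recs = [P.ProteinRecord(f"p{i}", "".join(rng.choice(letters, size=rng.integers(3, 9))))
                for i in range(4)]
        toks = [P.tokenize(r, cfg) for r in recs]
        batch = L._make_batch(toks, L._target_class(cfg), cfg.vocabulary.index(L.PAD))
        params = L._init_parameters(cfg, np.random.default_rng(0))
        _, grads = L._loss_and_grads(params, cfg.num_layers, batch)
        eps = 1e-5
        check = np.random.default_rng(1)
        for name in ["embed", "fwd_Wx0", "fwd_Wh1", "bwd_Wh0", "fwd_b0",
                     "fwd_Wout", "bwd_bout", "bwd_Wx1"]:
            arr = params[name]
            for _ in range(3):
                ij = tuple(check.integers(s) for s in arr.shape)
                orig = arr[ij]
                arr[ij] = orig + eps
                up, _ = L._loss_and_grads(params, cfg.num_layers, batch)
                arr[ij] = orig - eps
                down, _ = L._loss_and_grads(params, cfg.num_layers, batch)
                arr[ij] = orig
                numeric = (up - down) / (2 * eps)
                assert grads[name][ij] == pytest.approx(numeric, rel=1e-3, abs=1e-7)


class TestTraining:
    def test_rejects_degenerate_inputs(self, tiny_lm_config):
        rec = P.ProteinRecord("p", "MKV")
        with pytest.raises(ValueError):
            P.train_lm([], tiny_lm_config, 5)
        with pytest.raises(ValueError):
            P.train_lm([rec], tiny_lm_config, 0)
        with pytest.raises(ValueError, match="length"):
            P.train_lm([P.ProteinRecord("p", "M")], tiny_lm_config, 5)

    def test_same_seed_bit_identical_log(self, tiny_lm_config, tiny_records):
        a = P.train_lm(tiny_records, tiny_lm_config, 5)
        b = P.train_lm(tiny_records, tiny_lm_config, 5)
        assert a.training_log == b.training_log

    def test_loss_decreases_on_structured_data(self, tiny_lm_config):
        corpus = P.generate_corpus(P.FamilySpec(
            n_families=3, members_per_family=20, background_length=40, seed=2,
            residue_distribution=P.synthetic.natural_composition()))
        model = P.train_lm(corpus.proteins, tiny_lm_config, 60)
        log = np.asarray(model.training_log)
        assert log[-10:].mean() < log[:10].mean()


class TestEmbedding:
    def test_dimension_and_determinism(self, tiny_lm_config, tiny_records):
        model = P.untrained_lm(tiny_lm_config)
        e1 = P.embed(model, tiny_records[0])
        e2 = P.embed(model, tiny_records[0])
        assert e1.shape == (tiny_lm_config.embedding_dim,)
        assert np.array_equal(e1, e2)

    def test_length_one_sequence_is_its_single_state(self, tiny_lm_config):
        model = P.untrained_lm(tiny_lm_config)
        e = P.embed(model, P.ProteinRecord("p", "M"))
        assert e.shape == (tiny_lm_config.embedding_dim,)
        assert np.any(e != 0)

    def test_batch_padding_does_not_leak(self, tiny_lm_config, tiny_records):
        model = P.untrained_lm(tiny_lm_config)
        batched = P.embed_many(model, tiny_records)
        single = np.vstack([P.embed(model, r) for r in tiny_records])
        assert np.allclose(batched, single, atol=1e-12)

    def test_embedding_matrix_provenance(self, tiny_lm_config, tiny_records):
        m = P.embedding_matrix(P.untrained_lm(tiny_lm_config), tiny_records)
        assert m.method == "lm-mean" and m.dim == tiny_lm_config.embedding_dim


class TestPersistence:
    def test_checkpoint_round_trip(self, tmp_path, tiny_lm_config, tiny_records):
        model = P.train_lm(tiny_records, tiny_lm_config, 3)
        P.save_lm(model, tmp_path / "ckpt")
        loaded = P.load_lm(tmp_path / "ckpt")
        assert loaded.config == model.config
        assert loaded.training_log == model.training_log
        for k, v in model.parameters.items():
            assert np.array_equal(loaded.parameters[k], v)
        assert P.ece(loaded, tiny_records) == P.ece(model, tiny_records)


class TestEstimator:
    def test_cloneable_with_params(self):
        est = P.BiLSTMEmbedder(hidden_units=8, steps=2)
        assert clone(est).get_params()["hidden_units"] == 8

    def test_fit_transform_shapes(self, tiny_records):
        est = P.BiLSTMEmbedder(num_layers=1, hidden_units=8, steps=2, batch_size=4)
        out = est.fit(tiny_records).transform(tiny_records)
        assert out.shape == (len(tiny_records), 16)
        assert est.training_log_ and est.score(tiny_records) < 0
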
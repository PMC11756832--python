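"""Assembly contracts: shapes, pooling, parameter budgets, checkpoints."""

import numpy as np
import pytest

from frailvoice import models as md
from frailvoice.nn import MLPHead


@pytest.fixture(scope="module")
def fast_speech_module():
    cfg, _, _ = md.assembly_configs("SpeechAI", "fast")
    return md.SpeechEncoderModule(cfg, seed=3)


class TestSpeechEmbedding:
    def test_embedding_length_is_model_dim(self, fast_speech_module):
        rng = np.random.default_rng(0)
        vec = fast_speech_module.embed(rng.normal(size=(120, 60)))
        assert vec.shape == (fast_speech_module.config.model_dim,)

    def test_chunk_count_is_ceiling_division(self, fast_speech_module):
        x = np.zeros((1250, 60))
        assert len(fast_speech_module.chunks(x)) == 3  # 500+500+250

    def test_chunk_permutation_invariance(self, fast_speech_module):
        """Mean pooling over chunks makes the clip embedding order-invariant."""
        rng = np.random.default_rng(1)
        c = fast_speech_module.config.chunk_frames
        x = rng.normal(size=(3 * c, 60))
        permuted = np.concatenate([x[2 * c :], x[:c], x[c : 2 * c]])
        a = fast_speech_module.embed(x)
        b = fast_speech_module.embed(permuted)
        assert np.max(np.abs(a - b)) < 1e-6

    def test_wrong_column_count_rejected(self, fast_speech_module):
        with pytest.raises(ValueError):
            fast_speech_module.embed(np.zeros((50, 59)))

    def test_inference_is_deterministic(self, fast_speech_module):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(200, 60))
        assert np.array_equal(
            fast_speech_module.embed(x), fast_speech_module.embed(x)
        )


@pytest.fixture(scope="module")
def demo():
    return md.DemographicEmbedding(md.DemographicEmbeddingConfig(), seed=4)


class TestDemographicEmbedding:
    def test_same_decade_same_vector(self, demo):
        assert np.array_equal(demo.embed(65, "male"), demo.embed(69, "male"))

    def test_vector_length_six(self, demo):
        assert demo.embed(83, "female").shape == (6,)

    def test_distinct_bins_differ(self, demo):
        assert not np.array_equal(demo.embed(65, "male"), demo.embed(75, "male"))
        assert not np.array_equal(demo.embed(65, "male"), demo.embed(65, "female"))

    def test_age_below_range_clamps_with_warning(self, demo):
        with pytest.warns(UserWarning, match="clamping"):
            v = demo.embed(42, "female")
        assert np.array_equal(v, demo.embed(55, "female"))

    def test_unknown_sex_rejected(self, demo):
        with pytest.raises(ValueError):
            demo.embed(70, "other")


class TestPredict:
    @pytest.mark.parametrize("kind", md.KINDS)
    def test_probability_in_unit_interval(self, kind):
        assembly = md.build_assembly(kind, "fast", seed=5)
        rng = np.random.default_rng(6)
        p = assembly.predict(
            features=rng.normal(size=(80, 60)) if assembly.speech else None,
            age=72, sex="female",
        ) if assembly.demo else assembly.predict(features=rng.normal(size=(80, 60)))
        assert 0.0 <= p <= 1.0

    def test_zeroed_classifier_gives_exactly_half(self):
        assembly = md.build_assembly("SpeechAI", "fast", seed=7)
        for w in assembly.classifier.parameters().values():
            w[...] = 0.0
        p = assembly.predict(features=np.random.default_rng(8).normal(size=(60, 60)))
        assert p == 0.5

    def test_missing_branch_input_rejected(self):
        assembly = md.build_assembly("DemoSpeechAI", "fast", seed=9)
        with pytest.raises(ValueError):
            assembly.predict(age=70, sex="male")  # speech features absent

    def test_combined_model_shares_demographic_slice_with_demo_model(self):
        """With identical demographic tables, the demographic part of the
        combined model's pre-classifier vector equals the demographics-only
        model's embedding."""
        both = md.build_assembly("DemoSpeechAI", "fast", seed=10)
        demo_only = md.build_assembly("DemoAI", "fast", seed=11)
        demo_only.demo.age_table[...] = both.demo.age_table
        demo_only.demo.sex_table[...] = both.demo.sex_table
        feats = np.random.default_rng(12).normal(size=(70, 60))
        joint = both.joint_vector(features=feats, age=77, sex="male")
        d = both.speech.config.model_dim
        assert np.array_equal(joint[d:], demo_only.joint_vector(age=77, sex="male"))


@pytest.fixture(scope="module")
def reports():
    return {
        kind: md.count_parameters(md.build_assembly(kind, "conformance"))
        for kind in md.KINDS
    }


class TestParameterBudgets:
    def test_speech_model_embedding_share_rounds_to_96(self, reports):
        assert round(reports["SpeechAI"].embedding_share) == 96

    def test_speech_model_totals(self, reports):
        r = reports["SpeechAI"]
        assert 580_000 <= r.total <= 650_000
        assert 550_000 <= r.per_module["speech_embedding"] <= 620_000
        assert 20_000 <= r.per_module["classifier"] <= 30_000

    def test_demo_model_total(self, reports):
        assert 21_000 <= reports["DemoAI"].total <= 31_000

    def test_combined_model_budgets(self, reports):
        r = reports["DemoSpeechAI"]
        assert 590_000 <= r.total <= 660_000
        assert 29_000 <= r.per_module["classifier"] <= 39_000

    def test_finetuned_fraction_small_for_speech_models(self, reports):
        assert reports["SpeechAI"].trained_fraction_finetune <= 0.10
        assert reports["DemoSpeechAI"].trained_fraction_finetune <= 0.10
        assert reports["DemoAI"].trained_fraction_finetune == 1.0

    def test_counts_are_exact_integers(self, reports):
        for r in reports.values():
            assert r.total == sum(r.per_module.values())
            assert all(isinstance(v, int) and v >= 0 for v in r.per_module.values())


class TestCheckpoints:
    def test_round_trip(self, tmp_path):
        a = md.build_assembly("DemoSpeechAI", "fast", seed=13)
        b = md.build_assembly("DemoSpeechAI", "fast", seed=14)
        feats = np.random.default_rng(15).normal(size=(60, 60))
        pa = a.predict(features=feats, age=66, sex="female")
        md.save_checkpoint(a, tmp_path / "ck.npz", profile="fast")
        md.load_checkpoint(b, tmp_path / "ck.npz")
        assert b.predict(features=feats, age=66, sex="female") == pytest.approx(pa)
        assert (tmp_path / "ck.json").exists()

    def test_structure_mismatch_rejected(self, tmp_path):
        a = md.build_assembly("SpeechAI", "fast", seed=16)
        md.save_checkpoint(a, tmp_path / "ck.npz")
        b = md.build_assembly("DemoAI", "fast", seed=17)
        with pytest.raises(KeyError):
            md.load_checkpoint(b, tmp_path / "ck.npz")
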
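"""Joint loss, entity-level evaluation, training loop, CLI and estimator."""

import json

import numpy as np
import pytest

from gridner.corpus_io import EntityMention, LabeledSentence
from gridner.prefix_encoder import EncoderConfig
from gridner.synthetic_corpus import SynthesisConfig, generate_corpus
from gridner.train_eval import (
    EvalResult,
    TrainConfig,
    TrainedModel,
    evaluate_entities,
    predict,
    summarize_runs,
    total_loss,
    train_model,
)

from conftest import random_flat_sentence


def reference_prf(pred_sets, gold_sets):
    """Independent exact-match counter (set arithmetic, no shared code)."""
    tp = sum(len(set(p) & set(g)) for p, g in zip(pred_sets, gold_sets))
    np_, ng = sum(map(len, pred_sets)), sum(map(len, gold_sets))
    p = 100 * tp / np_ if np_ else 0.0
    r = 100 * tp / ng if ng else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return round(p, 2), round(r, 2), round(f, 2)


class TestTotalLoss:
    def test_alpha_zero_is_baseline(self):
        assert total_loss(1.7, 99.0, 0.0) == 1.7

    def test_weighted_sum(self):
        assert abs(total_loss(1.0, 0.5, 0.1) - 1.05) < 1e-12

    def test_gradient_is_weighted_sum_of_gradients(self):
        """d(total)/dθ = d(bioner)/dθ + α d(guidance)/dθ, checked by finite
        differences through a shared parameter."""
        from gridner._autodiff import Tensor

        rng = np.random.default_rng(0)
        theta = Tensor(rng.normal(size=4), requires_grad=True)
        alpha = 0.3

        def make_losses(t):
            a = (t**2).sum()
            b = (t.tanh()).sum()
            return a, b

        a, b = make_losses(theta)
        (a + alpha * b).backward()
        analytic = theta.grad.copy()
        eps = 1e-6
        for i in range(4):
            orig = theta.data[i]
            vals = []
            for delta in (eps, -eps):
                theta.data[i] = orig + delta
                a, b = make_losses(theta)
                vals.append(a.item() + alpha * b.item())
            theta.data[i] = orig
            assert abs(analytic[i] - (vals[0] - vals[1]) / (2 * eps)) < 1e-5


class TestEvaluateEntities:
    def test_perfect_predictions(self):
        gold = [{EntityMention(0, 1, "C")}, {EntityMention(2, 2, "D")}]
        r = evaluate_entities(gold, gold)
        assert (r.precision, r.recall, r.f1) == (100.0, 100.0, 100.0)

    def test_off_by_one_span_counts_fp_and_fn(self):
        gold = [{EntityMention(0, 2, "C")}]
        pred = [{EntityMention(0, 1, "C")}]
        r = evaluate_entities(pred, gold)
        assert r.tp == 0 and r.fp == 1 and r.fn == 1
        assert r.f1 == 0.0

    def test_type_mismatch_is_an_error(self):
        gold = [{EntityMention(0, 1, "Chemical")}]
        pred = [{EntityMention(0, 1, "Disease")}]
        r = evaluate_entities(pred, gold)
        assert r.tp == 0 and r.fp == 1 and r.fn == 1

    def test_agrees_with_independent_reference(self):
        rng = np.random.default_rng(1)
        pred_sets, gold_sets = [], []
        for _ in range(1000):
            g = random_flat_sentence(rng)
            gold_sets.append(set(g.mentions))
            # perturb gold into a prediction: drop/shift/retype some mentions
            p = set()
            for m in g.mentions:
                u = rng.random()
                if u < 0.5:
                    p.add(m)
                elif u < 0.7 and m.end + 1 < len(g):
                    p.add(EntityMention(m.start, m.end + 1, m.etype))
                elif u < 0.85:
                    p.add(EntityMention(m.start, m.end, "X"))
            pred_sets.append(p)
        r = evaluate_entities(pred_sets, gold_sets)
        assert (r.precision, r.recall, r.f1) == reference_prf(pred_sets, gold_sets)

    def test_summary_rounding(self):
        s = summarize_runs([90.0, 90.5, 91.0])
        assert s == {"mean": 90.5, "std": 0.41, "max": 91.0, "runs": 3}


@pytest.fixture(scope="module")
def trained_tiny():
    corpus = generate_corpus(SynthesisConfig(n_sentences=30, mean_length=8,
                                             max_length=12, seed=21))
    ec = EncoderConfig(layers=1, heads=2, hidden_dim=16, prefix_length=2,
                       word_dim=16)
    tc = TrainConfig(epochs=4, seed=3, alpha=0.01, batch_size=8)
    return corpus, train_model(corpus, ec, tc, d_g=16)


class TestTraining:
    def test_history_logs_all_loss_components(self, trained_tiny):
        _, tm = trained_tiny
        assert len(tm.history) == 4
        for rec in tm.history:
            assert {"loss_bioner", "loss_guidance", "loss_total"} <= set(rec)
            assert rec["loss_total"] >= rec["loss_bioner"]

    def test_fixed_seed_reproduces_metrics(self, trained_tiny):
        corpus, tm = trained_tiny
        ec = EncoderConfig(layers=1, heads=2, hidden_dim=16, prefix_length=2,
                           word_dim=16)
        tc = TrainConfig(epochs=4, seed=3, alpha=0.01, batch_size=8)
        tm2 = train_model(corpus, ec, tc, d_g=16)
        assert tm.history == tm2.history
        assert predict(corpus, tm) == predict(corpus, tm2)

    def test_checkpoint_round_trip(self, trained_tiny, tmp_path):
        corpus, tm = trained_tiny
        path = str(tmp_path / "model.npz")
        tm.save(path)
        back = TrainedModel.load(path)
        assert predict(corpus, back) == predict(corpus, tm)

    def test_empty_corpus_is_hard_error(self):
        with pytest.raises(ValueError):
            train_model([], EncoderConfig(), TrainConfig())

    def test_alpha_zero_skips_guidance(self):
        corpus = generate_corpus(SynthesisConfig(n_sentences=10, mean_length=6,
                                                 max_length=10, seed=22))
        ec = EncoderConfig(layers=1, heads=2, hidden_dim=16, prefix_length=2,
                           word_dim=16)
        tm = train_model(corpus, ec, TrainConfig(epochs=1, seed=0, alpha=0.0), d_g=16)
        assert tm.history[0]["loss_guidance"] == 0.0
        assert tm.history[0]["loss_total"] == pytest.approx(
            tm.history[0]["loss_bioner"])


class TestEstimator:
    def test_sklearn_params_round_trip(self):
        from gridner.estimator import GridNERTagger

        t = GridNERTagger(alpha=0.1, epochs=2)
        params = t.get_params()
        assert params["alpha"] == 0.1
        t.set_params(alpha=0.001)
        assert t.alpha == 0.001

    def test_unfitted_predict_raises(self):
        from gridner.estimator import GridNERTagger

        with pytest.raises(RuntimeError, match="not fitted"):
            GridNERTagger().predict([])

    def test_fit_predict_score(self):
        from gridner.estimator import GridNERTagger

        corpus = generate_corpus(SynthesisConfig(n_sentences=24, mean_length=7,
                                                 max_length=10, seed=23))
        t = GridNERTagger(layers=1, heads=2, hidden_dim=16, prefix_length=2,
                          word_dim=16, d_g=16, epochs=3, seed=1)
        t.fit(corpus)
        preds = t.predict(corpus)
        assert len(preds) == len(corpus)
        assert 0.0 <= t.score(corpus) <= 100.0
        assert len(t.history_) == 3


class TestCLI:
    def test_gen_encode_decode_pipeline(self, tmp_path):
        from click.testing import CliRunner

        from gridner.cli import main

        runner = CliRunner()
        corpus_path = tmp_path / "corpus.conll"
        r = runner.invoke(main, ["gen", "--seed", "5", "--n-sentences", "12",
                                 "--out", str(corpus_path)])
        assert r.exit_code == 0, r.output
        grids_path = tmp_path / "grids.jsonl"
        r = runner.invoke(main, ["encode", "--corpus", str(corpus_path),
                                 "--out", str(grids_path)])
        assert r.exit_code == 0, r.output
        out_path = tmp_path / "decoded.jsonl"
        r = runner.invoke(main, ["decode", "--grids", str(grids_path),
                                 "--types", "Chemical", "--out", str(out_path)])
        assert r.exit_code == 0, r.output
        from gridner.corpus_io import read_conll

        gold = read_conll(corpus_path)
        with open(out_path) as fh:
            for line, sent in zip(fh, gold):
                rec = json.loads(line)
                got = {EntityMention(a, b, t) for a, b, t in rec["mentions"]}
                assert got == sent.mentions

    def test_gen_requires_seed(self, tmp_path):
        from click.testing import CliRunner

        from gridner.cli import main

        r = CliRunner().invoke(main, ["gen", "--out", str(tmp_path / "x.conll")])
        assert r.exit_code != 0

    def test_train_predict_eval_viz(self, tmp_path):
        import yaml
        from click.testing import CliRunner

        from gridner.cli import main

        runner = CliRunner()
        corpus_path = tmp_path / "c.conll"
        runner.invoke(main, ["gen", "--seed", "6", "--n-sentences", "10",
                             "--out", str(corpus_path)])
        cfg = dict(layers=1, heads=2, hidden_dim=16, prefix_length=2,
                   word_dim=16, d_g=16, epochs=1, seed=0)
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        ckpt = tmp_path / "m.npz"
        r = runner.invoke(main, ["train", "--config", str(cfg_path), "--corpus",
                                 str(corpus_path), "--checkpoint", str(ckpt)])
        assert r.exit_code == 0, r.output
        pred_path = tmp_path / "pred.conll"
        r = runner.invoke(main, ["predict", "--corpus", str(corpus_path),
                                 "--checkpoint", str(ckpt), "--out", str(pred_path)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["eval", "--pred", str(pred_path),
                                 "--gold", str(corpus_path)])
        assert r.exit_code == 0, r.output
        scores = json.loads(r.output.strip().splitlines()[-1])
        assert set(scores) == {"precision", "recall", "f1"}
        img = tmp_path / "attn.png"
        for mode in ("averaged", "single-head", "all-heads"):
            r = runner.invoke(main, ["viz-attn", "--corpus", str(corpus_path),
                                     "--checkpoint", str(ckpt), "--mode", mode,
                                     "--out", str(img)])
            assert r.exit_code == 0, r.output
            assert img.exists() and img.stat().st_size > 0
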
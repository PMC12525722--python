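"""Metrics, the training loop and the repetition protocol."""

import numpy as np
import pytest

from ddilink.train_eval import (
    ExperimentConfig,
    auprc,
    auroc,
    compute_metrics,
    f1_accuracy,
    prepare_split_data,
    run_experiment,
    sweep,
    train,
    write_loss_log,
)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_three_of_four_concordant(self):
        assert auroc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_invariant_under_joint_permutation(self, rng):
        s = rng.uniform(size=12)
        y = rng.integers(0, 2, 12)
        y[0], y[1] = 0, 1
        perm = rng.permutation(12)
        assert auroc(s, y) == pytest.approx(auroc(s[perm], y[perm]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])


class TestAuprc:
    def test_perfect_separation(self):
        assert auprc([0.9, 0.8, 0.1], [1, 1, 0]) == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        assert auprc([0.5] * 10, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]) == pytest.approx(0.3)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            auprc([0.5, 0.6], [0, 0])


class TestF1Accuracy:
    def test_all_correct(self):
        assert f1_accuracy([0.9, 0.1], [1, 0]) == (1.0, 1.0)

    def test_balanced_confusion(self):
        # TP=1, FP=1, FN=1, TN=1
        f1, acc = f1_accuracy([0.9, 0.9, 0.1, 0.1], [1, 0, 1, 0])
        assert f1 == pytest.approx(0.5)
        assert acc == pytest.approx(0.5)

    def test_zero_recall_convention(self):
        f1, _ = f1_accuracy([0.1, 0.2], [1, 1])
        assert f1 == 0.0


def tiny_config(**kw):
    base = dict(emb_dim=12, mol_layers=2, intra_layers=2, epochs=3, patience=5,
                batch_size=4096, seeds=(0,))
    base.update(kw)
    return ExperimentConfig(**base)


class TestTrainLoop:
    def test_runs_and_reports_all_loss_components(self, toy_benchmark):
        drugs, network, _ = toy_benchmark
        data = prepare_split_data(drugs, network, seed=0)
        res = train(tiny_config(), data, seed=0)
        rec = res.loss_log[0]
        assert rec["total"] == pytest.approx(
            rec["Ls"] + rec["alpha"] * rec["Lom"] + rec["gamma"] * rec["Lfm"]
        )
        assert set(res.metrics) >= {"train", "test"}
        for m in res.metrics.values():
            assert all(0 <= v <= 1 for v in m.values())

    def test_deterministic_per_seed(self, toy_benchmark):
        drugs, network, _ = toy_benchmark
        data = prepare_split_data(drugs, network, seed=1)
        r1 = train(tiny_config(), data, seed=1)
        r2 = train(tiny_config(), data, seed=1)
        for k in r1.mol_encoder.params:
            np.testing.assert_array_equal(
                r1.mol_encoder.params[k].data, r2.mol_encoder.params[k].data
            )
        assert r1.metrics == r2.metrics

    def test_no_om_ablation_equals_alpha_zero(self, toy_benchmark):
        drugs, network, _ = toy_benchmark
        data = prepare_split_data(drugs, network, seed=0)
        a = train(tiny_config(ablation=("no_om",)), data, seed=0)
        b = train(tiny_config(alpha=0.0), data, seed=0)
        assert [r["total"] for r in a.loss_log] == [r["total"] for r in b.loss_log]

    def test_no_fm_ablation_equals_gamma_zero(self, toy_benchmark):
        drugs, network, _ = toy_benchmark
        data = prepare_split_data(drugs, network, seed=0)
        a = train(tiny_config(ablation=("no_fm",)), data, seed=0)
        b = train(tiny_config(gamma=0.0), data, seed=0)
        assert [r["total"] for r in a.loss_log] == [r["total"] for r in b.loss_log]

    def test_no_pretrain_ablation_ignores_checkpoint(self, toy_benchmark):
        from ddilink.encoders import MolecularEncoder

        drugs, network, _ = toy_benchmark
        data = prepare_split_data(drugs, network, seed=0)
        pre = MolecularEncoder(hidden_dim=12, num_layers=2, seed=99)
        for t in pre.params.values():
            t.data[:] = 7.0  # sentinel values a random init cannot produce
        cfg = tiny_config(epochs=0)
        with_ckpt = train(cfg, data, pretrained=pre, seed=0)
        assert np.all(with_ckpt.mol_encoder.params["W0"].data == 7.0)
        ablated = train(tiny_config(epochs=0, ablation=("no_pretrain",)), data,
                        pretrained=pre, seed=0)
        assert not np.any(ablated.mol_encoder.params["W0"].data == 7.0)

    def test_empty_train_split_rejected(self, toy_benchmark):
        drugs, network, _ = toy_benchmark
        data = prepare_split_data(drugs, network, seed=0)
        data.pairs["train"] = (np.array([], dtype=np.intp),) * 2 + (np.array([], dtype=np.intp),)
        with pytest.raises(ValueError):
            train(tiny_config(), data, seed=0)


class TestProtocol:
    def test_single_seed_report_has_zero_std(self, toy_benchmark):
        drugs, network, _ = toy_benchmark
        report, _ = run_experiment(tiny_config(), drugs, network)
        assert (report.aggregate.filter(like="_std") == 0).all().all()

    def test_same_seed_list_twice_is_identical(self, toy_benchmark):
        drugs, network, _ = toy_benchmark
        cfg = tiny_config(seeds=(3, 4))
        r1, _ = run_experiment(cfg, drugs, network)
        r2, _ = run_experiment(cfg, drugs, network)
        assert r1.per_seed.equals(r2.per_seed)

    def test_report_shape_per_seed_rows(self, toy_benchmark):
        drugs, network, _ = toy_benchmark
        cfg = tiny_config(seeds=(0, 1, 2))
        report, results = run_experiment(cfg, drugs, network)
        assert len(results) == 3
        assert set(report.per_seed["seed"]) == {0, 1, 2}
        assert set(report.aggregate["split"]) <= {"train", "valid", "test"}

    def test_sweep_single_value_matches_base_run(self, toy_benchmark):
        drugs, network, _ = toy_benchmark
        cfg = tiny_config(alpha=1.0)
        table = sweep(cfg, drugs, network, "alpha", [1.0])
        base, _ = run_experiment(cfg, drugs, network)
        test_row = table[table["split"] == "test"].iloc[0]
        assert test_row["auroc_mean"] == pytest.approx(base.mean("test", "auroc"))

    def test_sweep_row_count(self, toy_benchmark):
        drugs, network, _ = toy_benchmark
        table = sweep(tiny_config(), drugs, network, "gamma", [0.5, 1.0])
        assert sorted(set(table["gamma"])) == [0.5, 1.0]

    def test_unknown_sweep_parameter_rejected(self, toy_benchmark):
        drugs, network, _ = toy_benchmark
        with pytest.raises(ValueError):
            sweep(tiny_config(), drugs, network, "delta", [1.0])


def test_loss_log_roundtrips_as_jsonlines(tmp_path, toy_benchmark):
    import json

    drugs, network, _ = toy_benchmark
    data = prepare_split_data(drugs, network, seed=0)
    res = train(tiny_config(), data, seed=0)
    path = tmp_path / "loss.jsonl"
    write_loss_log(path, res.loss_log)
    back = [json.loads(line) for line in path.read_text().splitlines()]
    assert back == res.loss_log
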
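import dataclasses
import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import precision_recall_fscore_support

from texfuse import (
    ExperimentConfig,
    FusionNetSpec,
    SyntheticSpec,
    TrainConfig,
    build_network,
    compute_metrics,
    extract_features,
    generate_arrays,
    make_folds,
    run_experiment,
    train_network,
)
from texfuse.train_eval import SWEEP_AXES, sweep

from oracles import metrics_reference


class TestMakeFolds:
    def test_exact_divisibility_gives_one_per_class_per_fold(self):
        labels = [(f"s{i}", "a" if i < 5 else "b") for i in range(10)]
        plan = make_folds(labels, k=5, seed=0)
        for fold in range(5):
            ids = plan.fold_ids(fold)
            assert len(ids) == 2
            classes = {dict(labels)[sid] for sid in ids}
            assert classes == {"a", "b"}

    def test_deterministic_under_seed(self):
        labels = [(f"s{i}", str(i % 2)) for i in range(20)]
        assert make_folds(labels, 4, seed=7) == make_folds(labels, 4, seed=7)
        assert make_folds(labels, 4, seed=7) != make_folds(labels, 4, seed=8)

    def test_balanced_remainder_rule(self):
        labels = [(f"s{i}", "x") for i in range(13)] + [(f"t{i}", "y") for i in range(5)]
        plan = make_folds(labels, k=5, seed=3)
        sizes = sorted(
            sum(1 for s in plan.fold_ids(f) if s.startswith("s")) for f in range(5)
        )
        assert sizes == [2, 2, 3, 3, 3]

    def test_folds_partition_the_dataset(self):
        labels = [(f"s{i}", str(i % 3)) for i in range(23)]
        plan = make_folds(labels, k=4, seed=1)
        seen = [s for f in range(4) for s in plan.fold_ids(f)]
        assert sorted(seen) == sorted(s for s, _ in labels)

    def test_class_smaller_than_k_rejected(self):
        labels = [("a", "x"), ("b", "x"), ("c", "y")]
        with pytest.raises(ValueError):
            make_folds(labels, k=2, seed=0)


class TestComputeMetrics:
    def test_worked_confusion_example(self):
        # positive class: tp=3 fp=1 tn=4 fn=2
        truth = [1] * 5 + [0] * 5
        pred = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        rep = compute_metrics(pred, truth)
        pc = rep.per_class["1"]
        assert (pc["tp"], pc["fp"], pc["tn"], pc["fn"]) == (3, 1, 4, 2)
        assert rep.accuracy == pytest.approx(0.7)
        assert pc["precision"] == pytest.approx(0.75)
        assert pc["recall"] == pytest.approx(0.6)
        assert pc["f1"] == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_perfect_classifier(self):
        for avg in ("weighted", "macro"):
            rep = compute_metrics([0, 1, 0, 1], [0, 1, 0, 1], avg)
            assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 1.0

    def test_single_class_predictions_on_balanced_truth(self):
        rep = compute_metrics([0] * 10, [0] * 5 + [1] * 5)
        assert rep.accuracy == 0.5 and rep.recall == 0.5

    @settings(max_examples=50, derandomize=True)
    @given(
        seed=st.integers(min_value=0, max_value=2**31 - 1),
        n=st.integers(min_value=2, max_value=40),
        avg=st.sampled_from(("weighted", "macro")),
    )
    def test_matches_counting_oracle_and_sklearn(self, seed, n, avg):
        gen = np.random.Generator(np.random.PCG64(seed))
        truth = gen.integers(0, 2, n).tolist()
        pred = gen.integers(0, 2, n).tolist()
        rep = compute_metrics(pred, truth, avg)
        acc, prec, rec, f1 = metrics_reference(pred, truth, avg)
        assert rep.accuracy == pytest.approx(acc)
        assert rep.precision == pytest.approx(prec)
        assert rep.recall == pytest.approx(rec)
        assert rep.f1 == pytest.approx(f1)
        if len(set(truth)) == 2:  # sklearn cross-check where labels are complete
            sp, sr, sf, _ = precision_recall_fscore_support(
                truth, pred, average=avg, labels=[0, 1], zero_division=0
            )
            assert rep.precision == pytest.approx(sp)
            assert rep.recall == pytest.approx(sr)
            assert rep.f1 == pytest.approx(sf)

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_weighted_recall_equals_accuracy_in_binary(self, seed):
        gen = np.random.Generator(np.random.PCG64(seed))
        truth = gen.integers(0, 2, 25).tolist()
        pred = gen.integers(0, 2, 25).tolist()
        rep = compute_metrics(pred, truth, "weighted")
        assert rep.recall == pytest.approx(rep.accuracy, abs=1e-12)

    def test_f1_between_precision_and_recall_per_class(self):
        rep = compute_metrics([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        for pc in rep.per_class.values():
            lo, hi = sorted((pc["precision"], pc["recall"]))
            assert lo - 1e-12 <= pc["f1"] <= hi + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0])


TINY = ExperimentConfig(
    synthetic=SyntheticSpec(n_per_class=8, image_size=(32, 32), seed=5),
    model=FusionNetSpec(width_multiplier=0.03125, input_size=(32, 32)),
    train=TrainConfig(learning_rate=3e-4, epochs=2, batch_size=8, seed=1),
    k_folds=2,
)


class TestRunExperiment:
    def test_bundle_structure(self, tmp_path):
        bundle = run_experiment(TINY, out_dir=tmp_path)
        assert bundle["n_folds_completed"] == 2
        assert len(bundle["per_fold"]) == 2
        assert set(bundle["mean"]) == {"accuracy", "precision", "recall", "f1"}
        assert (tmp_path / "metrics.json").exists()
        assert (tmp_path / "predictions.csv").exists()
        assert (tmp_path / "resolved_config.yaml").exists()
        saved = json.loads((tmp_path / "metrics.json").read_text())
        assert saved["seed"] == 1

    def test_rerun_is_deterministic(self):
        a = run_experiment(TINY)
        b = run_experiment(TINY)
        assert a["mean"] == b["mean"]
        assert a["per_fold"] == b["per_fold"]

    def test_no_texture_ablation_same_shape(self):
        cfg = dataclasses.replace(TINY, use_texture=False)
        bundle = run_experiment(cfg)
        assert bundle["use_texture"] is False
        assert len(bundle["per_fold"]) == 2

    def test_missing_data_source_rejected(self):
        with pytest.raises(ValueError):
            run_experiment(ExperimentConfig(synthetic=None, data_dir=None))


def test_learning_sanity_on_separable_textures():
    """The scaled-down fused model fits a texture-separable training set
    (majority vote over 3 seeds, training accuracy > 0.9 in 10 epochs)."""
    spec = SyntheticSpec(n_per_class=30, seed=4)
    images, labels, _ = generate_arrays(spec)
    cfg = ExperimentConfig(synthetic=spec)
    depth, tex = extract_features(images, cfg)
    labels = np.asarray(labels)
    wins = 0
    for seed in (0, 1, 2):
        net = build_network(cfg.model, seed=seed)
        train_network(
            net, depth, tex, labels,
            TrainConfig(learning_rate=3e-4, epochs=10, batch_size=16, seed=seed),
        )
        logits = np.concatenate(
            [net.predict_logits(depth[i : i + 32], tex[i : i + 32]) for i in range(0, 60, 32)]
        )
        wins += (logits.argmax(1) == labels).mean() > 0.9
    assert wins >= 2


def test_sweep_axis_rosters():
    assert len(SWEEP_AXES["lbp_variant"]) == 6
    assert SWEEP_AXES["hog_cell_size"] == (2, 4, 8, 16, 32)
    assert len(SWEEP_AXES["fusion_position"]) == 6
    with pytest.raises(ValueError):
        sweep(TINY, "nonsense")


def test_sweep_produces_table(tmp_path):
    cfg = dataclasses.replace(
        TINY, train=TrainConfig(learning_rate=3e-4, epochs=1, batch_size=8, seed=0)
    )
    table = sweep(cfg, "hog_cell_size", out_csv=tmp_path / "t.csv")
    assert list(table["hog_cell_size"]) == [2, 4, 8, 16, 32]
    assert {"accuracy", "precision", "recall", "f1"} <= set(table.columns)
    assert (tmp_path / "t.csv").exists()


def test_config_yaml_round_trip(tmp_path):
    cfgfile = tmp_path / "exp.yaml"
    cfgfile.write_text(
        """
synthetic: {n_per_class: 8, image_size: [32, 32], seed: 5}
model: {width_multiplier: 0.03125, input_size: [32, 32], fusion_position: block2}
train: {learning_rate: 0.0003, epochs: 2, batch_size: 8, seed: 1}
k_folds: 2
"""
    )
    cfg = ExperimentConfig.from_yaml(cfgfile)
    assert cfg.model.fusion_position == "block2"
    assert cfg.synthetic.n_per_class == 8
    assert cfg.train.epochs == 2
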
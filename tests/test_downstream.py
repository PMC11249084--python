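"""Scaffold splitting, metric closed forms and fine-tuning contracts."""

import numpy as np
import pytest

import conformcl as c
from conformcl.downstream import MAE, RMSE, ROC_AUC, evaluate_metric


def _make_dataset(smiles, targets=None, task_type="regression", n_tasks=1):
    targets = targets if targets is not None else np.zeros((len(smiles), n_tasks))
    records = [
        c.MoleculeRecord(s, np.atleast_1d(t), np.ones(n_tasks, dtype=bool))
        for s, t in zip(smiles, targets)
    ]
    return c.Dataset(records, task_type, n_tasks)


class TestScaffoldSplit:
    def test_unique_scaffold_fixture_splits_80_10_10(self):
        ds = c.generate_fixture_dataset(100, seed=2, unique_scaffolds=True)
        split = c.scaffold_split(ds)
        assert (len(split.train), len(split.valid), len(split.test)) == (80, 10, 10)
        c.assert_no_scaffold_leakage(ds, split)

    def test_whole_groups_stay_together(self):
        ds = c.generate_fixture_dataset(60, seed=4)
        split = c.scaffold_split(ds)
        c.assert_no_scaffold_leakage(ds, split)
        assert sorted(split.all_indices()) == list(range(60))
        assert not (set(split.train) & set(split.valid) & set(split.test))

    def test_single_scaffold_dataset_goes_to_train_with_warning(self):
        smiles = [ch + "C1CCCCC1" for ch in ("CC", "CCC", "CCCC", "CCO")]
        ds = _make_dataset(smiles)
        with pytest.warns(UserWarning, match="exceeds every split"):
            split = c.scaffold_split(ds)
        assert len(split.train) == 4 and not split.valid and not split.test

    def test_greedy_fill_on_8_1_1_groups(self):
        big = [ch + "C1CCCCC1" for ch in
               ("CC", "CCC", "CCCC", "CCO", "CCN", "CCOC", "CCCO", "CCCN")]
        singles = ["CCC1CCCO1", "CCC1CCC1"]
        ds = _make_dataset(big + singles)
        split = c.scaffold_split(ds)
        assert split.train == list(range(8))
        assert {len(split.valid), len(split.test)} == {1}
        assert {split.valid[0], split.test[0]} == {8, 9}

    def test_chirality_awareness_changes_keys(self):
        assert c.scaffold_key("C[C@H]1CCCO1", True) != ""
        ds = _make_dataset(["C[C@H]1CC(CC)CO1", "C[C@@H]1CC(CC)CO1", "CCC1CCC1", "CCCC1CCCCC1"])
        for aware in (True, False):
            split = c.scaffold_split(ds, chirality_aware=aware)
            c.assert_no_scaffold_leakage(ds, split)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            c.scaffold_split(c.Dataset([], "regression", 1))


class TestMetricClosedForms:
    def test_rmse_and_mae_on_four_points(self):
        y = np.array([[0.0], [1.0], [2.0], [3.0]])
        pred = np.array([[1.0], [1.0], [0.0], [3.0]])
        mask = np.ones((4, 1), dtype=bool)
        # errors 1, 0, -2, 0 -> RMSE = sqrt(5/4), MAE = 3/4
        assert evaluate_metric(y, pred, mask, RMSE) == pytest.approx(np.sqrt(1.25))
        assert evaluate_metric(y, pred, mask, MAE) == pytest.approx(0.75)

    def test_roc_auc_pairwise_rank_form(self):
        y = np.array([[0.0], [0.0], [1.0], [1.0]])
        score = np.array([[0.1], [0.6], [0.5], [0.9]])
        mask = np.ones((4, 1), dtype=bool)
        # concordant pairs: (0.1<0.5),(0.1<0.9),(0.6<0.9) -> 3/4
        assert evaluate_metric(y, score, mask, ROC_AUC) == pytest.approx(0.75)

    def test_perfect_predictions_hit_metric_identities(self):
        y = np.array([[0.3], [1.2], [-0.5]])
        mask = np.ones((3, 1), dtype=bool)
        assert evaluate_metric(y, y.copy(), mask, RMSE) == 0.0
        assert evaluate_metric(y, y.copy(), mask, MAE) == 0.0
        labels = np.array([[0.0], [1.0], [0.0], [1.0]])
        assert evaluate_metric(labels, labels.copy(), np.ones_like(labels, dtype=bool), ROC_AUC) == 1.0

    def test_multitask_metric_is_mean_of_per_task_metrics(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(20, 12))
        pred = y + rng.normal(size=(20, 12))
        mask = np.ones((20, 12), dtype=bool)
        per_task = [
            float(np.mean(np.abs(pred[:, t] - y[:, t]))) for t in range(12)
        ]
        assert evaluate_metric(y, pred, mask, MAE) == pytest.approx(np.mean(per_task))

    def test_masked_entries_ignored(self):
        y = np.array([[0.0], [10.0]])
        pred = np.array([[0.0], [0.0]])
        mask = np.array([[True], [False]])
        assert evaluate_metric(y, pred, mask, RMSE) == 0.0


@pytest.fixture(scope="module")
def finetune_setup():
    ds = c.generate_fixture_dataset(30, seed=6)
    pools = c.build_pool_cache(ds, n_candidates=5, pool_size=3, seed=6)
    enc_cfg = c.EncoderConfig(hidden_dim=8, n_layers=1, n_rbf=6, cutoff=5.0, embed_dim=8, n_elements=20)
    split = c.scaffold_split(ds)
    return ds, pools, enc_cfg, split


class TestFinetune:
    def test_deterministic_given_config_and_seeds(self, finetune_setup):
        ds, pools, enc_cfg, split = finetune_setup
        cfg = c.FinetuneConfig(epochs=3, batch_size=16, seeds=(0,))
        r1 = c.finetune(None, ds, split, cfg, pools=pools, encoder_config=enc_cfg)
        r2 = c.finetune(None, ds, split, cfg, pools=pools, encoder_config=enc_cfg)
        assert r1.per_seed == r2.per_seed
        assert r1.metric == RMSE

    def test_reports_mean_and_std_over_seeds(self, finetune_setup):
        ds, pools, enc_cfg, split = finetune_setup
        cfg = c.FinetuneConfig(epochs=2, batch_size=16, seeds=(0, 1, 2))
        rep = c.finetune(None, ds, split, cfg, pools=pools, encoder_config=enc_cfg)
        assert len(rep.per_seed) == 3
        assert rep.mean == pytest.approx(np.mean(rep.per_seed))
        assert rep.std == pytest.approx(np.std(rep.per_seed))

    def test_classification_reports_roc_auc(self):
        ds = c.generate_fixture_dataset(60, task_type="classification", seed=8)
        pools = c.build_pool_cache(ds, n_candidates=5, pool_size=3, seed=8)
        enc_cfg = c.EncoderConfig(hidden_dim=8, n_layers=1, n_rbf=6, cutoff=5.0, embed_dim=8, n_elements=20)
        split = c.scaffold_split(ds)
        cfg = c.FinetuneConfig(epochs=2, batch_size=16, seeds=(0,))
        rep = c.finetune(None, ds, split, cfg, pools=pools, encoder_config=enc_cfg)
        assert rep.metric == ROC_AUC
        assert 0.0 <= rep.per_seed[0] <= 1.0

    def test_empty_train_split_rejected(self, finetune_setup):
        ds, pools, enc_cfg, _ = finetune_setup
        bad = c.SplitIndices(train=[], valid=[0], test=[1])
        with pytest.raises(ValueError):
            c.finetune(None, ds, bad, c.FinetuneConfig(epochs=1, seeds=(0,)),
                       pools=pools, encoder_config=enc_cfg)


class TestReducedTraining:
    def test_produces_one_paired_row_per_size(self, finetune_setup):
        ds, pools, enc_cfg, split = finetune_setup
        cfg = c.FinetuneConfig(epochs=2, batch_size=8, seeds=(0,))
        enc = c.SchNetEncoder(enc_cfg, seed=0)
        rows = c.reduced_training_experiment(
            ds, [5, 10], cfg, enc, split=split, pools=pools, encoder_config=enc_cfg
        )
        assert [r[0] for r in rows] == [5, 10]
        for _, pre, scr in rows:
            assert isinstance(pre, c.MetricsReport) and isinstance(scr, c.MetricsReport)

    def test_oversized_request_rejected(self, finetune_setup):
        ds, pools, enc_cfg, split = finetune_setup
        cfg = c.FinetuneConfig(epochs=1, seeds=(0,))
        enc = c.SchNetEncoder(enc_cfg, seed=0)
        with pytest.raises(ValueError):
            c.reduced_training_experiment(ds, [10_000], cfg, enc, split=split, pools=pools)
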
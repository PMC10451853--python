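"""F1/confusion correctness and the experiment harness plumbing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from batpipe.classifier import ClfTrainConfig
from batpipe.evaluation import (ConfusionMatrix, F1Report, SegmentDataset,
                                cross_collection_eval, directed_pairs,
                                f1_score, joined_eval, precision_score,
                                recall_score, task_classes)


class TestF1:
    @pytest.mark.parametrize("tp, fp, fn, expected", [
        (2, 1, 0, 0.8),
        (0, 0, 0, 0.0),
        (1, 1, 1, 0.5),
        (10, 0, 0, 1.0),
    ])
    def test_closed_form_cases(self, tp, fp, fn, expected):
        assert f1_score(tp, fp, fn) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            f1_score(-1, 0, 0)

    def test_equals_harmonic_mean_of_precision_recall(self):
        tp, fp, fn = 7, 3, 2
        p = precision_score(tp, fp)
        r = recall_score(tp, fn)
        assert f1_score(tp, fp, fn) == pytest.approx(2 * p * r / (p + r))


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array([0, 1, 2, 1, 0])
        cm = ConfusionMatrix.from_predictions(y, y, ["a", "b", "c"])
        assert np.array_equal(cm.counts, np.diag([2, 2, 1]))

    def test_single_predicted_class_single_column(self):
        y = np.array([0, 1, 2])
        cm = ConfusionMatrix.from_predictions(y, np.zeros(3, int),
                                              ["a", "b", "c"])
        assert cm.counts[:, 1:].sum() == 0
        assert cm.counts[:, 0].sum() == 3

    def test_row_normalization(self):
        cm = ConfusionMatrix.from_predictions(
            [0, 0, 1], [0, 1, 1], ["a", "b"])
        rows = cm.row_normalized()
        np.testing.assert_allclose(rows.sum(axis=1), [1.0, 1.0])

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix.from_predictions([0, 3], [0, 0], ["a", "b"])

    @given(st.integers(0, 2 ** 31 - 1))
    def test_f1_consistent_with_margins(self, seed):
        """f1 from the confusion margins equals a brute-force count."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        true = rng.integers(0, k, 60)
        pred = rng.integers(0, k, 60)
        cm = ConfusionMatrix.from_predictions(true, pred,
                                              [str(i) for i in range(k)])
        for c in range(k):
            tp = int(np.sum((true == c) & (pred == c)))
            fp = int(np.sum((true != c) & (pred == c)))
            fn = int(np.sum((true == c) & (pred != c)))
            assert (cm.tp(c), cm.fp(c), cm.fn(c)) == (tp, fp, fn)
            assert cm.f1(c) == pytest.approx(f1_score(tp, fp, fn))


class TestReports:
    def _report(self):
        run = pd.DataFrame({
            "class": ["P_pip", "P_nat"] * 2,
            "partition": ["val", "val", "test", "test"],
            "precision": [0.9, 0.8, 0.85, 0.75],
            "recall": [0.95, 0.7, 0.9, 0.65],
            "f1": [0.92, 0.75, 0.87, 0.70],
            "support": [100, 20, 100, 20],
        })
        run2 = run.copy()
        run2["f1"] += 0.02
        return F1Report.from_runs([run, run2])

    def test_mean_and_std_over_runs(self):
        report = self._report()
        row = report.lookup("P_pip", "val")
        assert row["f1_mean"] == pytest.approx(0.93)
        assert row["f1_std"] == pytest.approx(0.01)

    def test_json_roundtrip_lossless(self, tmp_path):
        report = self._report()
        path = tmp_path / "report.json"
        report.to_json(path)
        loaded = F1Report.from_json(path)
        pd.testing.assert_frame_equal(loaded.table, report.table)


class TestPairEnumeration:
    def test_two_by_two_design_yields_eight_directed_pairs(self):
        ids = ["east_2019", "west_2019", "east_2020", "west_2020"]
        pairs = directed_pairs(ids)
        assert len(pairs) == 8
        assert all(a != b for a, b in pairs)
        # pairs must share a location or a year, and both directions appear
        for a, b in pairs:
            (la, ya), (lb, yb) = a.rsplit("_", 1), b.rsplit("_", 1)
            assert la[0] == lb[0] or ya == yb
            assert (b, a) in pairs
        # diagonal pairs (different location AND year) are excluded
        assert ("east_2019", "west_2020") not in pairs

    def test_unparseable_id_rejected(self):
        with pytest.raises(ValueError):
            directed_pairs(["east2019", "west2019"])


class TestTaskClasses:
    def test_species_with_and_without_hybrids(self):
        assert task_classes("species") == ["P_pip", "P_nat", "P_pyg"]
        assert task_classes("species", with_hybrids=True) == [
            "P_pip", "P_nat", "P_pyg", "P_low", "P_high"]

    def test_genus_excludes_barbastelle_and_noise(self):
        classes = task_classes("genus")
        assert "B_bar" not in classes and "noise" not in classes
        assert set(classes) == {"Pipistrellus", "Nyctaloid", "Myotis",
                                "Plecotus"}

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            task_classes("family")


def _tiny_dataset(rng, classes, segments_per_class=18, collection="east_2019"):
    """A fabricated dataset with linearly separable MFCC-shaped features."""
    feats, labels, parents, collections = [], [], [], []
    for c, label in enumerate(classes):
        for i in range(segments_per_class):
            base = np.zeros((20, 586), dtype=np.float32)
            base[c * 3:(c + 1) * 3] = 1.0
            feats.append(base + 0.2 * rng.standard_normal((20, 586)))
            labels.append(label)
            parents.append(f"{collection}_{label}_{i // 2}")
            collections.append(collection)
    return SegmentDataset(np.stack(feats), np.asarray(labels),
                          np.asarray(parents), np.asarray(collections))


class TestHarnesses:
    def test_cross_collection_runs_all_directed_pairs(self):
        rng = np.random.default_rng(0)
        datasets = {
            "east_2019": _tiny_dataset(rng, ["P_pip", "P_nat"],
                                       collection="east_2019"),
            "west_2019": _tiny_dataset(rng, ["P_pip", "P_nat"],
                                       collection="west_2019"),
        }
        table = cross_collection_eval(
            datasets, "species",
            ClfTrainConfig(epochs=2, n_runs=1, seed=0), seed=0)
        directions = set(zip(table.per_pair["train"],
                             table.per_pair["test_collection"]))
        assert directions == {("east_2019", "west_2019"),
                              ("west_2019", "east_2019")}
        assert {"train", "val", "test"} == set(table.per_pair["partition"])

    def test_joined_eval_reports_all_partitions(self):
        rng = np.random.default_rng(1)
        dataset = _tiny_dataset(rng, ["P_pip", "P_nat"], segments_per_class=24)
        report = joined_eval(dataset, "species",
                             ClfTrainConfig(epochs=2, n_runs=2, seed=0),
                             seed=0)
        assert set(report.table["partition"]) == {"train", "val", "test"}
        assert set(report.table["class"]) == {"P_pip", "P_nat"}

    def test_single_class_task_rejected(self):
        rng = np.random.default_rng(2)
        dataset = _tiny_dataset(rng, ["P_pip"])
        with pytest.raises(ValueError, match="at least 2"):
            joined_eval(dataset, "species",
                        ClfTrainConfig(epochs=1, n_runs=1))
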
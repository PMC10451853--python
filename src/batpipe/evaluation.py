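"""F1 scoring, confusion matrices and the experiment harnesses.

Three experiment designs are provided on top of the classifier:

* **Directed cross-collection validation** — train and validate on one
  location-year collection, test on the test partition of another; run over
  every ordered pair of collections sharing a year or a location (8 pairs
  in a 2-location x 2-year design). This measures whether a model trained
  at one site/season transfers to another.
* **Joined-data training** — pool all collections, split 60:20:20 with
  per-class stratification preserving the natural imbalance, and compare
  validation vs. test scores; equality within the run-to-run spread is the
  robustness signature.
* **Hybrid-class comparison** — train species models with and without the
  hybrid class holding calls from the band where two Pipistrellus species
  overlap (40-42 kHz), and quantify the induced confusion.

The F1 score of class *c* is ``2 TP / (2 TP + FP + FN)`` computed from the
margins of the confusion matrix, with the 0/0 case scored as 0. Reported
values are means with standard deviations over independently seeded runs
(and over pairs, for the averaged cross-validation tables).
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd

from . import preprocessing
from .classifier import ClfTrainConfig, build_classifier, predict_labels, \
    normalize_mfcc, train_classifier
from .taxonomy import EXCLUDED, GENUS_LABELS, NOISE, is_bat_label, map_to_genus

__all__ = [
    "f1_score",
    "precision_score",
    "recall_score",
    "ConfusionMatrix",
    "F1Report",
    "CrossValTable",
    "SegmentDataset",
    "dataset_from_recordings",
    "task_classes",
    "directed_pairs",
    "cross_collection_eval",
    "joined_eval",
    "hybrid_class_experiment",
    "HybridExperimentResult",
]


# ---------------------------------------------------------------------------
# scores


def _check_counts(*counts):
    for c in counts:
        if c < 0:
            raise ValueError(f"counts must be >= 0, got {c}")


def f1_score(tp: float, fp: float, fn: float) -> float:
    """``2 TP / (2 TP + FP + FN)``; 0 when the denominator is 0."""
    _check_counts(tp, fp, fn)
    denom = 2 * tp + fp + fn
    return 0.0 if denom == 0 else 2 * tp / denom


def precision_score(tp: float, fp: float) -> float:
    _check_counts(tp, fp)
    return 0.0 if tp + fp == 0 else tp / (tp + fp)


def recall_score(tp: float, fn: float) -> float:
    _check_counts(tp, fn)
    return 0.0 if tp + fn == 0 else tp / (tp + fn)


@dataclasses.dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predictions."""

    counts: np.ndarray
    labels: list[str]

    @classmethod
    def from_predictions(cls, true, pred, labels) -> "ConfusionMatrix":
        true = np.asarray(true)
        pred = np.asarray(pred)
        if true.shape != pred.shape:
            raise ValueError("true and predicted label arrays differ in length")
        k = len(labels)
        if true.size and ((true.min() < 0) or (true.max() >= k)
                          or (pred.min() < 0) or (pred.max() >= k)):
            raise ValueError(f"labels must lie in [0, {k})")
        counts = np.zeros((k, k), dtype=np.int64)
        np.add.at(counts, (true, pred), 1)
        return cls(counts=counts, labels=list(labels))

    def tp(self, i: int) -> int:
        return int(self.counts[i, i])

    def fp(self, i: int) -> int:
        return int(self.counts[:, i].sum() - self.counts[i, i])

    def fn(self, i: int) -> int:
        return int(self.counts[i, :].sum() - self.counts[i, i])

    def support(self, i: int) -> int:
        return int(self.counts[i, :].sum())

    def f1(self, i: int) -> float:
        return f1_score(self.tp(i), self.fp(i), self.fn(i))

    def row_normalized(self) -> np.ndarray:
        """Rows scaled to sum to 1 (rows with no support stay zero)."""
        counts = self.counts.astype(np.float64)
        sums = counts.sum(axis=1, keepdims=True)
        return np.divide(counts, sums, out=np.zeros_like(counts),
                         where=sums > 0)

    def save_plot(self, path) -> None:
        """Absolute counts (log color scale) next to row-normalized shares."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import LogNorm
        fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
        shown = np.maximum(self.counts, 1e-1)
        for ax, data, norm, title in (
                (axes[0], shown, LogNorm(), "absolute counts"),
                (axes[1], self.row_normalized(), None, "row-normalized")):
            im = ax.imshow(data, cmap="viridis", norm=norm)
            ax.set_xticks(range(len(self.labels)), self.labels, rotation=45)
            ax.set_yticks(range(len(self.labels)), self.labels)
            ax.set_xlabel("predicted")
            ax.set_ylabel("true")
            ax.set_title(title)
            fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


# ---------------------------------------------------------------------------
# reports


@dataclasses.dataclass
class F1Report:
    """Per class and partition: precision/recall/F1 as mean +/- std."""

    table: pd.DataFrame  # class, partition, *_mean, *_std, support

    COLUMNS = ["class", "partition", "precision_mean", "precision_std",
               "recall_mean", "recall_std", "f1_mean", "f1_std", "support"]

    @classmethod
    def from_runs(cls, per_run: list[pd.DataFrame]) -> "F1Report":
        """Aggregate per-run rows (class, partition, precision, recall, f1,
        support) into mean +/- std over the runs."""
        stacked = pd.concat(per_run, ignore_index=True)
        rows = []
        for (label, part), grp in stacked.groupby(["class", "partition"],
                                                  sort=True):
            rows.append({
                "class": label, "partition": part,
                "precision_mean": grp["precision"].mean(),
                "precision_std": grp["precision"].std(ddof=0),
                "recall_mean": grp["recall"].mean(),
                "recall_std": grp["recall"].std(ddof=0),
                "f1_mean": grp["f1"].mean(),
                "f1_std": grp["f1"].std(ddof=0),
                "support": grp["support"].mean(),
            })
        return cls(table=pd.DataFrame(rows, columns=cls.COLUMNS))

    def lookup(self, label: str, partition: str) -> pd.Series:
        t = self.table
        hit = t[(t["class"] == label) & (t["partition"] == partition)]
        if hit.empty:
            raise KeyError(f"no entry for class {label!r}, "
                           f"partition {partition!r}")
        return hit.iloc[0]

    def to_json(self, path=None):
        payload = self.table.to_dict(orient="records")
        if path is None:
            return json.dumps(payload)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path_or_str) -> "F1Report":
        try:
            payload = json.loads(path_or_str)
        except (ValueError, TypeError):
            with open(path_or_str) as fh:
                payload = json.load(fh)
        return cls(table=pd.DataFrame(payload, columns=cls.COLUMNS))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# datasets


@dataclasses.dataclass
class SegmentDataset:
    """Normalized MFCC features for every 1 s segment of a corpus."""

    X: np.ndarray             # (n, 20, 586), normalized per matrix
    label_strs: np.ndarray    # (n,) recording class label
    parent: np.ndarray        # (n,) parent recording id
    collection: np.ndarray    # (n,) collection id

    def __len__(self):
        return len(self.X)

    def subset(self, mask) -> "SegmentDataset":
        return SegmentDataset(self.X[mask], self.label_strs[mask],
                              self.parent[mask], self.collection[mask])


def dataset_from_recordings(recordings, parent_ids=None) -> SegmentDataset:
    """Segment recordings and compute normalized MFCC features."""
    feats, labels, parents, collections = [], [], [], []
    for i, rec in enumerate(recordings):
        pid = parent_ids[i] if parent_ids is not None else f"rec{i:05d}"
        for seg in preprocessing.recycle_segments(rec, parent_id=pid):
            feats.append(normalize_mfcc(preprocessing.compute_mfcc(seg.samples)))
            labels.append(rec.class_label)
            parents.append(pid)
            collections.append(rec.collection)
    if not feats:
        raise ValueError("no segments could be produced from the recordings")
    return SegmentDataset(
        X=np.stack(feats),
        label_strs=np.asarray(labels),
        parent=np.asarray(parents),
        collection=np.asarray(collections),
    )


def task_classes(task: str, present: set[str] | None = None,
                 with_hybrids: bool = False) -> list[str]:
    """Class list of a task, optionally restricted to present labels."""
    if task == "batnoise":
        return ["bat", NOISE]
    if task == "genus":
        classes = list(GENUS_LABELS)
    elif task == "species":
        classes = ["P_pip", "P_nat", "P_pyg"]
        if with_hybrids:
            classes += ["P_low", "P_high"]
    else:
        raise ValueError(f"unknown task {task!r}")
    if present is not None:
        classes = [c for c in classes if c in present]
    return classes


def _task_targets(dataset: SegmentDataset, task: str, classes: list[str]):
    """Integer targets for the task; -1 marks segments outside the task."""
    index = {c: i for i, c in enumerate(classes)}
    y = np.full(len(dataset), -1, dtype=int)
    for i, label in enumerate(dataset.label_strs):
        if task == "batnoise":
            key = NOISE if label == NOISE else "bat"
        elif task == "genus":
            key = map_to_genus(label) if label != NOISE else EXCLUDED
        else:
            key = label
        y[i] = index.get(key, -1)
    return y


def _balance(idx: np.ndarray, y: np.ndarray, rng) -> np.ndarray:
    """Subsample majority classes to the minority count (bat/noise task)."""
    counts = {c: (y[idx] == c).sum() for c in np.unique(y[idx])}
    floor = min(counts.values())
    keep = []
    for c in sorted(counts):
        members = idx[y[idx] == c]
        keep.append(rng.choice(members, size=floor, replace=False))
    return np.sort(np.concatenate(keep))


def _parent_split(dataset: SegmentDataset, mask: np.ndarray, seed: int,
                  ratios=(0.6, 0.2, 0.2)) -> np.ndarray:
    """Recording-level stratified split mapped back onto segments."""
    sub = pd.DataFrame({
        "parent": dataset.parent[mask],
        "class": dataset.label_strs[mask],
    })
    parents = sub.drop_duplicates("parent")
    catalog = pd.DataFrame({
        "file": parents["parent"].to_numpy(),
        "class": parents["class"].to_numpy(),
        "collection": "", "height_m": 10, "duration_s": 1.0,
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rare-class warnings at small scale
        split = preprocessing.stratified_split(catalog, ratios=ratios,
                                               seed=seed)
    assignment = dict(zip(split["file"], split["split"]))
    out = np.array(["none"] * len(dataset), dtype=object)
    out[mask] = [assignment[p] for p in dataset.parent[mask]]
    return out


def _eval_partition(model, X, y, classes) -> pd.DataFrame:
    pred = predict_labels(model, X)
    cm = ConfusionMatrix.from_predictions(y, pred, classes)
    rows = []
    for i, label in enumerate(classes):
        if cm.support(i) == 0:
            continue  # absent classes are reported as absent, not as F1=0
        rows.append({
            "class": label,
            "precision": precision_score(cm.tp(i), cm.fp(i)),
            "recall": recall_score(cm.tp(i), cm.fn(i)),
            "f1": cm.f1(i),
            "support": cm.support(i),
        })
    return pd.DataFrame(rows), cm


def _train_and_eval(dataset: SegmentDataset, y, split_fn, classes, config,
                    task, test_override=None):
    """Train ``config.n_runs`` models; evaluate train/val/test partitions.

    ``split_fn(run_seed)`` supplies the partition assignment for each run;
    re-splitting per run makes the reported run-to-run spread include the
    split sampling variance, which matters at reduced corpus sizes. A
    harness can still pin one split by ignoring the seed.
    ``test_override`` replaces the test partition with (X, y) from another
    dataset (directed cross-collection evaluation).
    """
    in_task = y >= 0
    per_run = []
    confusions = []
    for run in range(config.n_runs):
        run_seed = (config.seed + 7919 * run) % (2 ** 31)
        rng = np.random.default_rng(run_seed)
        split = split_fn(run_seed)
        parts = {
            "train": in_task & (split == "train"),
            "val": in_task & (split == "val"),
        }
        train_idx = np.flatnonzero(parts["train"])
        if task == "batnoise":
            train_idx = _balance(train_idx, y, rng)
        model = build_classifier(len(classes), seed=run_seed)
        train_classifier(
            model, dataset.X[train_idx], y[train_idx],
            dataclasses.replace(config, seed=run_seed))
        frames = []
        run_cms = {}
        for part in ("train", "val"):
            idx = train_idx if part == "train" else np.flatnonzero(parts[part])
            frame, cm = _eval_partition(model, dataset.X[idx], y[idx], classes)
            frame["partition"] = part
            frames.append(frame)
            run_cms[part] = cm
        if test_override is not None:
            x_test, y_test = test_override
        else:
            test_mask = in_task & (split == "test")
            x_test, y_test = dataset.X[test_mask], y[test_mask]
        frame, cm = _eval_partition(model, x_test, y_test, classes)
        frame["partition"] = "test"
        frames.append(frame)
        run_cms["test"] = cm
        per_run.append(pd.concat(frames, ignore_index=True))
        confusions.append(run_cms)
    return per_run, confusions


# ---------------------------------------------------------------------------
# experiment harnesses


def directed_pairs(collection_ids) -> list[tuple[str, str]]:
    """Ordered pairs of collections sharing a location or a year.

    Collection ids follow the ``location_year`` convention (e.g.
    ``east_2019``). For 2 locations x 2 years this yields 8 directed pairs.
    """
    def parts(cid):
        if "_" not in cid:
            raise ValueError(f"collection id {cid!r} is not 'location_year'")
        loc, year = cid.rsplit("_", 1)
        return loc, year

    ids = list(collection_ids)
    pairs = []
    for a in ids:
        for b in ids:
            if a == b:
                continue
            (la, ya), (lb, yb) = parts(a), parts(b)
            if la == lb or ya == yb:
                pairs.append((a, b))
    return pairs


@dataclasses.dataclass
class CrossValTable:
    """Per-pair and averaged F1 results of directed cross-validation."""

    per_pair: pd.DataFrame  # train, test, class, partition, run, f1, support
    averaged: F1Report      # pooled over pairs and runs jointly

    def pair_table(self) -> pd.DataFrame:
        """Table-4 style: one row per direction, test-partition F1 per class."""
        test = self.per_pair[self.per_pair["partition"] == "test"]
        rows = []
        for (a, b), grp in test.groupby(["train", "test_collection"]):
            row = {"direction": f"{a} -> {b}"}
            for label, sub in grp.groupby("class"):
                row[f"f1_{label}"] = sub["f1"].mean()
                row[f"f1_{label}_std"] = sub["f1"].std(ddof=0)
            rows.append(row)
        return pd.DataFrame(rows)


def cross_collection_eval(datasets: dict[str, SegmentDataset], task: str,
                          config: ClfTrainConfig | None = None,
                          with_hybrids: bool = False,
                          seed: int = 0) -> CrossValTable:
    """Directed cross-collection validation over all admissible pairs.

    For each ordered pair (A, B) sharing a year or location: A is split
    60:20:20, the model trains on A-train and validates on A-val, and is
    tested on the *test partition* of B (so results are comparable with
    B's own within-collection evaluation). Classes missing from either
    side of a pair are skipped for that pair with a warning.
    """
    config = config or ClfTrainConfig()
    if len(datasets) < 2:
        raise ValueError("need at least 2 collections")
    pairs = directed_pairs(sorted(datasets))
    all_rows = []
    per_run_frames = []
    for pair_i, (a, b) in enumerate(pairs):
        ds_a, ds_b = datasets[a], datasets[b]
        present = set(ds_a.label_strs) & set(ds_b.label_strs) \
            if task == "species" else None
        classes = task_classes(task, with_hybrids=with_hybrids)
        if task != "batnoise":
            y_probe_a = _task_targets(ds_a, task, classes)
            y_probe_b = _task_targets(ds_b, task, classes)
            have_a = {classes[i] for i in np.unique(y_probe_a[y_probe_a >= 0])}
            have_b = {classes[i] for i in np.unique(y_probe_b[y_probe_b >= 0])}
            dropped = [c for c in classes if c not in (have_a & have_b)]
            if dropped:
                warnings.warn(f"pair {a}->{b}: classes {dropped} missing "
                              "from one side; skipped for this pair")
            classes = [c for c in classes if c in have_a and c in have_b]
            if len(classes) < 2:
                warnings.warn(f"pair {a}->{b}: fewer than 2 shared classes; "
                              "pair skipped")
                continue
        y_a = _task_targets(ds_a, task, classes)
        y_b = _task_targets(ds_b, task, classes)
        pair_seed = (seed + 104729 * pair_i) % (2 ** 31)
        split_a = _parent_split(ds_a, y_a >= 0, seed=pair_seed)
        split_b = _parent_split(ds_b, y_b >= 0, seed=pair_seed + 1)
        test_mask = (y_b >= 0) & (split_b == "test")
        per_run, _ = _train_and_eval(
            ds_a, y_a, lambda _s: split_a, classes,
            dataclasses.replace(config, seed=pair_seed), task,
            test_override=(ds_b.X[test_mask], y_b[test_mask]))
        for run_i, frame in enumerate(per_run):
            tagged = frame.copy()
            tagged["train"] = a
            tagged["test_collection"] = b
            tagged["run"] = run_i
            all_rows.append(tagged)
            per_run_frames.append(frame)
    if not all_rows:
        raise ValueError("no evaluable collection pairs")
    return CrossValTable(
        per_pair=pd.concat(all_rows, ignore_index=True),
        averaged=F1Report.from_runs(per_run_frames),
    )


def joined_eval(datasets, task: str, config: ClfTrainConfig | None = None,
                with_hybrids: bool = False, seed: int = 0) -> F1Report:
    """Join collections, split 60:20:20 preserving imbalance, train, report."""
    config = config or ClfTrainConfig()
    if isinstance(datasets, dict):
        datasets = list(datasets.values())
    if isinstance(datasets, SegmentDataset):
        datasets = [datasets]
    joined = SegmentDataset(
        X=np.concatenate([d.X for d in datasets]),
        label_strs=np.concatenate([d.label_strs for d in datasets]),
        parent=np.concatenate([d.parent for d in datasets]),
        collection=np.concatenate([d.collection for d in datasets]),
    )
    classes = task_classes(task, set(joined.label_strs),
                           with_hybrids=with_hybrids)
    if len(classes) < 2:
        raise ValueError(f"task {task!r} needs at least 2 classes present")
    y = _task_targets(joined, task, classes)
    per_run, _ = _train_and_eval(
        joined, y, lambda s: _parent_split(joined, y >= 0, seed=s),
        classes, dataclasses.replace(config, seed=seed), task)
    return F1Report.from_runs(per_run)


@dataclasses.dataclass
class HybridExperimentResult:
    report_without: F1Report
    report_with: F1Report
    confusion_without: ConfusionMatrix  # test partition, summed over runs
    confusion_with: ConfusionMatrix

    def hybrid_confusion_mass(self, species: str,
                              hybrid: str = "P_low") -> tuple[int, int]:
        """(species -> hybrid, hybrid -> species) test confusion counts."""
        cm = self.confusion_with
        i, j = cm.labels.index(species), cm.labels.index(hybrid)
        return int(cm.counts[i, j]), int(cm.counts[j, i])


def hybrid_class_experiment(dataset: SegmentDataset,
                            config: ClfTrainConfig | None = None,
                            seed: int = 0) -> HybridExperimentResult:
    """Species classification with and without the hybrid class P_low.

    Both variants share the same recording-level split. The with-hybrid
    variant requires P_pip, P_nat and P_low segments.
    """
    config = config or ClfTrainConfig()
    present = set(dataset.label_strs)
    for needed in ("P_pip", "P_nat", "P_low"):
        if needed not in present:
            raise ValueError(f"hybrid experiment requires class {needed!r}")
    results = {}
    confusions = {}
    for with_hybrids in (False, True):
        classes = task_classes("species", present, with_hybrids=with_hybrids)
        y = _task_targets(dataset, "species", classes)
        per_run, cms = _train_and_eval(
            dataset, y,
            lambda s, y=y: _parent_split(dataset, y >= 0, seed=s),
            classes, dataclasses.replace(config, seed=seed), "species")
        results[with_hybrids] = F1Report.from_runs(per_run)
        total = np.sum([c["test"].counts for c in cms], axis=0)
        confusions[with_hybrids] = ConfusionMatrix(
            counts=total, labels=classes)
    return HybridExperimentResult(
        report_without=results[False],
        report_with=results[True],
        confusion_without=confusions[False],
        confusion_with=confusions[True],
    )
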
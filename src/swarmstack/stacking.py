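"""Stacked generalization over the three base classifiers.

The meta-dataset's rows are the base-stage test instances; its three
predictor columns are the CSO-, KH- and BFO-selected classifiers'
predictions (in that fixed order) plus the true label.  It is split 80/20
stratified by the true label, and a 3-input / 6-hidden sigmoid network
trained by conjugate gradient acts as the super learner.

``run_pipeline`` orchestrates the whole chain: load -> impute -> SMOTE ->
normalize -> 60/40 split -> three selector runs -> three base networks ->
meta-dataset -> 80/20 split -> super learner -> metrics.  Every stage is
seeded from the master seed through named substreams.

Note: as constructed, the super learner trains on predictions for base
test instances, so base-classifier metrics (computed on the full test
set) and super-learner metrics (computed on the held-out 20% of meta
rows) are not measured on identical instances.  Set
``evaluate_bases_on_meta_test`` for a like-for-like comparison.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import dataio
from .bfo import BFOConfig, select_features_bfo
from .bpnn import BPNNConfig, init_network, predict, train_cga
from .cso import CSOConfig, select_features_cso
from .dataio import ClinicalDataset, SplitSpec, apply_normalization
from .fitness import FeatureMask, FitnessEvaluator, FitnessValue
from .kh import KHConfig, select_features_kh
from .metrics import compute_metrics, confusion

__all__ = ["MetaDataset", "PipelineConfig", "build_meta_dataset", "split_meta",
           "train_super_learner", "run_pipeline", "derive_seed"]

BASE_ORDER = ("cso", "kh", "bfo")


def derive_seed(master: int, label: str) -> int:
    """Deterministic named substream seed, always below 2**31."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class MetaDataset:
    """Base predictions (CSO, KH, BFO columns, fixed order) + true label."""

    predictions: np.ndarray   # (n, 3)
    labels: np.ndarray        # (n,)

    def __post_init__(self) -> None:
        self.predictions = np.asarray(self.predictions, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.predictions.ndim != 2 or self.predictions.shape[1] != 3:
            raise ValueError("meta dataset must have exactly 3 predictor columns")
        if self.predictions.shape[0] != self.labels.shape[0]:
            raise ValueError("predictions and labels differ in length")

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    def as_dataset(self) -> ClinicalDataset:
        return ClinicalDataset(
            feature_names=[f"pred_{a}" for a in BASE_ORDER],
            X=self.predictions,
            y=self.labels,
            missing_mask=np.zeros(self.predictions.shape, dtype=bool),
            provenance={"meta": True},
        )


@dataclass(frozen=True)
class FitnessConfig:
    folds: int = 5
    kernel: str = "rbf"
    C: float = 1.0


@dataclass(frozen=True)
class PipelineConfig:
    label_column: str = "label"
    missing_tokens: frozenset = dataio.DEFAULT_MISSING_TOKENS
    smote_k: int = 5
    smote_multiplier: int | None = None     # None -> auto from class ratio
    train_fraction: float = 0.6
    meta_fraction: float = 0.8
    fitness: FitnessConfig = FitnessConfig()
    cso: CSOConfig = CSOConfig()
    kh: KHConfig = KHConfig()
    bfo: BFOConfig = BFOConfig()
    bpnn_max_iterations: int = 100
    bpnn_tolerance: float = 1e-7
    meta_probabilities: bool = False
    evaluate_bases_on_meta_test: bool = False
    master_seed: int = 0


def build_meta_dataset(preds_cso, preds_kh, preds_bfo, labels) -> MetaDataset:
    """Column-stack the three base prediction vectors with the labels."""
    cols = [np.asarray(v).ravel() for v in (preds_cso, preds_kh, preds_bfo)]
    labels = np.asarray(labels).ravel()
    if any(c.shape != labels.shape for c in cols):
        raise ValueError("all prediction vectors must match the label length")
    return MetaDataset(predictions=np.column_stack(cols) if labels.size
                       else np.empty((0, 3)), labels=labels)


def split_meta(meta: MetaDataset, fraction: float, seed: int) -> tuple[MetaDataset, MetaDataset]:
    """Stratified 80/20-style split of meta rows, half-up train size."""
    ds = meta.as_dataset()
    tr, te = dataio.stratified_split(ds, SplitSpec(train_fraction=fraction, seed=seed))
    return (MetaDataset(tr.X, tr.y), MetaDataset(te.X, te.y))


def train_super_learner(meta_train: MetaDataset, cfg: BPNNConfig | None = None,
                        seed: int = 0):
    """Fit the 3-input / 6-hidden super-learner network on meta features."""
    if meta_train.n == 0:
        raise ValueError("empty meta training set")
    cfg = cfg or BPNNConfig(n_input=3, n_hidden=6, seed=seed)
    net = init_network(cfg)
    return train_cga(net, meta_train.as_dataset(), cfg)


def _mask_record(algorithm: str, mask: FeatureMask, names: list[str],
                 fit: FitnessValue) -> dict:
    return {
        "algorithm": algorithm,
        "bits": list(mask.bits),
        "feature_names": [names[i] for i in mask.indices()],
        "fitness": fit.accuracy,
        "cardinality": mask.cardinality,
    }


def run_pipeline(dataset, cfg: PipelineConfig) -> dict:
    """End-to-end run; ``dataset`` is a CSV path or a ClinicalDataset.

    Returns a JSON-serializable report with the selected masks, confusion
    counts and metric tables for the three base classifiers and the super
    learner.  Identical (dataset, config) pairs produce identical reports.
    """
    seed = cfg.master_seed
    if isinstance(dataset, (str,)) or hasattr(dataset, "__fspath__"):
        ds = dataio.load_csv(dataset, cfg.label_column, cfg.missing_tokens)
    else:
        ds = dataset

    ds = dataio.impute_mean(ds)
    ds = dataio.smote(ds, k_neighbors=cfg.smote_k, multiplier=cfg.smote_multiplier,
                      seed=derive_seed(seed, "smote"))
    ds, norm = dataio.minmax_normalize(ds)
    train, test = dataio.stratified_split(
        ds, SplitSpec(cfg.train_fraction, True, derive_seed(seed, "split")))

    evaluator = FitnessEvaluator(train, folds=cfg.fitness.folds,
                                 kernel=cfg.fitness.kernel, C=cfg.fitness.C,
                                 seed=derive_seed(seed, "fitness"))

    selections = {}
    selections["cso"] = select_features_cso(
        train, replace(cfg.cso, seed=derive_seed(seed, "cso")), evaluator)
    selections["kh"] = select_features_kh(
        train, replace(cfg.kh, seed=derive_seed(seed, "kh")), evaluator)
    selections["bfo"] = select_features_bfo(
        train, replace(cfg.bfo, seed=derive_seed(seed, "bfo")), evaluator)

    base_preds = {}
    report: dict = {"masks": {}, "base": {}, "super_learner": {},
                    "bookkeeping": {
                        "n_after_smote": ds.n_instances,
                        "n_train": train.n_instances,
                        "n_test": test.n_instances,
                    }}
    from .bpnn import forward  # local to keep module surface tidy

    for algo in BASE_ORDER:
        mask, fit, trace = selections[algo]
        report["masks"][algo] = _mask_record(algo, mask, ds.feature_names, fit)
        idx = mask.indices()
        sub_train = replace(train, X=train.X[:, idx],
                            missing_mask=train.missing_mask[:, idx],
                            feature_names=[train.feature_names[i] for i in idx])
        net_cfg = BPNNConfig(n_input=len(idx),
                             tolerance=cfg.bpnn_tolerance,
                             max_iterations=cfg.bpnn_max_iterations,
                             seed=derive_seed(seed, f"bpnn_{algo}"))
        net = train_cga(init_network(net_cfg), sub_train, net_cfg)
        X_test = test.X[:, idx]
        if cfg.meta_probabilities:
            base_preds[algo] = np.asarray(forward(net, X_test), dtype=float)
        else:
            base_preds[algo] = np.asarray(predict(net, X_test), dtype=float)
        hard = (base_preds[algo] >= 0.5).astype(int)
        cc = confusion(hard, test.y)
        report["base"][algo] = {
            "confusion": {"TP": cc.TP, "TN": cc.TN, "FP": cc.FP, "FN": cc.FN},
            "metrics": compute_metrics(cc).to_dict(),
            "selected_features": int(len(idx)),
            "trace_final": fit.accuracy,
        }

    meta = build_meta_dataset(base_preds["cso"], base_preds["kh"],
                              base_preds["bfo"], test.y)
    meta_train, meta_test = split_meta(meta, cfg.meta_fraction,
                                       derive_seed(seed, "meta_split"))
    super_cfg = BPNNConfig(n_input=3, n_hidden=6,
                           tolerance=cfg.bpnn_tolerance,
                           max_iterations=cfg.bpnn_max_iterations,
                           seed=derive_seed(seed, "super"))
    super_net = train_super_learner(meta_train, super_cfg)
    super_preds = np.atleast_1d(predict(super_net, meta_test.predictions))
    cc = confusion(super_preds, meta_test.labels)
    report["super_learner"] = {
        "confusion": {"TP": cc.TP, "TN": cc.TN, "FP": cc.FP, "FN": cc.FN},
        "metrics": compute_metrics(cc).to_dict(),
        "n_meta_train": meta_train.n,
        "n_meta_test": meta_test.n,
    }
    report["bookkeeping"]["fitness_evaluations"] = evaluator.evaluation_count
    report["normalization"] = norm.to_dict()

    if cfg.evaluate_bases_on_meta_test:
        # like-for-like comparison on the same held-out meta rows
        for j, algo in enumerate(BASE_ORDER):
            hard = (meta_test.predictions[:, j] >= 0.5).astype(int)
            cc = confusion(hard, meta_test.labels)
            report["base"][algo]["metrics_on_meta_test"] = compute_metrics(cc).to_dict()
    return report


def report_to_json(report: dict) -> str:
    """Canonical serialization used for determinism checks."""
    return json.dumps(report, sort_keys=True)
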
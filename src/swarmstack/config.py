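"""YAML configuration covering every pipeline stage.

The file is a flat mapping of optional blocks::

    label_column: label
    smote: {k_neighbors: 5, multiplier: null}
    split: {train_fraction: 0.6, meta_fraction: 0.8}
    fitness: {folds: 5, kernel: rbf, C: 1.0}
    cso: {N: 20, iterations: 50, ...}
    kh: {V_f: 0.02, RD_max: 0.005, ...}
    bfo: {S: 20, N_c: 10, ...}
    bpnn: {max_iterations: 100, tolerance: 1.0e-7}
    master_seed: 0

Unknown keys raise immediately; selector blocks are validated by their
config dataclasses (e.g. a krill ``RD_max`` outside [0.002, 0.01] is
rejected).
"""

from __future__ import annotations

import yaml

from .bfo import BFOConfig
from .cso import CSOConfig
from .kh import KHConfig
from .stacking import FitnessConfig, PipelineConfig

__all__ = ["load_config", "config_from_dict"]


def _build(cls, block: dict, name: str):
    try:
        return cls(**(block or {}))
    except TypeError as exc:
        raise ValueError(f"invalid key in {name!r} block: {exc}") from exc


def config_from_dict(doc: dict) -> PipelineConfig:
    doc = dict(doc or {})
    known = {"label_column", "missing_tokens", "smote", "split", "fitness",
             "cso", "kh", "bfo", "bpnn", "meta_probabilities",
             "evaluate_bases_on_meta_test", "master_seed"}
    extra = set(doc) - known
    if extra:
        raise ValueError(f"unknown configuration keys: {sorted(extra)}")
    smote = doc.get("smote") or {}
    split = doc.get("split") or {}
    bpnn = doc.get("bpnn") or {}
    return PipelineConfig(
        label_column=doc.get("label_column", "label"),
        missing_tokens=frozenset(doc.get("missing_tokens", {"?", ""})),
        smote_k=int(smote.get("k_neighbors", 5)),
        smote_multiplier=smote.get("multiplier"),
        train_fraction=float(split.get("train_fraction", 0.6)),
        meta_fraction=float(split.get("meta_fraction", 0.8)),
        fitness=_build(FitnessConfig, doc.get("fitness"), "fitness"),
        cso=_build(CSOConfig, doc.get("cso"), "cso"),
        kh=_build(KHConfig, doc.get("kh"), "kh"),
        bfo=_build(BFOConfig, doc.get("bfo"), "bfo"),
        bpnn_max_iterations=int(bpnn.get("max_iterations", 100)),
        bpnn_tolerance=float(bpnn.get("tolerance", 1e-7)),
        meta_probabilities=bool(doc.get("meta_probabilities", False)),
        evaluate_bases_on_meta_test=bool(doc.get("evaluate_bases_on_meta_test", False)),
        master_seed=int(doc.get("master_seed", 0)),
    )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return config_from_dict(doc)
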
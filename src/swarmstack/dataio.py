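"""Loading and preprocessing of clinical tabular datasets.

The preprocessing chain applied before feature selection is fixed:
mean imputation -> SMOTE minority oversampling -> min-max normalization
to [0, 1] -> stratified train/test split.  Each step is a pure function
from :class:`ClinicalDataset` to :class:`ClinicalDataset`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ClinicalDataset",
    "NormalizationParams",
    "SplitSpec",
    "load_csv",
    "impute_mean",
    "smote",
    "auto_multiplier",
    "minmax_normalize",
    "apply_normalization",
    "stratified_split",
    "round_half_up",
]

DEFAULT_MISSING_TOKENS = frozenset({"?", ""})


@dataclass
class ClinicalDataset:
    """A two-class tabular dataset with explicit missingness.

    ``X`` is an ``n x m`` float matrix, ``y`` holds binary labels where 1 is
    the positive (minority-at-load) class, and ``missing_mask`` marks cells
    that were missing in the source and have not yet been imputed.
    """

    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray
    missing_mask: np.ndarray
    class_names: tuple[str, str] = ("0", "1")
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.X.shape != self.missing_mask.shape:
            raise ValueError("X and missing_mask must agree in shape")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y must agree in row count")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names must match number of columns")
        labels = np.unique(self.y)
        if not np.isin(labels, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")

    @property
    def n_instances(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(count of class 0, count of class 1)."""
        return int((self.y == 0).sum()), int((self.y == 1).sum())

    def to_csv(self, path, label_column: str = "label") -> None:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df = df.mask(self.missing_mask)
        df[label_column] = [self.class_names[v] for v in self.y]
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature min/max fitted on one dataset, applied to another.

    The target range is fixed at [0, 1]; a constant feature (min == max)
    maps to 0 everywhere.
    """

    min_a: np.ndarray
    max_a: np.ndarray
    new_min: float = 0.0
    new_max: float = 1.0

    def __post_init__(self) -> None:
        if np.any(self.min_a > self.max_a):
            raise ValueError("per-feature min must not exceed max")

    def to_dict(self) -> dict:
        return {
            "min": [float(v) for v in self.min_a],
            "max": [float(v) for v in self.max_a],
            "new_min": self.new_min,
            "new_max": self.new_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(
            min_a=np.asarray(d["min"], dtype=float),
            max_a=np.asarray(d["max"], dtype=float),
            new_min=float(d.get("new_min", 0.0)),
            new_max=float(d.get("new_max", 1.0)),
        )


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.6
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction <= 1.0):
            raise ValueError("train_fraction must lie in (0, 1]")


def round_half_up(x: float | Decimal) -> int:
    """Round to the nearest integer with halves rounding up (249.6 -> 250)."""
    return int(Decimal(str(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def train_size(n: int, fraction: float) -> int:
    """Training-set size for an n-row dataset under half-up rounding."""
    return round_half_up(Decimal(str(fraction)) * n)


def load_csv(path, label_column: str, missing_tokens=DEFAULT_MISSING_TOKENS) -> ClinicalDataset:
    """Read a headered CSV into a :class:`ClinicalDataset`.

    All non-label columns must parse as floats or be one of
    ``missing_tokens``.  Labels are encoded so the minority class is the
    positive class (1); on an exact tie the lexicographically larger label
    string is positive.
    """
    tokens = {str(t) for t in missing_tokens}
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found")
    labels_raw = df[label_column].astype(str).str.strip()
    feat_df = df.drop(columns=[label_column])
    feature_names = list(feat_df.columns)

    uniq = sorted(labels_raw.unique())
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 label values, found {len(uniq)}: {uniq}")
    counts = labels_raw.value_counts()
    # minority class becomes the positive class; tie -> larger label string
    if counts[uniq[0]] == counts[uniq[1]]:
        positive = uniq[1]
    else:
        positive = counts.idxmin()
    negative = uniq[0] if positive == uniq[1] else uniq[1]
    y = (labels_raw == positive).to_numpy().astype(int)

    n, m = feat_df.shape
    X = np.zeros((n, m))
    mask = np.zeros((n, m), dtype=bool)
    for j, col in enumerate(feature_names):
        vals = feat_df[col].astype(str).str.strip()
        miss = vals.isin(tokens)
        mask[:, j] = miss.to_numpy()
        try:
            X[~mask[:, j], j] = vals[~miss].astype(float).to_numpy()
        except ValueError as exc:
            raise ValueError(f"non-numeric value in column {col!r}: {exc}") from exc
    return ClinicalDataset(
        feature_names=feature_names,
        X=X,
        y=y,
        missing_mask=mask,
        class_names=(str(negative), str(positive)),
        provenance={"source": str(path), "label_column": label_column},
    )


def impute_mean(ds: ClinicalDataset) -> ClinicalDataset:
    """Replace each missing cell by its feature's mean over observed rows.

    The mean is global (not class-conditional).  A feature with no observed
    value at all is an error.
    """
    if not ds.missing_mask.any():
        return replace(ds, missing_mask=np.zeros_like(ds.missing_mask))
    X = ds.X.copy()
    for j in range(ds.n_features):
        miss = ds.missing_mask[:, j]
        if miss.all():
            raise ValueError(f"feature {ds.feature_names[j]!r} has no observed values")
        if miss.any():
            X[miss, j] = X[~miss, j].mean()
    return replace(ds, X=X, missing_mask=np.zeros_like(ds.missing_mask))


def auto_multiplier(n_majority: int, n_minority: int) -> int:
    """Oversampling multiplier from the class ratio.

    Below ratio 1.5 the dataset is left as is; otherwise the ratio is
    rounded half-up so the rebalanced minority roughly matches the majority.
    """
    if n_minority < 1 or n_majority < n_minority:
        raise ValueError("require n_majority >= n_minority >= 1")
    ratio = n_majority / n_minority
    if ratio < 1.5:
        return 1
    return round_half_up(Decimal(n_majority) / Decimal(n_minority))


def smote(ds: ClinicalDataset, k_neighbors: int = 5, multiplier: int | None = None,
          seed: int = 0) -> ClinicalDataset:
    """Synthetic minority oversampling by k-NN interpolation.

    Each minority instance p contributes ``multiplier - 1`` synthetic rows
    ``p + u * (q - p)`` with q drawn uniformly from p's ``k_neighbors``
    nearest minority neighbours (Euclidean) and u ~ Uniform(0, 1).  The
    output has exactly ``n_majority + multiplier * n_minority`` rows, with
    synthetic rows appended after the originals.  ``multiplier=None``
    selects :func:`auto_multiplier` from the class counts.
    """
    if ds.missing_mask.any():
        raise ValueError("impute before SMOTE")
    n0, n1 = ds.class_counts()
    minority_label = 1 if n1 <= n0 else 0
    n_min = min(n0, n1)
    n_maj = max(n0, n1)
    if multiplier is None:
        multiplier = auto_multiplier(n_maj, n_min)
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    if multiplier == 1:
        return replace(ds)
    if n_min < k_neighbors + 1:
        raise ValueError(
            f"minority class has {n_min} instances; need >= {k_neighbors + 1}")

    rng = np.random.default_rng(seed)
    minority = ds.X[ds.y == minority_label]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(minority)
    _, idx = nn.kneighbors(minority)  # column 0 is the point itself
    synth = []
    for i in range(n_min):
        p = minority[i]
        for _ in range(multiplier - 1):
            q = minority[rng.choice(idx[i, 1:])]
            u = rng.uniform()
            synth.append(p + u * (q - p))
    synth = np.asarray(synth)
    X = np.vstack([ds.X, synth])
    y = np.concatenate([ds.y, np.full(len(synth), minority_label, dtype=int)])
    mask = np.zeros(X.shape, dtype=bool)
    prov = dict(ds.provenance)
    prov["smote"] = {"multiplier": int(multiplier), "k_neighbors": int(k_neighbors)}
    return replace(ds, X=X, y=y, missing_mask=mask, provenance=prov)


def minmax_normalize(ds: ClinicalDataset) -> tuple[ClinicalDataset, NormalizationParams]:
    """Fit per-feature min/max on ``ds`` and rescale it to [0, 1]."""
    if ds.missing_mask.any():
        raise ValueError("impute before normalization")
    params = NormalizationParams(min_a=ds.X.min(axis=0), max_a=ds.X.max(axis=0))
    return apply_normalization(ds, params), params


def apply_normalization(ds: ClinicalDataset, params: NormalizationParams) -> ClinicalDataset:
    """a' = (a - min_A) / (max_A - min_A) * (new_max - new_min) + new_min.

    Constant features (zero denominator) map to ``new_min``.
    """
    span = params.max_a - params.min_a
    safe = np.where(span == 0, 1.0, span)
    Xn = (ds.X - params.min_a) / safe
    Xn[:, span == 0] = 0.0
    Xn = Xn * (params.new_max - params.new_min) + params.new_min
    return replace(ds, X=Xn)


def stratified_split(ds: ClinicalDataset, spec: SplitSpec) -> tuple[ClinicalDataset, ClinicalDataset]:
    """Deterministic stratified partition into train and test.

    The train size is ``round_half_up(train_fraction * n)``; per-class
    training counts come from largest-remainder apportionment, so each is
    within one instance of ``train_fraction`` times the class total.
    """
    n = ds.n_instances
    if n < 1:
        raise ValueError("empty dataset")
    target = train_size(n, spec.train_fraction)
    rng = np.random.default_rng(spec.seed)

    if spec.stratified:
        classes = np.unique(ds.y)
        ideal = {c: float(Decimal(str(spec.train_fraction)) * int((ds.y == c).sum()))
                 for c in classes}
        base = {c: math.floor(ideal[c]) for c in classes}
        leftover = target - sum(base.values())
        order = sorted(classes, key=lambda c: ideal[c] - base[c], reverse=True)
        for c in order[:leftover]:
            base[c] += 1
        train_idx = []
        for c in classes:
            rows = np.flatnonzero(ds.y == c)
            rng.shuffle(rows)
            train_idx.extend(rows[: base[c]])
    else:
        rows = np.arange(n)
        rng.shuffle(rows)
        train_idx = list(rows[:target])

    train_idx = np.sort(np.asarray(train_idx, dtype=int))
    test_idx = np.setdiff1d(np.arange(n), train_idx)

    def take(idx: np.ndarray) -> ClinicalDataset:
        return replace(ds, X=ds.X[idx], y=ds.y[idx], missing_mask=ds.missing_mask[idx])

    return take(train_idx), take(test_idx)
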
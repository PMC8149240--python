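"""Wrapper fitness: SVM accuracy of a candidate feature subset.

All three feature selectors score a candidate subset by the stratified
k-fold cross-validated accuracy of a support-vector-machine classifier
trained on the masked-in features of the (preprocessed) training set.
Evaluations are cached by mask bits, so a selector re-visiting a subset
pays nothing and the cache miss count bounds the true search cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataio import ClinicalDataset

__all__ = ["FeatureMask", "FitnessValue", "FitnessEvaluator", "beats", "decode_position"]


@dataclass(frozen=True)
class FeatureMask:
    """Binary inclusion vector over the feature set."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("mask bits must be 0/1")

    @classmethod
    def from_array(cls, arr) -> "FeatureMask":
        return cls(tuple(int(b) for b in np.asarray(arr).ravel()))

    @property
    def cardinality(self) -> int:
        return sum(self.bits)

    def indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.bits))

    def __len__(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class FitnessValue:
    """Cross-validated accuracy plus the bookkeeping selectors sort on."""

    accuracy: float
    mask_cardinality: int
    evaluation_count: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")

    @property
    def objective(self) -> float:
        """Minimization form used by the swarm updates."""
        return 1.0 - self.accuracy


def beats(a: FitnessValue, b: FitnessValue) -> bool:
    """True iff a strictly beats b: higher accuracy, then fewer features.

    A full tie keeps the incumbent (callers replace only on ``beats``).
    """
    if a.accuracy != b.accuracy:
        return a.accuracy > b.accuracy
    return a.mask_cardinality < b.mask_cardinality


def decode_position(position: np.ndarray) -> FeatureMask:
    """Threshold a continuous [0,1] position into a feature mask.

    bit_j = 1 iff position_j >= 0.5.  An all-zero decode is rescued by
    switching on the single largest component, so every agent always maps
    to a trainable subset.
    """
    position = np.asarray(position, dtype=float)
    bits = (position >= 0.5).astype(int)
    if bits.sum() == 0:
        bits[int(np.argmax(position))] = 1
    return FeatureMask.from_array(bits)


@dataclass
class FitnessEvaluator:
    """Cached SVM-accuracy fitness over a fixed training set.

    The fold assignment is fixed by ``seed`` at construction, so fitness is
    a deterministic function of the mask and repeated queries return the
    identical :class:`FitnessValue` object.
    """

    train: ClinicalDataset
    folds: int = 5
    kernel: str = "rbf"
    C: float = 1.0
    seed: int = 0
    _cache: dict = field(default_factory=dict, repr=False)
    _misses: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.train.missing_mask.any():
            raise ValueError("fitness requires a fully imputed training set")
        self._splits = list(
            StratifiedKFold(self.folds, shuffle=True, random_state=self.seed)
            .split(self.train.X, self.train.y)
        )

    @property
    def evaluation_count(self) -> int:
        """Number of cross-validations actually run (cache misses)."""
        return self._misses

    def evaluate(self, mask: FeatureMask) -> FitnessValue:
        if len(mask) != self.train.n_features:
            raise ValueError("mask length does not match feature count")
        key = mask.bits
        if key in self._cache:
            return self._cache[key]
        if mask.cardinality == 0:
            value = FitnessValue(0.0, 0, self._misses)
        else:
            Xm = self.train.X[:, mask.indices()]
            y = self.train.y
            accs = []
            for tr, te in self._splits:
                clf = SVC(kernel=self.kernel, C=self.C)
                clf.fit(Xm[tr], y[tr])
                accs.append(float((clf.predict(Xm[te]) == y[te]).mean()))
            self._misses += 1
            value = FitnessValue(float(np.mean(accs)), mask.cardinality, self._misses)
        self._cache[key] = value
        return value

    __call__ = evaluate
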
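"""Per-window, per-channel time-domain features and dataset partitioning.

The four default features are the classic time-domain set: mean absolute
value (MAV), waveform length (WL), slope sign changes (SSC), and zero
crossings (ZC). ZC and SSC take an optional deadband threshold ``eps``
(volts); with ``eps=0`` both are amplitude-scale invariant, while MAV and
WL scale linearly with the signal.

Feature-matrix columns are channel-major: all features of channel 0, then
channel 1, and so on — ``ch{c}_{feature}`` in exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from emgpr.preprocess import WindowSet

FEATURE_NAMES = ("mav", "wl", "ssc", "zc")


def mav(x: np.ndarray) -> float:
    """Mean absolute value: (1/N) sum |x_i|."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 1:
        raise ValueError("mav needs at least one sample")
    return float(np.mean(np.abs(x)))


def waveform_length(x: np.ndarray) -> float:
    """Total variation: sum |x_{i+1} - x_i|."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("waveform_length needs at least two samples")
    return float(np.sum(np.abs(np.diff(x))))


def _effective_signs(x: np.ndarray) -> np.ndarray:
    """Signs with zeros inheriting the previous nonzero sample's sign.

    Leading zeros (no previous nonzero sample) keep sign 0 and cannot form
    a crossing.
    """
    s = np.sign(x)
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    return s


def zero_crossings(x: np.ndarray, eps: float = 0.0) -> int:
    """Count sign flips between consecutive samples with |x_i - x_{i+1}| > eps."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("zero_crossings needs at least two samples")
    if eps < 0:
        raise ValueError("eps must be >= 0")
    s = _effective_signs(x)
    opposite = s[:-1] * s[1:] < 0
    big_enough = np.abs(np.diff(x)) > eps
    return int(np.count_nonzero(opposite & big_enough))


def slope_sign_changes(x: np.ndarray, eps: float = 0.0) -> int:
    """Count interior extrema where at least one adjacent difference exceeds eps.

    An interior sample x_i counts when (x_i - x_{i-1})(x_i - x_{i+1}) > 0
    and max(|x_i - x_{i-1}|, |x_i - x_{i+1}|) > eps.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise ValueError("slope_sign_changes needs at least three samples")
    if eps < 0:
        raise ValueError("eps must be >= 0")
    d_prev = x[1:-1] - x[:-2]
    d_next = x[1:-1] - x[2:]
    is_extremum = d_prev * d_next > 0
    exceeds = (np.abs(d_prev) > eps) | (np.abs(d_next) > eps)
    return int(np.count_nonzero(is_extremum & exceeds))


_FEATURE_FUNCS = {
    "mav": lambda x, eps: mav(x),
    "wl": lambda x, eps: waveform_length(x),
    "ssc": slope_sign_changes,
    "zc": zero_crossings,
}


@dataclass(frozen=True)
class FeatureSpec:
    features: tuple[str, ...] = FEATURE_NAMES
    eps: float = 0.0  # deadband for zc/ssc, volts

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))
        if not self.features:
            raise ValueError("feature list must be non-empty")
        unknown = set(self.features) - set(_FEATURE_FUNCS)
        if unknown:
            raise ValueError(f"unknown features: {sorted(unknown)}")
        if self.eps < 0:
            raise ValueError("eps must be >= 0")


@dataclass
class FeatureMatrix:
    """Rows = windows, columns = channels x features, one class label per row."""

    values: np.ndarray
    labels: np.ndarray  # class label per row
    column_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("one label per row required")
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("column_names must match column count")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(str(lab), None)
        return list(seen)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "class", self.labels)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        if "class" not in df.columns:
            raise ValueError("feature CSV must have a 'class' column")
        labels = df.pop("class").to_numpy()
        return cls(values=df.to_numpy(dtype=np.float64), labels=labels,
                   column_names=list(df.columns))


def feature_column_names(n_channels: int, spec: FeatureSpec) -> list[str]:
    return [f"ch{c}_{f}" for c in range(n_channels) for f in spec.features]


def extract_features(window_set: WindowSet, spec: FeatureSpec | None = None) -> FeatureMatrix:
    """Compute the feature vector of every window in the set.

    Column order is channel-major then feature, matching
    :func:`feature_column_names`.
    """
    spec = spec or FeatureSpec()
    n_channels = next(iter(window_set.signals.values())).shape[1] if window_set.signals else 0
    names = feature_column_names(n_channels, spec)
    rows = np.empty((len(window_set.windows), len(names)))
    labels = []
    for r, (label, start, stop) in enumerate(window_set.windows):
        seg = window_set.signals[label][start:stop]
        if not np.all(np.isfinite(seg)):
            raise ValueError(f"non-finite samples in window {r} of class {label!r}")
        col = 0
        for c in range(n_channels):
            x = seg[:, c]
            for f in spec.features:
                rows[r, col] = _FEATURE_FUNCS[f](x, spec.eps)
                col += 1
        labels.append(label)
    return FeatureMatrix(values=rows, labels=np.array(labels, dtype=object), column_names=names)


@dataclass
class DataSplit:
    """Disjoint training/validation/test row indices covering all rows."""

    training: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    proportions: tuple[float, float, float]
    rng_seed: int

    def __post_init__(self) -> None:
        parts = [np.asarray(p, dtype=int) for p in (self.training, self.validation, self.test)]
        self.training, self.validation, self.test = parts
        combined = np.concatenate(parts)
        if len(np.unique(combined)) != combined.size:
            raise ValueError("split sets must be disjoint")


def largest_remainder_sizes(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Integer set sizes summing to n, by largest-remainder rounding."""
    exact = [n * p for p in proportions]
    sizes = [int(np.floor(e)) for e in exact]
    shortfall = n - sum(sizes)
    remainders = sorted(
        range(len(proportions)), key=lambda i: (exact[i] - sizes[i], -i), reverse=True
    )
    for i in remainders[:shortfall]:
        sizes[i] += 1
    return sizes


def split_sets(
    matrix: FeatureMatrix,
    proportions: tuple[float, float, float] = (0.40, 0.20, 0.40),
    rng_seed: int = 0,
) -> DataSplit:
    """Stratified random partition into training/validation/test.

    Within every class, rows are shuffled (seeded) and dealt to the three
    sets with largest-remainder rounding, so per-class counts are within
    one window of the target proportions.
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(rng_seed)
    train, val, test = [], [], []
    for cls in matrix.classes:
        rows = np.flatnonzero(matrix.labels == cls)
        if rows.size < 3 and all(p > 0 for p in proportions):
            raise ValueError(f"class {cls!r} has {rows.size} windows; need >= 3 to split")
        rows = rng.permutation(rows)
        n_tr, n_va, n_te = largest_remainder_sizes(rows.size, proportions)
        train.append(rows[:n_tr])
        val.append(rows[n_tr: n_tr + n_va])
        test.append(rows[n_tr + n_va:])
        assert rows.size - n_tr - n_va == n_te
    cat = lambda parts: np.sort(np.concatenate(parts)) if parts else np.array([], dtype=int)
    return DataSplit(
        training=cat(train), validation=cat(val), test=cat(test),
        proportions=tuple(proportions), rng_seed=rng_seed,
    )
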
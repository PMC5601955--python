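"""Pairwise linear discriminant analysis with one-vs-one majority voting.

Each unordered class pair (a, b) gets a linear discriminant fitted on the
training rows of those two classes only: with pooled within-class
covariance S (ridge-stabilized as S + lambda*I) and class means mu_a, mu_b,

    w  = (S + lambda*I)^-1 (mu_a - mu_b)
    b0 = -w . (mu_a + mu_b) / 2          (equal priors, midpoint rule)

d(x) = w.x + b0 > 0 votes for a, otherwise b. Multiclass prediction takes
the class with most votes; ties break by the largest sum of |d(x)| over the
tied classes' pairs, then by lowest class index. Both rules are
deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from emgpr.features import DataSplit, FeatureMatrix


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled covariance is singular; refit with a ridge lambda > 0."""


@dataclass
class LdaPair:
    class_a: str
    class_b: str
    w: np.ndarray
    b0: float

    def decision(self, x: np.ndarray) -> float:
        return float(self.w @ x + self.b0)


def _fit_pair(
    xa: np.ndarray, xb: np.ndarray, class_a: str, class_b: str, ridge: float
) -> LdaPair:
    mu_a = xa.mean(axis=0)
    mu_b = xb.mean(axis=0)
    # pooled within-class scatter, (n_a + n_b - 2) denominator
    sa = (xa - mu_a).T @ (xa - mu_a)
    sb = (xb - mu_b).T @ (xb - mu_b)
    dof = xa.shape[0] + xb.shape[0] - 2
    cov = (sa + sb) / max(dof, 1)
    dim = cov.shape[0]
    cov_r = cov + ridge * np.eye(dim)
    try:
        w = np.linalg.solve(cov_r, mu_a - mu_b)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            f"pooled covariance for pair ({class_a!r}, {class_b!r}) is singular; "
            "use ridge_lambda > 0"
        ) from exc
    if not np.all(np.isfinite(w)):
        raise SingularCovarianceError(
            f"non-finite discriminant for pair ({class_a!r}, {class_b!r}); "
            "use ridge_lambda > 0"
        )
    b0 = float(-w @ (mu_a + mu_b) / 2.0)
    return LdaPair(class_a=class_a, class_b=class_b, w=w, b0=b0)


@dataclass
class OvoClassifier:
    classes: list[str]
    pairs: list[LdaPair]
    ridge_lambda: float
    column_names: list[str]

    @property
    def n_features(self) -> int:
        return len(self.column_names)

    def predict_one(self, x: np.ndarray) -> tuple[str, dict[str, int]]:
        """Label plus per-class vote counts for one feature vector."""
        x = np.asarray(x, dtype=np.float64)
        if x.shape != (self.n_features,):
            raise ValueError(
                f"feature vector has shape {x.shape}, classifier expects ({self.n_features},)"
            )
        votes = {c: 0 for c in self.classes}
        margins = {c: 0.0 for c in self.classes}
        for pair in self.pairs:
            d = pair.decision(x)
            winner = pair.class_a if d > 0 else pair.class_b
            votes[winner] += 1
            margins[pair.class_a] += abs(d)
            margins[pair.class_b] += abs(d)
        top = max(votes.values())
        tied = [c for c in self.classes if votes[c] == top]
        if len(tied) > 1:
            best = max(margins[c] for c in tied)
            tied = [c for c in tied if margins[c] == best]
        # residual ties resolve to the lowest class index
        return tied[0], votes

    def predict(self, xs: np.ndarray) -> np.ndarray:
        xs = np.atleast_2d(np.asarray(xs, dtype=np.float64))
        return np.array([self.predict_one(x)[0] for x in xs], dtype=object)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": self.classes,
            "ridge_lambda": self.ridge_lambda,
            "column_names": self.column_names,
            "pairs": [
                {
                    "class_a": p.class_a,
                    "class_b": p.class_b,
                    "w": [float(v) for v in p.w],
                    "b0": p.b0,
                }
                for p in self.pairs
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "OvoClassifier":
        payload = json.loads(Path(path).read_text())
        pairs = [
            LdaPair(
                class_a=p["class_a"], class_b=p["class_b"],
                w=np.array(p["w"], dtype=np.float64), b0=p["b0"],
            )
            for p in payload["pairs"]
        ]
        return cls(
            classes=payload["classes"], pairs=pairs,
            ridge_lambda=payload["ridge_lambda"],
            column_names=payload["column_names"],
        )


def default_ridge(cov_trace: float, dim: int) -> float:
    return 1e-6 * cov_trace / dim if dim else 0.0


def fit_ovo(
    matrix: FeatureMatrix,
    split: DataSplit | None = None,
    ridge_lambda: float | None = None,
) -> OvoClassifier:
    """Fit one discriminant per unordered class pair on the training rows.

    ``ridge_lambda=None`` uses the default 1e-6 * trace(S_pooled)/dim,
    computed over all training rows; pass 0.0 to disable ridging (raises
    if the covariance is singular).
    """
    rows = split.training if split is not None else np.arange(matrix.n_rows)
    x = matrix.values[rows]
    y = matrix.labels[rows]
    classes = matrix.classes
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    by_class = {c: x[y == c] for c in classes}
    for c, xc in by_class.items():
        if xc.shape[0] < 2:
            raise ValueError(f"class {c!r} has {xc.shape[0]} training rows; need >= 2")
    if ridge_lambda is None:
        pooled = sum(
            (xc - xc.mean(axis=0)).T @ (xc - xc.mean(axis=0)) for xc in by_class.values()
        ) / max(x.shape[0] - len(classes), 1)
        ridge_lambda = default_ridge(float(np.trace(pooled)), x.shape[1])
    pairs = [
        _fit_pair(by_class[a], by_class[b], a, b, ridge_lambda)
        for i, a in enumerate(classes)
        for b in classes[i + 1:]
    ]
    return OvoClassifier(
        classes=classes, pairs=pairs, ridge_lambda=float(ridge_lambda),
        column_names=list(matrix.column_names),
    )


def offline_accuracy(
    clf: OvoClassifier, matrix: FeatureMatrix, split: DataSplit | None = None
) -> float:
    """Fraction of test rows predicted correctly."""
    rows = split.test if split is not None else np.arange(matrix.n_rows)
    if len(rows) == 0:
        raise ValueError("test partition is empty")
    preds = clf.predict(matrix.values[rows])
    return float(np.mean(preds == matrix.labels[rows]))
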
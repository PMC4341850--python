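"""One-dimensional Gaussian Bayes classification with leave-one-out evaluation.

Each class is modelled by a univariate normal density fitted to its feature
values (population variance, i.e. divide by n, with a small variance floor so
single-sample classes remain well defined); priors are the class frequencies.
The decision threshold is the feature value where the class posteriors are
equal — for equal variances and priors simply the midpoint of the means, in
general a root of the quadratic obtained by equating the class log densities
plus log priors.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class GaussianClassModel:
    """Per-class mean/variance/prior for a 1-D two-class Gaussian Bayes rule.

    Classes are stored in sorted label order; ties in the posterior resolve
    to the first class.
    """

    classes: tuple
    means: tuple
    variances: tuple
    priors: tuple
    feature_name: str = ""
    var_floor: float = 0.0

    def log_posterior(self, x) -> np.ndarray:
        """Unnormalized log posteriors, shape (n_classes,) + shape(x)."""
        x = np.asarray(x, dtype=float)
        out = []
        for m, v, p in zip(self.means, self.variances, self.priors):
            out.append(math.log(p) - 0.5 * math.log(2 * math.pi * v) - (x - m) ** 2 / (2 * v))
        return np.stack(out)


def fit_gaussian_bayes(
    features,
    labels,
    *,
    equal_variance: bool = False,
    feature_name: str = "",
    var_floor: float | None = None,
) -> GaussianClassModel:
    """Fit class means, (population) variances and frequency priors.

    ``var_floor`` defaults to ``1e-9 * range(features)**2 + 1e-12`` so that a
    class with a single sample or zero spread keeps a valid density.
    """
    x = np.asarray(features, dtype=float)
    labels = list(labels)
    if len(x) != len(labels):
        raise ValidationError("features and labels must have equal length")
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValidationError(f"need at least two classes, got {classes}")
    counts = Counter(labels)
    for c in classes:
        if counts[c] == 0:
            raise ValidationError(f"class {c!r} has no samples")
    if var_floor is None:
        span = float(x.max() - x.min()) if len(x) else 0.0
        var_floor = 1e-9 * span**2 + 1e-12
    means, variances, priors = [], [], []
    mask_by_class = {c: np.array([l == c for l in labels]) for c in classes}
    for c in classes:
        xc = x[mask_by_class[c]]
        means.append(float(xc.mean()))
        variances.append(float(xc.var()))  # population convention (divide by n)
        priors.append(counts[c] / len(labels))
    if equal_variance:
        pooled = float(sum(v * counts[c] for v, c in zip(variances, classes)) / len(labels))
        variances = [pooled] * len(classes)
    variances = [max(v, var_floor) for v in variances]
    return GaussianClassModel(
        classes, tuple(means), tuple(variances), tuple(priors), feature_name, var_floor
    )


def _threshold_roots(model: GaussianClassModel) -> list:
    (m1, m2), (v1, v2), (p1, p2) = model.means, model.variances, model.priors
    a = 0.5 * (1.0 / v2 - 1.0 / v1)
    b = m1 / v1 - m2 / v2
    c = (
        m2**2 / (2 * v2)
        - m1**2 / (2 * v1)
        + math.log(p1 / p2)
        + 0.5 * math.log(v2 / v1)
    )
    scale = max(abs(a), abs(b), abs(c), 1.0)
    if abs(a) < 1e-14 * scale:
        if abs(b) < 1e-14 * scale:
            raise ValidationError("identical class densities: no decision threshold")
        return [-c / b]
    disc = b**2 - 4 * a * c
    if disc < 0:
        raise ValidationError("class posteriors never cross: no decision threshold")
    sq = math.sqrt(disc)
    return sorted(((-b - sq) / (2 * a), (-b + sq) / (2 * a)))


def decision_threshold(model: GaussianClassModel, all_roots: bool = False):
    """Feature value(s) where the two class posteriors are equal.

    With ``all_roots=False`` returns the single operating threshold: for
    equal variances the unique crossing; otherwise the root lying between
    the class means (falling back to the root closest to their midpoint).
    """
    roots = _threshold_roots(model)
    if all_roots:
        return tuple(roots)
    if len(roots) == 1:
        return float(roots[0])
    lo, hi = sorted(model.means)
    inside = [r for r in roots if lo <= r <= hi]
    if inside:
        return float(inside[0])
    mid = 0.5 * (lo + hi)
    return float(min(roots, key=lambda r: abs(r - mid)))


def predict(model: GaussianClassModel, x):
    """Class with the maximal posterior; posterior ties go to the first class."""
    lp = model.log_posterior(x)
    if np.ndim(x) == 0:
        return model.classes[int(np.argmax(lp))]
    return [model.classes[i] for i in np.argmax(lp, axis=0)]


@dataclass
class ConfusionTable:
    """2x2 table of predicted class (rows) x actual class (columns)."""

    classes: tuple
    table: np.ndarray

    @property
    def total(self) -> int:
        return int(self.table.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.table)) / self.total

    @property
    def n_errors(self) -> int:
        return self.total - int(np.trace(self.table))

    def is_diagonal(self) -> bool:
        return self.n_errors == 0

    def to_dict(self) -> dict:
        return {
            f"pred_{p}_actual_{a}": int(self.table[i, j])
            for i, p in enumerate(self.classes)
            for j, a in enumerate(self.classes)
        }


def leave_one_out(features, labels, *, equal_variance: bool = False) -> ConfusionTable:
    """Leave-one-out cross-validation of the Gaussian Bayes rule.

    Each sample is predicted by a model trained on all remaining samples;
    a fold that would lose a class entirely raises an error naming the fold.
    """
    x = np.asarray(features, dtype=float)
    labels = list(labels)
    classes = tuple(sorted(set(labels)))
    counts = Counter(labels)
    for c in classes:
        if counts[c] < 2:
            raise ValidationError(
                f"class {c!r} has {counts[c]} sample(s); leave-one-out needs >= 2 per class"
            )
    idx = {c: i for i, c in enumerate(classes)}
    table = np.zeros((len(classes), len(classes)), dtype=int)
    for i in range(len(x)):
        rest = [j for j in range(len(x)) if j != i]
        rest_labels = [labels[j] for j in rest]
        if set(rest_labels) != set(classes):
            raise ValidationError(f"fold {i} loses class {labels[i]!r} entirely")
        model = fit_gaussian_bayes(x[rest], rest_labels, equal_variance=equal_variance)
        pred = predict(model, float(x[i]))
        table[idx[pred], idx[labels[i]]] += 1
    return ConfusionTable(classes, table)
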
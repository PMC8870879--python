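"""Entropy-based dependence measures for feature screening.

All measures operate on discretized variables and use plug-in
(maximum-likelihood) probability estimates with base-2 logarithms, so
entropies are in bits.  Symmetric uncertainty (SU) normalizes mutual
information into [0, 1]; its multivariate extension (MSU) normalizes
total correlation by the sum of marginal entropies with the
``n/(n-1)`` multiplier, so that full dependence of any number of
variables maps to 1 and joint independence to 0.

Continuous inputs must be discretized first (see :func:`discretize`);
the default is equal-frequency binning with ``max(2, floor(sqrt(n)/2))``
bins capped at 10, a free choice documented in ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiscretizedVariable",
    "default_n_bins",
    "discretize",
    "entropy",
    "joint_entropy",
    "joint_entropy_multi",
    "conditional_entropy",
    "mutual_information",
    "symmetric_uncertainty",
    "total_correlation",
    "msu",
    "pearson",
]

#: Guard on the theoretical size of the n-way contingency table.
JOINT_TABLE_CELL_GUARD = int(1e7)


class CapacityError(ValueError):
    """Joint contingency table would exceed the cell guard."""


@dataclass
class DiscretizedVariable:
    """Integer category labels plus the edges that produced them.

    Storing ``bin_edges`` lets held-out data be mapped onto the bins
    learned from training data (idempotent on the training sample).
    """

    labels: np.ndarray
    n_bins: int
    strategy: str = "equal-frequency"
    bin_edges: np.ndarray = field(default_factory=lambda: np.array([]))
    constant: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.n_bins):
            raise ValueError("labels must lie in [0, n_bins)")

    def __len__(self) -> int:
        return self.labels.size

    def apply(self, values: np.ndarray) -> "DiscretizedVariable":
        """Re-apply the stored edges to new data."""
        labels = np.searchsorted(self.bin_edges, np.asarray(values, float), side="right")
        labels = np.clip(labels, 0, self.n_bins - 1)
        return DiscretizedVariable(labels, self.n_bins, self.strategy, self.bin_edges, self.constant)


def default_n_bins(n_samples: int) -> int:
    return min(10, max(2, int(np.sqrt(n_samples) / 2)))


def discretize(values, n_bins: int | None = None, strategy: str = "equal-frequency") -> DiscretizedVariable:
    """Bin a numeric series into integer categories.

    Equal-frequency (default) places interior edges at quantiles, with
    ties resolved by the sample's value order; equal-width splits the
    observed range uniformly.  A constant input collapses to a single
    category and is flagged.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot discretize an empty series")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    if n_bins is None:
        n_bins = default_n_bins(x.size)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if np.ptp(x) == 0:
        return DiscretizedVariable(np.zeros(x.size, dtype=np.int64), 1, strategy,
                                   np.array([]), constant=True)
    if strategy == "equal-frequency":
        qs = np.linspace(0, 1, n_bins + 1)[1:-1]
        edges = np.unique(np.quantile(x, qs))
    elif strategy == "equal-width":
        edges = np.linspace(x.min(), x.max(), n_bins + 1)[1:-1]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    labels = np.searchsorted(edges, x, side="right")
    n_eff = int(labels.max()) + 1
    return DiscretizedVariable(labels, n_eff, strategy, edges)


def _as_labels(x) -> np.ndarray:
    if isinstance(x, DiscretizedVariable):
        return x.labels
    arr = np.asarray(x)
    if arr.dtype.kind in "fc":
        # Continuous input: caller should discretize explicitly; accept
        # exact discrete floats only.
        if not np.all(arr == np.round(arr)):
            raise TypeError("continuous input: call discretize() first")
    return arr.astype(np.int64, copy=False)


def _plugin_entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def entropy(x) -> float:
    """Plug-in Shannon entropy in bits; 0*log 0 := 0."""
    labels = _as_labels(x)
    if labels.size == 0:
        raise ValueError("empty variable")
    _, counts = np.unique(labels, return_counts=True)
    return _plugin_entropy(counts)


def joint_entropy(x, y) -> float:
    return joint_entropy_multi([x, y])


def joint_entropy_multi(variables) -> float:
    """Plug-in entropy of the n-way contingency table.

    The table is counted sparsely (only observed cells), but the guard
    on the theoretical cell count is enforced so callers do not build
    degenerate high-dimensional estimates.
    """
    cols = [_as_labels(v) for v in variables]
    if len(cols) == 0:
        raise ValueError("need at least one variable")
    n = cols[0].size
    if any(c.size != n for c in cols):
        raise ValueError("length mismatch among variables")
    cells = 1.0
    for c in cols:
        cells *= max(1, int(c.max()) - int(c.min()) + 1)
    if cells > JOINT_TABLE_CELL_GUARD:
        raise CapacityError(
            f"joint table would have {cells:.3g} cells (> {JOINT_TABLE_CELL_GUARD:g}); reduce bins"
        )
    stacked = np.column_stack(cols)
    _, counts = np.unique(stacked, axis=0, return_counts=True)
    return _plugin_entropy(counts)


def conditional_entropy(x, y) -> float:
    """H(X|Y) = H(X,Y) - H(Y), always >= 0 up to rounding."""
    xl, yl = _as_labels(x), _as_labels(y)
    if xl.size != yl.size:
        raise ValueError("length mismatch")
    return max(0.0, joint_entropy(xl, yl) - entropy(yl))


def mutual_information(x, y) -> float:
    """MI(X;Y) = H(X) + H(Y) - H(X,Y) in bits (symmetric form)."""
    xl, yl = _as_labels(x), _as_labels(y)
    if xl.size != yl.size:
        raise ValueError("length mismatch")
    return max(0.0, entropy(xl) + entropy(yl) - joint_entropy(xl, yl))


def symmetric_uncertainty(x, y) -> float:
    """SU(X,Y) = 2*MI / (H(X)+H(Y)), in [0, 1].

    Returns NaN when both variables are constant (dependence undefined).
    """
    xl, yl = _as_labels(x), _as_labels(y)
    hx, hy = entropy(xl), entropy(yl)
    denom = hx + hy
    if denom <= 0.0:
        return float("nan")
    su = 2.0 * mutual_information(xl, yl) / denom
    return float(min(1.0, max(0.0, su)))


def total_correlation(variables) -> float:
    """C(X_1:n) = sum_i H(X_i) - H(X_1:n) >= 0; equals MI for n = 2."""
    cols = [_as_labels(v) for v in variables]
    if len(cols) < 1:
        raise ValueError("need at least one variable")
    marginal = sum(entropy(c) for c in cols)
    return max(0.0, marginal - joint_entropy_multi(cols))


def msu(variables) -> float:
    """Multivariate symmetric uncertainty of n >= 2 variables.

    MSU = (n/(n-1)) * (1 - H(joint)/sum_i H(X_i)), clipped to [0, 1]
    against floating error only.  NaN when every variable is constant.
    """
    cols = [_as_labels(v) for v in variables]
    n = len(cols)
    if n < 2:
        raise ValueError("MSU needs at least two variables")
    marginal = sum(entropy(c) for c in cols)
    if marginal <= 0.0:
        return float("nan")
    value = (n / (n - 1.0)) * (1.0 - joint_entropy_multi(cols) / marginal)
    return float(min(1.0, max(0.0, value)))


def pearson(x, y) -> float:
    """Product-moment correlation; NaN for constant input (flagged upstream)."""
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if xa.size != ya.size:
        raise ValueError("length mismatch")
    if np.std(xa) == 0.0 or np.std(ya) == 0.0:
        return float("nan")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    return float((xc * yc).sum() / np.sqrt((xc * xc).sum() * (yc * yc).sum()))
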
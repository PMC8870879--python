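"""Hybrid feature selection driven by (multivariate) symmetric uncertainty.

The selector combines two filter methods and fuses their rankings:

1. **FC-MSU** — a fast-correlation filter.  Step 1 ranks features by
   SU with the target and keeps those above a relevance threshold
   (set S1).  Step 2 removes redundancy: walking S1 in SU-descending
   order, a lower-ranked feature *f* is displaced by a kept feature
   *g* when ``SU(g, f) >= p * SU(f, target)``; the scale *p* starts
   high and decreases by 0.1 per round down to 1, and the rounds stop
   early once the MSU of the surviving set (plus the target) drops to
   a near-zero value — the survivors S' are then mutually
   non-redundant "predominant" features.  Every removal is logged for
   auditability.

2. **ReliefF with MSU pre-ranking** — instance-based weights that
   reward features whose values separate target classes among
   Manhattan-nearest neighbors, and therefore see feature
   interactions that per-feature filters miss.  The continuous target
   is discretized into quantile classes; misses are weighted by class
   priors.  A SU pre-ranking keeps only the top fraction of features
   before the (quadratic-cost) weight computation.

The final list is the mean-rank fusion of the two orders, truncated
to ``top_k``.  A Pearson-|r| baseline ranking is provided for the
linear-only comparison mode.

Estimators follow the scikit-learn API (``fit`` / ``transform`` /
``get_support``) and compose with sklearn pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from . import infotheory as it

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "fc_step1_relevance",
    "fc_step2_redundancy",
    "relieff_diff",
    "relieff_weights",
    "fuse_rankings",
    "pearson_baseline_rank",
    "select_features",
    "HybridFeatureSelector",
    "PearsonCorrelationSelector",
]


@dataclass
class SelectionConfig:
    """Tunables of the hybrid selector.

    ``relevance_threshold`` must sit between the plug-in SU bias floor
    (~(B-1)^2 / (N ln2) / (Hx+Hy), about 0.01 at N=2000 with 10 bins)
    and the SU a genuinely relevant feature can reach; a feature that
    carries 1/k of the target's variance among k independent causes
    tops out near 0.05, which motivates the 0.03 default.
    """

    relevance_threshold: float = 0.03
    p_start: float = 2.0
    p_step: float = 0.1
    p_floor: float = 1.0
    msu_stop: float = 0.05
    relieff_k: int = 10
    relieff_m: int | None = None      # None -> use every instance
    target_bins: int = 5
    top_k: int = 12
    prerank_fraction: float = 0.5
    n_bins: int | None = None         # None -> default_n_bins(n_samples)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.relevance_threshold < 1):
            raise ValueError("relevance_threshold must be in [0, 1)")
        if not (self.p_start >= self.p_floor >= 1.0):
            raise ValueError("need p_start >= p_floor >= 1")
        if not (0 < self.msu_stop < 1):
            raise ValueError("msu_stop must be in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not (0 < self.prerank_fraction <= 1):
            raise ValueError("prerank_fraction must be in (0, 1]")


@dataclass
class SelectionResult:
    su_ranking: list                 # (feature, SU with target), sorted desc
    s1: list
    s_prime: list
    final_p: float
    final_msu: float
    removal_log: list
    relieff_weights: list            # (feature, W), sorted desc
    fused_rank: list
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["su_ranking"] = [[f, float(s)] for f, s in self.su_ranking]
        d["relieff_weights"] = [[f, float(w)] for f, w in self.relieff_weights]
        return d


# ---------------------------------------------------------------------------


def _discretize_frame(X: pd.DataFrame, n_bins: int | None):
    nb = n_bins if n_bins is not None else it.default_n_bins(len(X))
    return {c: it.discretize(X[c].to_numpy(), nb) for c in X.columns}


def fc_step1_relevance(X: pd.DataFrame, y, config: SelectionConfig | None = None):
    """SU-with-target ranking and the relevant set S1."""
    config = config or SelectionConfig()
    if X.shape[1] < 2:
        raise ValueError("need at least two features")
    disc = _discretize_frame(X, config.n_bins)
    yd = it.discretize(np.asarray(y, dtype=float), config.n_bins)
    su = {c: it.symmetric_uncertainty(disc[c], yd) for c in X.columns}
    order = sorted(X.columns, key=lambda c: (-su[c], list(X.columns).index(c)))
    ranking = [(c, su[c]) for c in order]
    s1 = [c for c, s in ranking if s >= config.relevance_threshold]
    return ranking, s1


def _msu_guarded(variables, n_raw_list):
    """MSU with automatic bin reduction to respect the joint-table guard."""
    try:
        return it.msu(variables)
    except it.CapacityError:
        n_vars = len(variables)
        nb = max(2, int(it.JOINT_TABLE_CELL_GUARD ** (1.0 / n_vars)))
        redisc = [it.discretize(raw, nb) for raw in n_raw_list]
        return it.msu(redisc)


def fc_step2_redundancy(s1, X: pd.DataFrame, y, config: SelectionConfig | None = None,
                        su_with_target: dict | None = None):
    """Redundancy elimination over S1 with the decreasing-p schedule.

    Returns ``(s_prime, removal_log, final_p, final_msu)``.  The log
    records, for every removal, which kept feature displaced which
    candidate at which value of p, so S' is reconstructible from S1.
    """
    config = config or SelectionConfig()
    if not s1:
        return [], [], config.p_start, float("nan")
    disc = _discretize_frame(X[list(s1)], config.n_bins)
    yd = it.discretize(np.asarray(y, dtype=float), config.n_bins)
    if su_with_target is None:
        su_with_target = {c: it.symmetric_uncertainty(disc[c], yd) for c in s1}
    order = sorted(s1, key=lambda c: (-su_with_target[c], list(X.columns).index(c)))

    pair_cache: dict = {}

    def pair_su(a, b):
        key = (a, b) if a <= b else (b, a)
        if key not in pair_cache:
            pair_cache[key] = it.symmetric_uncertainty(disc[a], disc[b])
        return pair_cache[key]

    survivors = list(order)
    log: list = []
    p = config.p_start
    final_msu = float("nan")
    while True:
        kept: list = []
        for f in survivors:
            displaced_by = None
            for g in kept:
                if pair_su(g, f) >= p * su_with_target[f]:
                    displaced_by = g
                    break
            if displaced_by is None:
                kept.append(f)
            else:
                log.append({"removed": f, "by": displaced_by, "p": round(p, 10),
                            "su_pair": pair_su(displaced_by, f),
                            "su_target": su_with_target[f]})
        survivors = kept
        if survivors:
            raw = [X[c].to_numpy() for c in survivors] + [np.asarray(y, float)]
            vars_ = [disc[c] for c in survivors] + [yd]
            final_msu = _msu_guarded(vars_, raw)
        if (np.isfinite(final_msu) and final_msu <= config.msu_stop) \
                or p <= config.p_floor + 1e-12 or not survivors:
            break
        p = p - config.p_step
    return survivors, log, float(p), float(final_msu)


# ---------------------------------------------------------------------------
# ReliefF


def relieff_diff(v1: float, v2: float, vmin: float, vmax: float,
                 kind: str = "numeric") -> float:
    """Per-feature difference in [0, 1]: indicator for nominal features,
    range-normalized absolute difference for numeric ones."""
    if kind == "nominal":
        return 0.0 if v1 == v2 else 1.0
    rng = vmax - vmin
    if rng <= 0:
        return 0.0
    return abs(v1 - v2) / rng


def relieff_weights(X: pd.DataFrame, y, config: SelectionConfig | None = None):
    """ReliefF weights on the SU-preranked candidate features.

    The target is discretized into quantile classes; neighbors use
    Manhattan distance over [0,1]-scaled features; misses are weighted
    by ``p(C) / (1 - p(class(Y_i)))``.  Weights lie in [-1, 1].
    """
    config = config or SelectionConfig()
    rng = np.random.default_rng(config.seed)
    n = len(X)

    ranking, _ = fc_step1_relevance(X, y, config) if X.shape[1] >= 2 else ([], [])
    n_keep = max(2, int(np.ceil(config.prerank_fraction * X.shape[1])))
    candidates = [c for c, _ in ranking[:n_keep]] if ranking else list(X.columns)

    Xc = X[candidates].to_numpy(dtype=float)
    vmin, vmax = Xc.min(axis=0), Xc.max(axis=0)
    span = np.where(vmax - vmin > 0, vmax - vmin, 1.0)
    Xs = (Xc - vmin) / span

    yv = np.asarray(y, dtype=float)
    edges = np.unique(np.quantile(yv, np.linspace(0, 1, config.target_bins + 1)[1:-1]))
    classes = np.searchsorted(edges, yv, side="right")
    labels, counts = np.unique(classes, return_counts=True)
    priors = {int(c): cnt / n for c, cnt in zip(labels, counts)}
    by_class = {int(c): np.flatnonzero(classes == c) for c in labels}

    m = n if config.relieff_m is None else min(config.relieff_m, n)
    sampled = np.arange(n) if m == n else np.sort(rng.choice(n, size=m, replace=False))

    k = config.relieff_k
    W = np.zeros(len(candidates))
    chunk = 256
    for start in range(0, m, chunk):
        idx = sampled[start:start + chunk]
        D = cdist(Xs[idx], Xs, metric="cityblock")
        for row, i in enumerate(idx):
            ci = int(classes[i])
            same = by_class[ci]
            same = same[same != i]
            if same.size == 0:
                continue
            kh = min(k, same.size)
            hit_idx = same[np.argpartition(D[row, same], kh - 1)[:kh]]
            W -= np.abs(Xs[i] - Xs[hit_idx]).sum(axis=0) / (m * kh)
            denom = 1.0 - priors[ci]
            if denom <= 0:
                continue
            for c in by_class:
                if c == ci:
                    continue
                others = by_class[c]
                km = min(k, others.size)
                if km == 0:
                    continue
                miss_idx = others[np.argpartition(D[row, others], km - 1)[:km]]
                W += (priors[c] / denom) * np.abs(Xs[i] - Xs[miss_idx]).sum(axis=0) / (m * km)
    order = np.argsort(-W, kind="stable")
    return [(candidates[j], float(W[j])) for j in order]


# ---------------------------------------------------------------------------
# fusion and baseline


def fuse_rankings(fc_order, relieff_order, top_k: int, universe=None):
    """Mean-rank fusion; features absent from a ranking get worst-rank + 1.

    Ties break by FC rank, then by position in ``universe`` (column
    order).  Returns the first ``top_k`` features.
    """
    if universe is None:
        universe = list(dict.fromkeys(list(fc_order) + list(relieff_order)))
    universe = list(universe)

    def ranks(order):
        pos = {f: i + 1 for i, f in enumerate(order)}
        worst = len(order) + 1
        return {f: pos.get(f, worst) for f in universe}

    r_fc, r_rf = ranks(list(fc_order)), ranks(list(relieff_order))
    mean_rank = {f: 0.5 * (r_fc[f] + r_rf[f]) for f in universe}
    fused = sorted(universe, key=lambda f: (mean_rank[f], r_fc[f], universe.index(f)))
    if top_k > len(fused):
        return fused
    return fused[:top_k]


def pearson_baseline_rank(X: pd.DataFrame, y):
    """Features by |Pearson r| with the target, descending; constant
    columns rank last with a NaN score."""
    yv = np.asarray(y, dtype=float)
    scores = {c: it.pearson(X[c].to_numpy(), yv) for c in X.columns}
    def key(c):
        r = scores[c]
        return (-(abs(r) if np.isfinite(r) else -1.0), list(X.columns).index(c))
    order = sorted(X.columns, key=key)
    return [(c, scores[c]) for c in order]


def select_features(X: pd.DataFrame, y, config: SelectionConfig | None = None,
                    method: str = "msu-hybrid") -> SelectionResult:
    """Run the full selection pipeline on a feature matrix."""
    config = config or SelectionConfig()
    if method == "pearson":
        ranking = pearson_baseline_rank(X, y)
        fused = [c for c, _ in ranking[:config.top_k]]
        return SelectionResult(su_ranking=[], s1=[], s_prime=[], final_p=np.nan,
                               final_msu=np.nan, removal_log=[],
                               relieff_weights=[],
                               fused_rank=fused, config=asdict(config))
    if method != "msu-hybrid":
        raise ValueError(f"unknown method {method!r}")
    su_ranking, s1 = fc_step1_relevance(X, y, config)
    su_map = dict(su_ranking)
    s_prime, log, final_p, final_msu = fc_step2_redundancy(
        s1, X, y, config, su_with_target=su_map)
    rf = relieff_weights(X, y, config)
    fused = fuse_rankings(list(s_prime), [c for c, _ in rf], config.top_k,
                          universe=list(X.columns))
    return SelectionResult(su_ranking=su_ranking, s1=s1, s_prime=s_prime,
                           final_p=final_p, final_msu=final_msu, removal_log=log,
                           relieff_weights=rf, fused_rank=fused,
                           config=asdict(config))


# ---------------------------------------------------------------------------
# scikit-learn estimators


class HybridFeatureSelector(SelectorMixin, BaseEstimator):
    """MSU-hybrid feature selector (FC-MSU + ReliefF, mean-rank fused).

    Parameters mirror :class:`SelectionConfig`.  After ``fit`` the
    fused top-k features form the support mask; the full audit trail
    is available as ``result_``.
    """

    def __init__(self, relevance_threshold: float = 0.03, p_start: float = 2.0,
                 p_step: float = 0.1, p_floor: float = 1.0, msu_stop: float = 0.05,
                 relieff_k: int = 10, relieff_m: int | None = None,
                 target_bins: int = 5, top_k: int = 12,
                 prerank_fraction: float = 0.5, n_bins: int | None = None,
                 seed: int = 0):
        self.relevance_threshold = relevance_threshold
        self.p_start = p_start
        self.p_step = p_step
        self.p_floor = p_floor
        self.msu_stop = msu_stop
        self.relieff_k = relieff_k
        self.relieff_m = relieff_m
        self.target_bins = target_bins
        self.top_k = top_k
        self.prerank_fraction = prerank_fraction
        self.n_bins = n_bins
        self.seed = seed

    def _config(self) -> SelectionConfig:
        return SelectionConfig(**{k: getattr(self, k)
                                  for k in SelectionConfig.__dataclass_fields__})

    def fit(self, X, y):
        X = self._to_frame(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.result_ = select_features(X, y, self._config(), method="msu-hybrid")
        sel = set(self.result_.fused_rank)
        self.support_ = np.array([c in sel for c in X.columns])
        return self

    @staticmethod
    def _to_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])

    def _get_support_mask(self):
        return self.support_

    def _more_tags(self):
        return {"allow_nan": False, "requires_y": True}


class PearsonCorrelationSelector(SelectorMixin, BaseEstimator):
    """|Pearson r| top-k baseline selector (linear comparison mode)."""

    def __init__(self, top_k: int = 12):
        self.top_k = top_k

    def fit(self, X, y):
        X = HybridFeatureSelector._to_frame(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.ranking_ = pearson_baseline_rank(X, y)
        sel = {c for c, _ in self.ranking_[:self.top_k]}
        self.support_ = np.array([c in sel for c in X.columns])
        return self

    def _get_support_mask(self):
        return self.support_

    def _more_tags(self):
        return {"allow_nan": False, "requires_y": True}
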
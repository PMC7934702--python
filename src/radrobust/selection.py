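"""Redundancy clustering and univariate informativeness selection.

Features are grouped by Spearman rank correlation with average-linkage
hierarchical clustering on the distance ``1 - |rho|`` (anti-correlated
features carry the same information, so the absolute correlation is used);
the tree is cut so that features correlated above the threshold (default
0.85) land in one cluster.  Each cluster is then represented by its highest-
AUC feature, and only representatives whose two-group AUC exceeds the minimum
(default 0.7) survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu, spearmanr

from .tables import SchemaError, feature_columns

__all__ = [
    "ClusterAssignment",
    "AucResult",
    "spearman_matrix",
    "cluster_features",
    "univariate_auc",
    "auc_table",
    "select_representatives",
]

logger = logging.getLogger(__name__)

DEFAULT_CORR_THRESHOLD = 0.85
DEFAULT_MIN_AUC = 0.7


@dataclass(frozen=True)
class ClusterAssignment:
    """Feature -> cluster id map plus the linkage record that produced it."""

    labels: dict[str, int]
    linkage_matrix: np.ndarray | None = None

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for name, cid in self.labels.items():
            out.setdefault(cid, []).append(name)
        return out


@dataclass(frozen=True)
class AucResult:
    feature: str
    auc: float  # orientation-free, in [0.5, 1]
    ci_low: float | None = None
    ci_high: float | None = None


def spearman_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Feature-by-feature Spearman rank correlation matrix.

    Annotation columns are dropped; ties get average ranks (scipy).  A
    constant feature has no defined rank correlation — its off-diagonal
    entries are set to 0 and a warning is logged, so it ends up alone in its
    own cluster rather than aborting the run.
    """
    features = feature_columns(table)
    if len(features) < 2:
        raise ValueError(f"need at least 2 features, got {features}")
    data = table[features].to_numpy(dtype=float)
    if data.shape[0] < 3:
        raise ValueError(f"need at least 3 samples, got {data.shape[0]}")
    import warnings

    with warnings.catch_warnings():
        # constant columns are handled explicitly below
        warnings.simplefilter("ignore")
        rho = spearmanr(data).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-feature case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    constant = data.std(axis=0) == 0
    if constant.any():
        names = [f for f, c in zip(features, constant) if c]
        logger.warning("constant feature(s) %s: undefined correlations treated as 0", names)
        rho[constant, :] = 0.0
        rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=features, columns=features)


def cluster_features(
    corr: pd.DataFrame, threshold: float = DEFAULT_CORR_THRESHOLD
) -> ClusterAssignment:
    """Average-linkage hierarchical clustering on distance ``1 - |rho|``.

    The dendrogram is cut at distance ``1 - threshold``, so feature pairs
    with ``|rho| > threshold`` are merged into one cluster.
    """
    features = list(corr.columns)
    if len(features) == 1:
        return ClusterAssignment({features[0]: 1})
    dist = 1.0 - np.abs(corr.to_numpy(dtype=float))
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(np.clip(dist, 0.0, None), checks=False)
    link = linkage(condensed, method="average")
    ids = fcluster(link, t=1.0 - threshold, criterion="distance")
    return ClusterAssignment(dict(zip(features, (int(i) for i in ids))), link)


def univariate_auc(
    values: Sequence[float],
    labels: Sequence,
    ci: bool = False,
    n_boot: int = 2000,
    seed: int = 0,
    name: str = "feature",
) -> AucResult:
    """Orientation-free two-group AUC from the Mann-Whitney U statistic.

    ``A = U / (n1 * n2)`` with ties counted one half; since no positive class
    is designated the reported AUC is ``max(A, 1 - A)`` and lies in [0.5, 1].
    The optional CI is a percentile bootstrap over samples (within groups).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"labels must contain exactly 2 non-empty groups, got {list(levels)}")
    a = values[labels == levels[0]]
    b = values[labels == levels[1]]

    def _auc(x, y):
        u = mannwhitneyu(x, y, alternative="two-sided").statistic
        frac = u / (len(x) * len(y))
        return max(frac, 1.0 - frac)

    auc = float(_auc(a, b))
    lo = hi = None
    if ci:
        rng = np.random.default_rng(seed)
        boot = np.empty(n_boot)
        for i in range(n_boot):
            boot[i] = _auc(rng.choice(a, len(a)), rng.choice(b, len(b)))
        lo, hi = (float(q) for q in np.quantile(boot, [0.025, 0.975]))
    return AucResult(name, auc, lo, hi)


def auc_table(
    table: pd.DataFrame, label_col: str = "group", ci: bool = False, seed: int = 0
) -> list[AucResult]:
    """Univariate AUC of every feature column against a binary label column."""
    if label_col not in table.columns:
        raise SchemaError(f"label column {label_col!r} not found")
    labels = table[label_col].to_numpy()
    return [
        univariate_auc(table[f].to_numpy(), labels, ci=ci, seed=seed, name=f)
        for f in feature_columns(table)
    ]


def select_representatives(
    clusters: ClusterAssignment,
    aucs: Sequence[AucResult] | Mapping[str, float],
    min_auc: float = DEFAULT_MIN_AUC,
) -> list[str]:
    """Best feature per cluster, kept only if its AUC exceeds ``min_auc``.

    Ties on AUC break lexicographically by feature name; the result is sorted
    by descending AUC then name.
    """
    if not isinstance(aucs, Mapping):
        aucs = {r.feature: r.auc for r in aucs}
    missing = [f for f in clusters.labels if f not in aucs]
    if missing:
        raise SchemaError(f"clustered feature(s) without an AUC: {missing}")
    selected = []
    for _, members in sorted(clusters.clusters().items()):
        best = min(members, key=lambda f: (-aucs[f], f))
        if aucs[best] > min_auc:
            selected.append(best)
    return sorted(selected, key=lambda f: (-aucs[f], f))
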
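"""Biological-vs-noise signal robustness testing for radiomics features.

For a feature, the *biological signal* (BS) is the set of absolute
cross-group pairwise differences between the two patient groups
(``|x_r - x_s|`` over every wildtype/mutant pair, so ``n_r * n_s`` values).
The *noise signal* for a pair of scan conditions (i, j) is the set of
per-lesion absolute differences of the feature measured on the same phantom
lesions under the two conditions (``n_p`` values).  Both are normalised by
the single constant ``mu_BS + sigma_BS`` derived from the biological signal,
and each condition pair's noise distribution is compared with the biological
distribution by a two-sample t-test.  A feature is *robust* at a condition
pair when the distributions differ significantly (p < alpha) **and** the
biological signal mean exceeds the noise mean — significance with the noise
above the biology must not count as robustness.

:class:`RobustnessModel` packages the procedure statsmodels-style: build it
from a cohort table and a phantom table, call :meth:`~RobustnessModel.fit`,
and read the per-condition-pair grids, aggregates and ``summary()`` off the
returned :class:`RobustnessResults`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import SchemaError, feature_columns, validate_feature_table

__all__ = [
    "SignalSet",
    "ComparisonResult",
    "RobustnessMatrix",
    "biological_signal",
    "noise_signal",
    "normalize_signals",
    "compare_signals",
    "robustness_matrix",
    "aggregate_robustness",
    "RobustnessModel",
    "RobustnessResults",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class SignalSet:
    """A set of non-negative absolute feature differences with its moments.

    ``kind`` is "biological" (cross-group pairs) or "noise" (per-lesion
    cross-condition pairs); ``provenance`` records the group or condition
    pair.  ``ddof=0`` gives population moments (the default convention
    throughout the package); ``ddof=1`` the sample convention.
    """

    kind: str
    values: np.ndarray
    provenance: tuple[str, str]
    ddof: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        if values.size == 0:
            raise ValueError("signal set must be non-empty")
        if np.any(values < 0) or np.any(~np.isfinite(values)):
            raise ValueError("signal values must be finite and non-negative")
        object.__setattr__(self, "values", values)

    @property
    def mu(self) -> float:
        return float(self.values.mean())

    @property
    def sigma(self) -> float:
        return float(self.values.std(ddof=self.ddof))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ComparisonResult:
    t: float
    p: float
    robust: bool


@dataclass(frozen=True)
class RobustnessMatrix:
    """Per-feature grid of noise-vs-biology comparisons over condition pairs."""

    feature: str
    mean_bs: float  # mean normalised biological signal
    cells: pd.DataFrame  # one row per unordered condition pair (i, j), i > j

    @property
    def n_robust(self) -> int:
        return int(self.cells["robust"].sum())

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def biological_signal(wildtype_values, mutant_values, ddof: int = 0) -> SignalSet:
    """Cross-group absolute pairwise differences (size ``n_r * n_s``)."""
    x = np.asarray(wildtype_values, dtype=float)
    y = np.asarray(mutant_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    diffs = np.abs(x[:, None] - y[None, :]).ravel()
    return SignalSet("biological", diffs, ("wildtype", "mutant"), ddof=ddof)


def noise_signal(
    phantom: pd.DataFrame,
    feature: str,
    condition_i: str,
    condition_j: str,
    ddof: int = 0,
) -> SignalSet:
    """Per-lesion absolute differences between two scan conditions (size ``n_p``).

    Every lesion must be measured under both conditions; a lesion missing
    under either condition is an incomplete design and raises.
    """
    if feature not in phantom.columns:
        raise SchemaError(f"feature {feature!r} not in phantom table")
    sub = phantom[phantom["condition_id"].isin([condition_i, condition_j])]
    wide = sub.pivot(index="lesion_id", columns="condition_id", values=feature)
    for cond in (condition_i, condition_j):
        if cond not in wide.columns:
            raise ValueError(f"incomplete design: no phantom rows for condition {cond!r}")
        if wide[cond].isna().any():
            missing = list(wide.index[wide[cond].isna()])
            raise ValueError(
                f"incomplete design: lesion(s) {missing} missing under condition {cond!r}"
            )
    diffs = np.abs(wide[condition_i].to_numpy() - wide[condition_j].to_numpy())
    return SignalSet("noise", diffs, (condition_i, condition_j), ddof=ddof)


def normalize_signals(
    bs: SignalSet, ns_sets: Sequence[SignalSet]
) -> tuple[SignalSet, list[SignalSet]]:
    """Divide the BS and every NS by the one constant ``mu_BS + sigma_BS``.

    All noise sets are scaled by the biological-signal constant (not their
    own moments), so normalised noise means are directly comparable with the
    normalised biological mean ``mu_BS / (mu_BS + sigma_BS)``.
    """
    denom = bs.mu + bs.sigma
    if denom <= 0:
        raise ValueError("degenerate biological signal: mu + sigma is zero (all differences 0)")
    bs_norm = replace(bs, values=bs.values / denom)
    ns_norm = [replace(ns, values=ns.values / denom) for ns in ns_sets]
    return bs_norm, ns_norm


def compare_signals(
    bs_norm: SignalSet,
    ns_norm: SignalSet,
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = True,
) -> ComparisonResult:
    """Two-sided two-sample t-test of noise vs biology, plus the robust flag.

    Pooled-variance by default (``equal_var=False`` gives Welch).  Robust
    means p < alpha *and* mean(BS) > mean(NS).  If both sets have zero
    variance the t-test is undefined; p is then defined as 1 when the means
    are equal and 0 otherwise (logged as degenerate).
    """
    a, b = bs_norm.values, ns_norm.values
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each signal set needs at least 2 values for the t-test")
    if a.std() == 0 and b.std() == 0:
        logger.warning("degenerate t-test: both signal sets have zero variance")
        p = 1.0 if a.mean() == b.mean() else 0.0
        t = 0.0 if p == 1.0 else np.inf * np.sign(a.mean() - b.mean())
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
    return ComparisonResult(t, p, robust=bool(p < alpha and a.mean() > b.mean()))


def condition_pairs(condition_ids: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered condition pairs (later vs earlier), ``n_c(n_c-1)/2`` of them."""
    return [(b, a) for a, b in itertools.combinations(condition_ids, 2)]


def robustness_matrix(
    feature: str,
    cohort: pd.DataFrame,
    phantom: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    ddof: int = 0,
    equal_var: bool = True,
    p_adjust: str | None = None,
) -> RobustnessMatrix:
    """Full per-feature robustness grid over every unordered condition pair.

    The biological signal is built once from the cohort's two groups; each of
    the ``n_c(n_c-1)/2`` condition pairs contributes one noise set and one
    t-test.  ``p_adjust`` ("bonferroni" or "fdr_bh") optionally corrects the
    per-pair p-values across the grid; off by default, matching a per-pair
    alpha reading.
    """
    if feature not in cohort.columns:
        raise SchemaError(f"feature {feature!r} not in cohort table")
    groups = cohort["group"].to_numpy()
    bs = biological_signal(
        cohort.loc[groups == "wildtype", feature].to_numpy(),
        cohort.loc[groups == "mutant", feature].to_numpy(),
        ddof=ddof,
    )
    conditions = list(pd.unique(phantom["condition_id"]))
    if len(conditions) < 2:
        raise ValueError(f"phantom table must contain >= 2 conditions, got {conditions}")
    pairs = condition_pairs(conditions)
    ns_sets = [noise_signal(phantom, feature, i, j, ddof=ddof) for i, j in pairs]
    bs_norm, ns_norm = normalize_signals(bs, ns_sets)
    rows = []
    for (cond_i, cond_j), ns in zip(pairs, ns_norm):
        cmp = compare_signals(bs_norm, ns, alpha=alpha, equal_var=equal_var)
        rows.append(
            {
                "condition_i": cond_i,
                "condition_j": cond_j,
                "mean_ns": ns.mu,
                "t": cmp.t,
                "p": cmp.p,
                "robust": cmp.robust,
            }
        )
    cells = pd.DataFrame(rows)
    if p_adjust is not None:
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests(cells["p"], alpha=alpha, method=p_adjust)
        cells["p"] = p_adj
        cells["robust"] = reject & (bs_norm.mu > cells["mean_ns"].to_numpy())
    return RobustnessMatrix(feature, bs_norm.mu, cells)


def aggregate_robustness(matrix: RobustnessMatrix) -> tuple[bool, float]:
    """Overall call for a feature: robust iff a strict majority of cells are."""
    fraction = matrix.n_robust / matrix.n_cells
    return fraction > 0.5, fraction


class RobustnessModel:
    """Biological-vs-noise robustness assessment of radiomics features.

    Parameters
    ----------
    cohort
        Two-group feature table (``sample_id``, ``group`` in
        {wildtype, mutant}, feature columns).
    phantom
        Lesion-by-condition feature table (``lesion_id``, ``condition_id``,
        feature columns); every lesion must appear under every condition.
    features
        Features to assess; defaults to the features present in both tables.
    alpha
        Per-condition-pair significance level (default 0.05).
    ddof
        0 for population moments in signal-set normalisation (default),
        1 for the sample convention.
    equal_var
        Pooled-variance t-test when True (default), Welch otherwise.
    p_adjust
        Optional multiple-testing correction across a feature's grid
        ("bonferroni", "fdr_bh"); None (off) by default.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        phantom: pd.DataFrame,
        features: Sequence[str] | None = None,
        alpha: float = DEFAULT_ALPHA,
        ddof: int = 0,
        equal_var: bool = True,
        p_adjust: str | None = None,
    ) -> None:
        self.cohort = validate_feature_table(cohort.copy(), "cohort")
        self.phantom = validate_feature_table(phantom.copy(), "phantom")
        if features is None:
            features = [
                f for f in feature_columns(self.cohort) if f in feature_columns(self.phantom)
            ]
            if not features:
                raise SchemaError("cohort and phantom tables share no feature columns")
        else:
            features = list(features)
            for f in features:
                if f not in self.cohort.columns or f not in self.phantom.columns:
                    raise SchemaError(f"feature {f!r} missing from cohort or phantom table")
        self.features = features
        self.alpha = alpha
        self.ddof = ddof
        self.equal_var = equal_var
        self.p_adjust = p_adjust

    @classmethod
    def from_csv(cls, cohort_path: str, phantom_path: str, **kwargs) -> "RobustnessModel":
        from .tables import read_feature_table

        return cls(
            read_feature_table(cohort_path, "cohort"),
            read_feature_table(phantom_path, "phantom"),
            **kwargs,
        )

    def fit(self) -> "RobustnessResults":
        matrices = {
            f: robustness_matrix(
                f,
                self.cohort,
                self.phantom,
                alpha=self.alpha,
                ddof=self.ddof,
                equal_var=self.equal_var,
                p_adjust=self.p_adjust,
            )
            for f in self.features
        }
        return RobustnessResults(self, matrices)


class RobustnessResults:
    """Fitted robustness grids with aggregates, summary table and plotting."""

    def __init__(self, model: RobustnessModel, matrices: dict[str, RobustnessMatrix]):
        self.model = model
        self.matrices = matrices

    def aggregate(self) -> pd.DataFrame:
        """One row per feature: mean normalised BS, robust-cell fraction, call."""
        rows = []
        for name, m in self.matrices.items():
            overall, fraction = aggregate_robustness(m)
            rows.append(
                {
                    "feature": name,
                    "mean_bs": m.mean_bs,
                    "n_cells": m.n_cells,
                    "n_robust": m.n_robust,
                    "fraction_robust": fraction,
                    "robust": overall,
                }
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per (feature, condition pair)."""
        frames = []
        for name, m in self.matrices.items():
            cells = m.cells.copy()
            cells.insert(0, "feature", name)
            cells.insert(1, "mean_bs", m.mean_bs)
            frames.append(cells)
        return pd.concat(frames, ignore_index=True)

    def grid(self, feature: str, value: str = "mean_ns") -> pd.DataFrame:
        """Condition-by-condition grid of a cell quantity for one feature."""
        m = self.matrices[feature]
        conds = list(pd.unique(self.model.phantom["condition_id"]))
        g = pd.DataFrame(np.nan, index=conds, columns=conds)
        for _, row in m.cells.iterrows():
            g.loc[row["condition_i"], row["condition_j"]] = row[value]
            g.loc[row["condition_j"], row["condition_i"]] = row[value]
        return g

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [
            "Radiomics feature robustness: biological vs acquisition-noise signal",
            f"cohort n = {len(self.model.cohort)}; "
            f"phantom lesions x conditions = "
            f"{self.model.phantom['lesion_id'].nunique()} x "
            f"{self.model.phantom['condition_id'].nunique()}; "
            f"alpha = {self.model.alpha}"
            + (f"; p-adjust = {self.model.p_adjust}" if self.model.p_adjust else ""),
            "",
            f"{'feature':<28}{'mean BS':>9}{'robust cells':>14}{'fraction':>10}{'robust':>8}",
            "-" * 69,
        ]
        for _, r in agg.iterrows():
            lines.append(
                f"{r['feature']:<28}{r['mean_bs']:>9.3f}"
                f"{f'{r.n_robust}/{r.n_cells}':>14}{r['fraction_robust']:>10.3f}"
                f"{'yes' if r['robust'] else 'no':>8}"
            )
        return "\n".join(lines)

    def plot_feature(self, feature: str, ax=None):
        """Heatmap of mean normalised noise per condition pair; robust cells hatched."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        g = self.grid(feature, "mean_ns")
        robust = self.grid(feature, "robust")
        im = ax.imshow(g.to_numpy(), cmap="viridis")
        ax.set_xticks(range(len(g.columns)), g.columns, rotation=90)
        ax.set_yticks(range(len(g.index)), g.index)
        for i in range(len(g.index)):
            for j in range(len(g.columns)):
                if i != j and robust.iloc[i, j] == 1.0:
                    ax.text(j, i, "*", ha="center", va="center", color="w")
        m = self.matrices[feature]
        ax.set_title(f"{feature}: mean BS = {m.mean_bs:.3f} (* = robust pair)")
        ax.figure.colorbar(im, ax=ax, label="mean normalised noise signal")
        return ax
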
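"""Test-retest reproducibility screening with Lin's concordance correlation.

Lin's CCC measures agreement between paired measurements by combining their
correlation with how far the pairs sit from the identity line:

    ccc = 2 * s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)

with population (1/n) moment estimates, Lin's original convention.  Features
whose test-retest CCC falls below the threshold (default 0.85) are screened
out before any downstream selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import SchemaError, feature_columns

__all__ = ["CccResult", "concordance_correlation", "screen_reproducible"]

DEFAULT_CCC_THRESHOLD = 0.85


@dataclass(frozen=True)
class CccResult:
    feature: str
    ccc: float
    kept: bool


def concordance_correlation(x, y) -> float:
    """Lin's concordance correlation coefficient between paired measurements.

    Uses 1/n moment estimates.  Undefined (raises) when both inputs are
    constant, since neither correlation nor scale accuracy is then defined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise SchemaError(f"paired inputs differ in length: {x.shape} vs {y.shape}")
    if x.ndim != 1 or len(x) < 2:
        raise ValueError(f"need at least 2 paired values, got shape {x.shape}")
    var_x = np.var(x)
    var_y = np.var(y)
    if var_x == 0 and var_y == 0:
        raise ValueError("CCC undefined: both inputs are constant")
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2.0 * cov / (var_x + var_y + (x.mean() - y.mean()) ** 2))


def screen_reproducible(
    test: pd.DataFrame,
    retest: pd.DataFrame,
    threshold: float = DEFAULT_CCC_THRESHOLD,
) -> list[CccResult]:
    """Per-feature CCC between a test table and its retest replicate.

    Rows are matched on ``sample_id`` when present (order-insensitive),
    otherwise positionally.  A feature is kept iff its CCC is at least the
    threshold (the screen excludes features with CCC *smaller than* the
    threshold).
    """
    features = feature_columns(test)
    if features != feature_columns(retest):
        raise SchemaError(
            f"feature columns differ: {features} vs {feature_columns(retest)}"
        )
    if "sample_id" in test.columns and "sample_id" in retest.columns:
        if set(test["sample_id"]) != set(retest["sample_id"]):
            raise SchemaError("test and retest tables contain different sample_ids")
        test = test.set_index("sample_id")
        retest = retest.set_index("sample_id").reindex(test.index)
    elif len(test) != len(retest):
        raise SchemaError(f"row counts differ: {len(test)} vs {len(retest)}")
    results = []
    for name in features:
        ccc = concordance_correlation(test[name].to_numpy(), retest[name].to_numpy())
        results.append(CccResult(name, ccc, kept=ccc >= threshold))
    return results
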
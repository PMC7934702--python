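"""End-to-end orchestration: simulate -> screen -> select -> assess robustness.

The default configuration plants a small, fully-known ground truth that
mirrors the structure of a delta-radiomics study: a 20/26 two-group cohort,
a test-retest replicate with per-feature reliability targets, and a
24-lesion x 8-condition phantom table whose per-condition noise scale grows
as the effective mAs drops.  Size- and boundary-style features are planted
with strong group effects and small acquisition noise; one texture-energy
feature is planted with acquisition noise on the scale of its biological
signal, so the pipeline should keep it through screening and selection but
flag it as non-robust.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .reproducibility import screen_reproducible
from .robustness import RobustnessModel
from .selection import auc_table, cluster_features, select_representatives, spearman_matrix
from .synthetic import (
    CohortConfig,
    FeatureSpec,
    default_scan_conditions,
    generate_cohort_table,
    generate_phantom_table,
    generate_retest_table,
)
from .tables import feature_columns, write_feature_table

__all__ = ["default_config", "run_pipeline"]

logger = logging.getLogger(__name__)

# Planted ground truth for the default synthetic study.  Columns are named
# after the style of delta feature they emulate; values are in arbitrary
# delta-feature units with unit within-group spread.
_DEFAULT_CONFIG = {
    "cohort": {
        "n_wildtype": 20,
        "n_mutant": 26,
        "features": {
            # size-style: strong effect, tiny acquisition noise
            "delta_volume": {"mean_wildtype": 0.0, "mean_mutant": 2.0, "sd": 1.0},
            # redundant size-style twin (same cluster as delta_volume)
            "delta_tumor_mass": {"duplicate_of": "delta_volume", "duplicate_noise_sd": 0.3},
            # boundary-style: clear effect, small noise
            "delta_sigmoid_offset": {"mean_wildtype": 0.0, "mean_mutant": 1.6, "sd": 1.0},
            # texture-style: effect present, moderate noise
            "delta_gabor_energy": {"mean_wildtype": 0.0, "mean_mutant": 1.5, "sd": 1.0},
            # texture-energy-style: effect present but acquisition noise dominates
            "delta_dwt_energy": {"mean_wildtype": 0.0, "mean_mutant": 1.4, "sd": 1.0},
            # uninformative shape-style feature (fails the AUC gate)
            "delta_compactness": {"mean_wildtype": 0.0, "mean_mutant": 0.0, "sd": 1.0},
            # informative but unreliable feature (fails the CCC screen)
            "delta_skewness": {"mean_wildtype": 0.0, "mean_mutant": 1.5, "sd": 1.0},
        },
    },
    "retest": {
        "target_ccc": {
            "delta_volume": 0.97,
            "delta_tumor_mass": 0.97,
            "delta_sigmoid_offset": 0.96,
            "delta_gabor_energy": 0.95,
            "delta_dwt_energy": 0.95,
            "delta_compactness": 0.95,
            "delta_skewness": 0.3,
        }
    },
    "phantom": {
        "n_lesions": 24,
        "base_sd": 1.0,  # spread of per-lesion base values
        # per-feature acquisition-noise scale at the reference (highest) mAs;
        # the per-condition scale is this times sqrt(mas_ref / mas)
        "noise_scale": {
            "delta_volume": 0.05,
            "delta_tumor_mass": 0.05,
            "delta_sigmoid_offset": 0.08,
            "delta_gabor_energy": 0.15,
            "delta_dwt_energy": 1.5,
            "delta_compactness": 0.1,
            "delta_skewness": 0.5,
        },
    },
    "screen": {"ccc_threshold": 0.85},
    "select": {"corr_threshold": 0.85, "min_auc": 0.7},
    "robustness": {"alpha": 0.05, "ddof": 0, "equal_var": True, "p_adjust": None},
}


def default_config() -> dict:
    """A deep copy of the default synthetic-study configuration."""
    return copy.deepcopy(_DEFAULT_CONFIG)


def _build_tables(config: Mapping, seed: int):
    cohort_cfg = config["cohort"]
    specs = {name: FeatureSpec(**kw) for name, kw in cohort_cfg["features"].items()}
    cohort = generate_cohort_table(
        CohortConfig(cohort_cfg["n_wildtype"], cohort_cfg["n_mutant"], specs, seed=seed)
    )
    retest = generate_retest_table(cohort, config["retest"]["target_ccc"], seed=seed + 1)

    phantom_cfg = config["phantom"]
    conditions = default_scan_conditions()
    features = list(cohort_cfg["features"])
    rng = np.random.default_rng(seed + 2)
    base = pd.DataFrame(
        rng.normal(0.0, phantom_cfg["base_sd"], size=(phantom_cfg["n_lesions"], len(features))),
        columns=features,
    )
    mas = np.array([c.effective_mas for c in conditions])
    per_condition = np.sqrt(mas.max() / mas)  # noise grows as dose drops
    noise = {
        f: per_condition * phantom_cfg["noise_scale"][f] for f in features
    }
    phantom = generate_phantom_table(
        phantom_cfg["n_lesions"], conditions, base, noise, seed=seed + 3
    )
    return cohort, retest, phantom


def run_pipeline(
    config: Mapping | None = None, seed: int = 0, out_dir: str | None = None
) -> dict:
    """Run screen -> select -> robustness on synthetic (or provided) tables.

    ``config`` defaults to :func:`default_config`.  Returns a JSON-serialisable
    report with the CCC screen, the cluster assignment, per-feature AUCs, the
    selected representatives and each selected feature's robustness grid and
    aggregate call.  With ``out_dir`` the report (JSON) and all intermediate
    tables (CSV) are written there; reruns with the same config and seed are
    byte-identical.
    """
    if config is None:
        config = default_config()
    cohort, retest, phantom = _build_tables(config, seed)

    ccc_results = screen_reproducible(
        cohort, retest, threshold=config["screen"]["ccc_threshold"]
    )
    kept = [r.feature for r in ccc_results if r.kept]
    if not kept:
        raise ValueError("no feature survived the reproducibility screen")

    reduced = cohort[["sample_id", "group"] + kept]
    if len(kept) > 1:
        corr = spearman_matrix(reduced)
        clusters = cluster_features(corr, threshold=config["select"]["corr_threshold"])
    else:
        from .selection import ClusterAssignment

        clusters = ClusterAssignment({kept[0]: 1})
    aucs = auc_table(reduced)
    selected = select_representatives(clusters, aucs, min_auc=config["select"]["min_auc"])

    report = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "ccc": {r.feature: {"ccc": r.ccc, "kept": r.kept} for r in ccc_results},
        "clusters": clusters.labels,
        "auc": {r.feature: r.auc for r in aucs},
        "selected": selected,
        "robustness": {},
    }
    if selected:
        model = RobustnessModel(
            cohort, phantom, features=selected, **config["robustness"]
        )
        results = model.fit()
        for name, matrix in results.matrices.items():
            overall = results.aggregate().set_index("feature").loc[name]
            report["robustness"][name] = {
                "mean_bs": matrix.mean_bs,
                "n_cells": matrix.n_cells,
                "n_robust": matrix.n_robust,
                "fraction_robust": float(overall["fraction_robust"]),
                "robust": bool(overall["robust"]),
                "cells": matrix.cells.to_dict(orient="records"),
            }
    logger.info(
        "pipeline: %d features -> %d reproducible -> %d selected (%d robust); seed=%d",
        len(feature_columns(cohort)),
        len(kept),
        len(selected),
        sum(1 for f in report["robustness"].values() if f["robust"]),
        seed,
    )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_feature_table(cohort, os.path.join(out_dir, "cohort.csv"))
        write_feature_table(retest, os.path.join(out_dir, "retest.csv"))
        write_feature_table(phantom, os.path.join(out_dir, "phantom.csv"))
        if selected:
            results.to_frame().to_csv(os.path.join(out_dir, "robustness.csv"), index=False)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
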
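"""Synthetic phantom lesions, scan conditions and tabular feature generators.

The phantom emulates a thoracic lesion insert set: a factorial of two
volume-equivalent sphere diameters (10 and 20 mm), four shapes (spherical,
elliptical, lobular, spiculated) and three densities (-630, -10, +100 HU)
embedded in lung-parenchyma background (-850 HU).  Lesions are rendered in
isolation on a regular grid; acquisition effects are modelled as additive
Gaussian noise whose standard deviation scales as 1/sqrt(effective mAs),
followed by a small scanner-specific Gaussian blur standing in for
reconstruction-kernel differences.

Tabular generators produce cohort (two-group), test-retest and
lesion-by-condition feature tables with known ground truth, so the screening
and robustness stages can be exercised end to end without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import CtVolume, LesionMask

__all__ = [
    "LesionSpec",
    "ScanCondition",
    "NoiseModel",
    "CohortConfig",
    "FeatureSpec",
    "SHAPES",
    "default_lesion_specs",
    "default_scan_conditions",
    "generate_phantom_lesions",
    "apply_scan_condition",
    "generate_cohort_table",
    "generate_retest_table",
    "generate_phantom_table",
]

SHAPES = ("spherical", "elliptical", "lobular", "spiculated")

#: default factorial: 2 sizes x 4 shapes x 3 densities = 24 lesions
DEFAULT_DIAMETERS_MM = (10.0, 20.0)
DEFAULT_DENSITIES_HU = (-630.0, -10.0, 100.0)
DEFAULT_BACKGROUND_HU = -850.0

#: in-plane 0.7 mm, slice 1.25 mm, as (z, y, x)
DEFAULT_SPACING = (1.25, 0.7, 0.7)


@dataclass(frozen=True)
class LesionSpec:
    """One phantom lesion: volume-equivalent sphere diameter, shape, density."""

    effective_diameter: float  # mm
    shape: str
    density: float  # HU

    def __post_init__(self) -> None:
        if self.effective_diameter <= 0:
            raise ValueError(f"invalid lesion spec: effective_diameter must be > 0, got {self.effective_diameter}")
        if self.shape not in SHAPES:
            raise ValueError(f"invalid lesion spec: unknown shape {self.shape!r}; expected one of {SHAPES}")
        if not -1000.0 <= self.density <= 3000.0:
            raise ValueError(f"invalid lesion spec: density {self.density} HU outside [-1000, 3000]")


@dataclass(frozen=True)
class ScanCondition:
    """One acquisition setting: scanner plus tube current and exposure time.

    The effective mAs (current x exposure time) is proportional to the x-ray
    output and is what the noise model keys on.
    """

    scanner_id: str
    tube_current: float  # mA
    exposure_time: float  # s

    def __post_init__(self) -> None:
        if self.tube_current <= 0:
            raise ValueError(f"invalid condition: tube_current must be > 0, got {self.tube_current}")
        if self.exposure_time <= 0:
            raise ValueError(f"invalid condition: exposure_time must be > 0, got {self.exposure_time}")

    @property
    def effective_mas(self) -> float:
        return self.tube_current * self.exposure_time

    @property
    def condition_id(self) -> str:
        return f"{self.scanner_id}-{self.tube_current:g}mA"


def default_scan_conditions() -> list[ScanCondition]:
    """The 8 default conditions: two scanners at four tube currents each.

    Scanner #1 runs 395/195/100/50 mA at 0.7 s exposure; scanner #2 runs
    480/260/130/65 mA at 0.5 s, chosen so the effective mAs levels roughly
    match across scanners.
    """
    conditions = [ScanCondition("scanner1", ma, 0.7) for ma in (395, 195, 100, 50)]
    conditions += [ScanCondition("scanner2", ma, 0.5) for ma in (480, 260, 130, 65)]
    return conditions


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition noise law: sigma = sigma_ref * sqrt(mas_ref / effective_mas).

    ``blur_mm`` maps scanner_id to the standard deviation (mm) of an extra
    Gaussian blur applied after the noise; it stands in for scanner-specific
    reconstruction-kernel differences.
    """

    sigma_ref: float = 20.0  # HU at mas_ref
    mas_ref: float = 276.5  # highest scanner1 effective mAs (395 mA x 0.7 s)
    blur_mm: Mapping[str, float] = field(
        default_factory=lambda: {"scanner1": 0.0, "scanner2": 0.4}
    )

    def sigma(self, effective_mas: float) -> float:
        if effective_mas <= 0:
            raise ValueError(f"invalid condition: effective mAs must be > 0, got {effective_mas}")
        return self.sigma_ref * np.sqrt(self.mas_ref / effective_mas)


def default_lesion_specs() -> list[LesionSpec]:
    """The default 2 x 4 x 3 factorial of lesion specs (24 lesions)."""
    return [
        LesionSpec(d, shape, hu)
        for d in DEFAULT_DIAMETERS_MM
        for shape in SHAPES
        for hu in DEFAULT_DENSITIES_HU
    ]


# --- shape geometry -------------------------------------------------------
#
# Each shape is a star-convex surface r(u) = R0 * g(u) over unit directions u.
# R0 is normalised so the enclosed volume (1/3 * mean(g^3) * 4*pi * R0^3 ... )
# equals the volume-equivalent sphere of the requested effective diameter.

# fixed, deterministic bump/spike directions (Fibonacci sphere points)
def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.cos(phi), np.sin(phi) * np.sin(theta), np.sin(phi) * np.cos(theta)], axis=1
    )  # (z, y, x) components


_LOBULE_DIRS = _fibonacci_directions(4)
_LOBULE_AMPLITUDE = 0.22
_LOBULE_WIDTH = 0.65  # radians

_SPIKE_DIRS = _fibonacci_directions(12)
_SPIKE_AMPLITUDE = 0.7
_SPIKE_WIDTH = 0.12  # radians

# ellipsoid axis ratios (z, y, x), volume-normalised at render time
_ELLIPSE_RATIOS = np.array([0.5, 0.7, 1.0])


def _shape_factor(shape: str, dirs: np.ndarray) -> np.ndarray:
    """Radial shape factor g(u) for unit directions ``dirs`` (n x 3, zyx)."""
    if shape == "spherical":
        return np.ones(len(dirs))
    if shape == "elliptical":
        scaled = dirs / _ELLIPSE_RATIOS
        return 1.0 / np.linalg.norm(scaled, axis=1)
    if shape in ("lobular", "spiculated"):
        if shape == "lobular":
            centers, amp, width = _LOBULE_DIRS, _LOBULE_AMPLITUDE, _LOBULE_WIDTH
        else:
            centers, amp, width = _SPIKE_DIRS, _SPIKE_AMPLITUDE, _SPIKE_WIDTH
        cosang = np.clip(dirs @ centers.T, -1.0, 1.0)
        ang = np.arccos(cosang)
        return 1.0 + amp * np.exp(-((ang / width) ** 2)).sum(axis=1)
    raise ValueError(f"unknown shape {shape!r}")


def _volume_normalised_radius(spec: LesionSpec) -> float:
    """Base radius R0 such that the star-convex body matches the spec volume."""
    quad = _fibonacci_directions(4096)
    g3 = _shape_factor(spec.shape, quad) ** 3
    return (spec.effective_diameter / 2.0) / float(np.mean(g3)) ** (1.0 / 3.0)


def _render_lesion(
    spec: LesionSpec, spacing: tuple[float, float, float], background_hu: float
) -> tuple[CtVolume, LesionMask]:
    r0 = _volume_normalised_radius(spec)
    max_r = r0 * float(_shape_factor(spec.shape, _fibonacci_directions(512)).max())
    half_extent = max_r + 3.0  # mm margin
    shape = tuple(2 * int(np.ceil(half_extent / s)) + 1 for s in spacing)
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([zz, yy, xx], axis=-1)
    rho = np.linalg.norm(coords, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = coords / rho[..., None]
    dirs[rho == 0] = [0.0, 0.0, 1.0]
    g = _shape_factor(spec.shape, dirs.reshape(-1, 3)).reshape(shape)
    mask = rho <= r0 * g
    values = np.where(mask, spec.density, background_hu)
    return CtVolume(values, spacing), LesionMask(mask, spacing)


def generate_phantom_lesions(
    grid_spacing: tuple[float, float, float] = DEFAULT_SPACING,
    specs: Sequence[LesionSpec] | None = None,
    background_hu: float = DEFAULT_BACKGROUND_HU,
) -> list[tuple[LesionSpec, CtVolume, LesionMask]]:
    """Render noise-free lesion volumes and masks, one per spec.

    ``specs=None`` expands to the default 24-lesion factorial.  Each lesion is
    rendered in isolation: lesion voxels take the spec density and everything
    else the background HU.  The mask volume is normalised to the
    volume-equivalent sphere of the spec's effective diameter (to within
    voxelisation error).
    """
    if any(s <= 0 for s in grid_spacing):
        raise ValueError(f"grid spacing must be positive on all axes, got {grid_spacing}")
    if specs is None:
        specs = default_lesion_specs()
    out = []
    for spec in specs:
        if not isinstance(spec, LesionSpec):
            spec = LesionSpec(*spec)
        volume, mask = _render_lesion(spec, tuple(grid_spacing), background_hu)
        out.append((spec, volume, mask))
    return out


def apply_scan_condition(
    volume: CtVolume,
    condition: ScanCondition,
    noise_model: NoiseModel | None = None,
    seed: int = 0,
) -> CtVolume:
    """Simulate acquiring ``volume`` under ``condition``.

    Adds zero-mean Gaussian noise with std sigma_ref*sqrt(mas_ref/mAs), then a
    scanner-specific Gaussian blur. Deterministic given the seed.
    """
    if noise_model is None:
        noise_model = NoiseModel()
    sigma = noise_model.sigma(condition.effective_mas)
    values = volume.values
    if sigma > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, sigma, size=values.shape)
    blur = float(noise_model.blur_mm.get(condition.scanner_id, 0.0))
    if blur > 0:
        values = ndimage.gaussian_filter(values, sigma=[blur / s for s in volume.spacing])
    elif sigma == 0:
        values = values.copy()
    return CtVolume(values, volume.spacing)


# --- tabular generators ---------------------------------------------------


@dataclass(frozen=True)
class FeatureSpec:
    """Ground truth for one cohort feature.

    ``duplicate_of`` makes the feature a noisy copy of an earlier one (for
    planting redundant features); the group means/sd are then ignored except
    for ``duplicate_noise_sd``.
    """

    mean_wildtype: float = 0.0
    mean_mutant: float = 0.0
    sd: float = 1.0
    family: str = "gaussian"
    duplicate_of: str | None = None
    duplicate_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.duplicate_of is None and self.sd <= 0:
            raise ValueError(f"invalid feature spec: sd must be > 0, got {self.sd}")
        if self.family not in ("gaussian", "lognormal"):
            raise ValueError(f"invalid feature spec: unknown family {self.family!r}")


@dataclass(frozen=True)
class CohortConfig:
    """Two-group cohort layout: group sizes and per-feature ground truth."""

    n_wildtype: int = 20
    n_mutant: int = 26
    feature_specs: Mapping[str, FeatureSpec] = field(
        default_factory=lambda: {"feature": FeatureSpec(0.0, 1.0, 1.0)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wildtype < 1 or self.n_mutant < 1:
            raise ValueError(
                f"invalid config: group sizes must be >= 1, got "
                f"{self.n_wildtype} wildtype / {self.n_mutant} mutant"
            )
        if not self.feature_specs:
            raise ValueError("invalid config: at least one feature spec required")


def generate_cohort_table(config: CohortConfig) -> pd.DataFrame:
    """Draw a two-group cohort feature table with known per-feature effects.

    Returns one row per subject with ``sample_id`` and ``group`` annotations
    followed by the feature columns.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_wildtype + config.n_mutant
    groups = ["wildtype"] * config.n_wildtype + ["mutant"] * config.n_mutant
    table = pd.DataFrame(
        {
            "sample_id": [f"subject_{i+1:03d}" for i in range(n)],
            "group": groups,
        }
    )
    for name, spec in config.feature_specs.items():
        if spec.duplicate_of is not None:
            if spec.duplicate_of not in table.columns:
                raise ValueError(
                    f"invalid config: feature {name!r} duplicates unknown feature {spec.duplicate_of!r}"
                )
            base = table[spec.duplicate_of].to_numpy()
            table[name] = base + rng.normal(0.0, spec.duplicate_noise_sd, size=n)
            continue
        means = np.where(
            np.asarray(groups) == "wildtype", spec.mean_wildtype, spec.mean_mutant
        )
        draws = rng.normal(means, spec.sd)
        if spec.family == "lognormal":
            draws = np.exp(draws)
        table[name] = draws
    return table


def generate_retest_table(
    base: pd.DataFrame,
    target_ccc: float | Mapping[str, float],
    seed: int = 0,
) -> pd.DataFrame:
    """Build a retest replicate of ``base`` with a controlled expected CCC.

    Adds independent zero-mean Gaussian noise with variance
    ``2 * var(x) * (1 - c) / c`` per feature, which makes the expected
    concordance correlation between base and retest equal to the target ``c``
    (population-moment convention). ``target_ccc`` may be a scalar or a
    per-feature mapping; targets must lie in (0, 1].
    """
    from .tables import feature_columns

    features = feature_columns(base)
    if not isinstance(target_ccc, Mapping):
        target_ccc = {f: float(target_ccc) for f in features}
    rng = np.random.default_rng(seed)
    retest = base.copy()
    for name in features:
        c = float(target_ccc.get(name, 1.0))
        if not 0.0 < c <= 1.0:
            raise ValueError(f"invalid target CCC for {name!r}: {c} not in (0, 1]")
        x = base[name].to_numpy(dtype=float)
        if c == 1.0:
            continue
        var_x = float(np.var(x))  # population moments, matching Lin's CCC
        sigma_e = np.sqrt(2.0 * var_x * (1.0 - c) / c)
        retest[name] = x + rng.normal(0.0, sigma_e, size=len(x))
    return retest


def _as_condition_ids(conditions: Sequence) -> list[str]:
    ids = [c.condition_id if isinstance(c, ScanCondition) else str(c) for c in conditions]
    if len(set(ids)) != len(ids):
        raise ValueError(f"invalid config: duplicate condition ids in {ids}")
    return ids


def generate_phantom_table(
    n_lesions: int,
    conditions: Sequence,
    base_values: pd.DataFrame | np.ndarray | Sequence[float],
    noise_scale,
    seed: int = 0,
) -> pd.DataFrame:
    """Tabular shortcut for phantom features measured under every condition.

    Each lesion has a fixed per-feature base value; the measurement under
    condition ``c`` is base + N(0, noise_scale[c]).  Lesion identity is
    preserved across conditions, so per-lesion cross-condition differences
    recover exactly the injected acquisition noise.

    ``base_values``: (n_lesions x features) DataFrame, or a 1-D sequence for a
    single feature named ``"feature"``.  ``noise_scale``: scalar, per-condition
    sequence, per-feature mapping, or (n_conditions x features) DataFrame.
    Condition-level sub-seeds are derived deterministically from
    ``(seed, condition index)``.
    """
    if n_lesions < 1:
        raise ValueError(f"invalid config: n_lesions must be >= 1, got {n_lesions}")
    if len(conditions) < 2:
        raise ValueError(f"invalid config: at least 2 conditions required, got {len(conditions)}")
    condition_ids = _as_condition_ids(conditions)
    n_c = len(condition_ids)

    if not isinstance(base_values, pd.DataFrame):
        arr = np.asarray(base_values, dtype=float)
        if arr.ndim == 1:
            base_values = pd.DataFrame({"feature": arr})
        else:
            base_values = pd.DataFrame(arr, columns=[f"feature_{i+1}" for i in range(arr.shape[1])])
    if len(base_values) != n_lesions:
        raise ValueError(
            f"invalid config: base_values has {len(base_values)} rows, expected {n_lesions}"
        )
    features = list(base_values.columns)

    # normalise noise_scale to an (n_conditions x n_features) array
    if isinstance(noise_scale, pd.DataFrame):
        scale = noise_scale.reindex(columns=features).to_numpy(dtype=float)
    elif isinstance(noise_scale, Mapping):
        scale = np.column_stack(
            [np.broadcast_to(np.asarray(noise_scale[f], dtype=float), (n_c,)) for f in features]
        )
    else:
        arr = np.asarray(noise_scale, dtype=float)
        if arr.ndim == 0:
            scale = np.full((n_c, len(features)), float(arr))
        else:
            if arr.shape[0] != n_c:
                raise ValueError(
                    f"invalid config: noise_scale length {arr.shape[0]} != {n_c} conditions"
                )
            scale = np.repeat(arr[:, None], len(features), axis=1)
    if scale.shape != (n_c, len(features)) or np.any(scale < 0) or np.any(~np.isfinite(scale)):
        raise ValueError("invalid config: noise_scale must be finite and non-negative")

    rows = []
    base = base_values.to_numpy(dtype=float)
    for k, cid in enumerate(condition_ids):
        rng = np.random.default_rng([seed, k])
        noise = rng.normal(0.0, 1.0, size=base.shape) * scale[k]
        block = pd.DataFrame(base + noise, columns=features)
        block.insert(0, "condition_id", cid)
        block.insert(0, "lesion_id", [f"lesion_{i+1:02d}" for i in range(n_lesions)])
        rows.append(block)
    return pd.concat(rows, ignore_index=True)
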
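"""File formats, run configuration, and fixture generators.

Hair arrays are exchanged as tab-separated tables with columns ``axial_mm``,
``circum_frac``, ``theta_deg`` (one row per hair); run configurations are flat
YAML key-value files whose keys mirror :class:`~cercalsim.model.ModelParams`
and :class:`~cercalsim.geometry.ConeDomain` fields, all defaulting to the
published values.  Fixture generators produce the null and positive-control
point patterns used to validate the statistics: homogeneous Poisson (uniform
per unit area), parent-offspring clustered, and von Mises direction mixtures.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import ConeDomain
from .model import HairConfiguration, ModelParams
from .optimize import sample_positions

__all__ = [
    "ConfigError",
    "DataError",
    "HAIR_COLUMNS",
    "RunConfig",
    "load_config",
    "read_hair_table",
    "write_hair_table",
    "generate_poisson_fixture",
    "generate_clustered_fixture",
    "generate_vonmises_fixture",
]

HAIR_COLUMNS = ["axial_mm", "circum_frac", "theta_deg"]


class ConfigError(ValueError):
    """Invalid run configuration."""


class DataError(ValueError):
    """Invalid hair-table data."""


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration: model + domain parameters plus output and
    analysis options."""

    params: ModelParams
    domain: ConeDomain
    hair_table: str = "hairs.tsv"
    cost_trace: str = "cost_trace.tsv"
    log_level: str = "INFO"
    ripley_min: float = 0.05
    ripley_max: float = 0.75
    ripley_step: float = 0.05
    peak_smooth_bins: int = 3
    peak_prominence_frac: float = 0.05
    cercus_rotation: float = 30.0


_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParams)}
_DOMAIN_KEYS = {f.name for f in dataclasses.fields(ConeDomain)}
_OPTION_KEYS = {
    f.name for f in dataclasses.fields(RunConfig) if f.name not in ("params", "domain")
}


def load_config(path) -> RunConfig:
    """Read a flat YAML config; unknown keys are rejected by name."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a flat key-value mapping")
    unknown = set(raw) - _PARAM_KEYS - _DOMAIN_KEYS - _OPTION_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    try:
        params = ModelParams(**{k: v for k, v in raw.items() if k in _PARAM_KEYS})
        domain = ConeDomain(**{k: v for k, v in raw.items() if k in _DOMAIN_KEYS})
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    options = {k: v for k, v in raw.items() if k in _OPTION_KEYS}
    return RunConfig(params=params, domain=domain, **options)


def write_hair_table(config: HairConfiguration, path) -> None:
    """Write a hair array as TSV; 12 significant digits round-trip exactly at
    the 1e-9 mm/deg level."""
    df = pd.DataFrame(
        {
            "axial_mm": config.axial,
            "circum_frac": config.circum,
            "theta_deg": config.theta,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_hair_table(path, domain: ConeDomain | None = None) -> HairConfiguration:
    """Read and validate a hair table; errors name the offending data row
    (1-based, excluding the header)."""
    if domain is None:
        domain = ConeDomain()
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise DataError(f"cannot read hair table {path}: {exc}") from exc
    missing = [c for c in HAIR_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"hair table missing column(s): {', '.join(missing)}")
    values = {}
    for col in HAIR_COLUMNS:
        v = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(np.isnan(v) != df[col].isna().to_numpy())
        nan = np.flatnonzero(np.isnan(v))
        if bad.size:
            raise DataError(f"row {bad[0] + 1}: non-numeric value in {col}")
        if nan.size:
            raise DataError(f"row {nan[0] + 1}: missing value in {col}")
        values[col] = v
    checks = [
        ("axial_mm", values["axial_mm"], 0.0, domain.axial_length),
        ("circum_frac", values["circum_frac"], -1.0, 1.0),
        ("theta_deg", values["theta_deg"], -180.0, 180.0),
    ]
    for col, v, lo, hi in checks:
        bad = np.flatnonzero((v < lo) | (v > hi))
        if bad.size:
            raise DataError(
                f"row {bad[0] + 1}: {col}={v[bad[0]]!r} outside [{lo}, {hi}]"
            )
    return HairConfiguration(
        domain, values["axial_mm"], values["circum_frac"], values["theta_deg"]
    )


# --- fixtures --------------------------------------------------------------

def generate_poisson_fixture(
    domain: ConeDomain, n: int, rng: np.random.Generator
) -> HairConfiguration:
    """Homogeneous Poisson null pattern: ``n`` points uniform per unit area,
    uniform directions."""
    if n < 0:
        raise ValueError("n must be non-negative")
    u = rng.random((n, 3))
    ax, ci = sample_positions(domain, u[:, 0], u[:, 1])
    th = 180.0 - 360.0 * u[:, 2]
    return HairConfiguration(domain, ax, ci, th)


def generate_clustered_fixture(
    domain: ConeDomain,
    n_parents: int,
    offspring_per_parent: int,
    cluster_sd_mm: float,
    rng: np.random.Generator,
) -> HairConfiguration:
    """Positive control for clustering: uniform parents, each with a tight
    cluster of offspring (isotropic Gaussian displacements of scale
    ``cluster_sd_mm`` in the flattened plane; axial clipped to the domain,
    circumference wrapped).  Total count = n_parents * offspring_per_parent."""
    if n_parents <= 0 or offspring_per_parent <= 0 or cluster_sd_mm < 0:
        raise ValueError("fixture parameters must be positive")
    u = rng.random((n_parents, 2))
    pax, pci = sample_positions(domain, u[:, 0], u[:, 1])
    ax = np.repeat(pax, offspring_per_parent)
    ci = np.repeat(pci, offspring_per_parent)
    n = ax.size
    disp = rng.normal(scale=cluster_sd_mm, size=(n, 2))
    # reflect axial displacements back into the segment (triangle fold) so
    # large cluster scales approach a spatially uniform limit
    L = domain.axial_length
    folded = np.mod(ax + disp[:, 0], 2.0 * L)
    ax = np.where(folded > L, 2.0 * L - folded, folded)
    from .geometry import local_height

    h = local_height(domain, ax)
    ci = ci + disp[:, 1] / (h / 2.0)  # arc-length offset to fraction
    th = 180.0 - 360.0 * rng.random(n)
    return HairConfiguration(domain, ax, ci, th)


def generate_vonmises_fixture(
    domain: ConeDomain,
    n: int,
    modes_deg,
    kappa: float,
    rng: np.random.Generator,
) -> HairConfiguration:
    """Uniform positions with directions drawn from an equal-weight von Mises
    mixture centered at ``modes_deg``; used to validate peak counting."""
    modes = np.atleast_1d(np.asarray(modes_deg, dtype=float))
    if n < 0 or modes.size == 0 or kappa < 0:
        raise ValueError("invalid von Mises fixture parameters")
    u = rng.random((n, 2))
    ax, ci = sample_positions(domain, u[:, 0], u[:, 1])
    which = rng.integers(modes.size, size=n)
    th = np.rad2deg(rng.vonmises(np.deg2rad(modes[which]), kappa, size=n))
    return HairConfiguration(domain, ax, ci, th)
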
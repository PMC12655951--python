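"""Run configuration for feature extraction and statistics.

All tunables of the curve parameterization live in :class:`FeatureConfig`;
statistical options and paths live in :class:`RunConfig`. Both can be loaded
from a YAML mapping whose keys match the dataclass field names.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml


@dataclass
class FeatureConfig:
    """Tunables of contact detection, segmentation and the elastic fit.

    Units are N and mm throughout.

    Attributes
    ----------
    probe_diameter_mm : flat cylindrical probe diameter; pressures are
        force / probe face area (N/mm^2 == MPa).
    contact_threshold_n : force at which full probe-skin contact is declared;
        samples before the first crossing are discarded and the deformation
        axis is re-zeroed there.
    plateau_offset_mm : flesh-penetration averaging starts this far beyond
        the rupture point.
    drop_frac, drop_min_n, drop_window_mm : a yield event (stage 1) is a fall
        of the smoothed force by at least ``max(drop_frac * F, drop_min_n)``
        within the next ``drop_window_mm`` of deformation.
    smooth_window : centered moving-average length (samples) used only inside
        yield detection, never in the elastic fit.
    resid_frac, resid_persist_mm : stage-2 fallback fires at the first index
        where the raw force falls below the fitted elastic line by more than
        ``resid_frac`` of the fitted value, sustained over ``resid_persist_mm``.
    r2_min, min_span_mm : backward expansion of the elastic window keeps
        growing while the window R^2 stays at or above ``r2_min``; the seed
        window spans ``min_span_mm``.
    pred_resid_k, pred_resid_floor_n : second expansion gate — the next
        candidate point is absorbed only if its prediction residual is within
        ``pred_resid_k`` times the current fit RMSE (floored at
        ``pred_resid_floor_n``). Keeps the tangent contact segment out of the
        fit when noise is low.
    aggregate_step_mm : grid spacing of the mean +/- SD aggregate curve.
    """

    probe_diameter_mm: float = 8.1
    contact_threshold_n: float = 0.1
    plateau_offset_mm: float = 1.0
    drop_frac: float = 0.02
    drop_min_n: float = 0.1
    drop_window_mm: float = 0.2
    smooth_window: int = 5
    resid_frac: float = 0.05
    resid_persist_mm: float = 0.05
    r2_min: float = 0.995
    min_span_mm: float = 0.2
    pred_resid_k: float = 3.5
    pred_resid_floor_n: float = 1e-6
    aggregate_step_mm: float = 0.2

    @classmethod
    def from_mapping(cls, mapping: dict[str, Any]) -> "FeatureConfig":
        names = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in mapping.items() if k in names})


@dataclass
class RunConfig:
    """Full pipeline configuration: paths, feature tunables, stats options."""

    features: FeatureConfig = field(default_factory=FeatureConfig)
    adjust: str = "holm"          # Dunn p adjustment: holm | bonferroni | none
    alpha: float = 0.05
    pca_variables: tuple[str, ...] = (
        "Pa_mpa", "Pb_mpa", "Pc_mpa", "Ka_n_per_mm", "Kf",
        "density_g_cm3", "volume_cm3",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(features=FeatureConfig.from_mapping(raw))
        for key in ("adjust", "alpha", "seed"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "pca_variables" in raw:
            cfg.pca_variables = tuple(raw["pca_variables"])
        cfg.__post_init__()
        return cfg
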
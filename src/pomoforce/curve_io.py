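"""Reading, writing and contact preprocessing of force-deformation records.

A penetration test record is a monotone deformation grid (mm) with the
compressive force (N) at each point. Acquisition starts with an approach
phase; full probe-skin contact is declared at a small force threshold
(0.1 N by default) and the deformation axis is re-zeroed there, which is the
axis every downstream feature refers to.

File formats (CSV, UTF-8, header row, columns addressed by name):

* curve file:      ``deformation_mm,force_N[,...]`` (extra columns ignored)
* sample manifest: ``sample_id,genotype,year,curve_file[,probe_diameter_mm]``
* morphology:      ``sample_id,mass_g,height_mm,d1_mm,d2_mm,volume_cm3[,density_g_cm3]``
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContactError, DataError, FormatError

__all__ = [
    "Curve",
    "CurveMeta",
    "Morphology",
    "preprocess_contact",
    "read_curve",
    "write_curve",
    "read_manifest",
    "read_morphology",
    "write_morphology",
]

MIN_CURVE_LEN = 10
_DEPTH_TOL_MM = 0.05


@dataclass
class CurveMeta:
    """Acquisition metadata attached to one penetration-test record."""

    sample_id: str
    genotype: str = ""
    year: int = 0
    probe_diameter_mm: float = 8.1
    contact_threshold_n: float = 0.1
    loading_speed_mm_s: float = 0.05  # metadata only, not used in analysis
    max_depth_mm: float = 5.0
    curve_file: str = ""

    def __post_init__(self) -> None:
        if self.probe_diameter_mm <= 0:
            raise ValueError("probe_diameter_mm must be positive")
        if self.contact_threshold_n <= 0:
            raise ValueError("contact_threshold_n must be positive")


@dataclass
class Curve:
    """A preprocessed force-deformation record.

    ``deformation`` is strictly increasing and starts at 0 (the contact
    point); ``force`` is non-negative and the same length. ``n_raw_rows``
    preserves the row count of the source file before contact trimming.
    """

    deformation: np.ndarray
    force: np.ndarray
    meta: CurveMeta
    n_raw_rows: int = 0

    def __post_init__(self) -> None:
        self.deformation = np.asarray(self.deformation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if not self.n_raw_rows:
            self.n_raw_rows = len(self.deformation)

    def validate(self) -> "Curve":
        d, f = self.deformation, self.force
        if len(d) != len(f):
            raise DataError(f"{self.meta.sample_id}: series lengths differ")
        if len(d) < MIN_CURVE_LEN:
            raise DataError(
                f"{self.meta.sample_id}: only {len(d)} samples after "
                f"preprocessing (need >= {MIN_CURVE_LEN})"
            )
        if not np.all(np.diff(d) > 0):
            raise DataError(f"{self.meta.sample_id}: deformation not strictly increasing")
        if abs(d[0]) > 1e-12:
            raise DataError(f"{self.meta.sample_id}: deformation not re-zeroed at contact")
        if np.any(f < 0):
            raise DataError(f"{self.meta.sample_id}: negative force after preprocessing")
        if d[-1] > self.meta.max_depth_mm + _DEPTH_TOL_MM:
            raise DataError(
                f"{self.meta.sample_id}: max deformation {d[-1]:.3f} mm exceeds "
                f"declared depth {self.meta.max_depth_mm} mm"
            )
        return self

    def __len__(self) -> int:
        return len(self.deformation)


@dataclass
class Morphology:
    """Per-fruit morphological record; density is recomputed from m / V."""

    sample_id: str
    mass_g: float
    height_mm: float
    d1_mm: float
    d2_mm: float
    volume_cm3: float
    density_g_cm3: float = field(default=0.0)

    def __post_init__(self) -> None:
        for name in ("mass_g", "height_mm", "d1_mm", "d2_mm", "volume_cm3"):
            if getattr(self, name) <= 0:
                raise DataError(f"{self.sample_id}: {name} must be positive")
        computed = self.mass_g / self.volume_cm3
        if self.density_g_cm3:
            if abs(self.density_g_cm3 - computed) > 0.01:
                warnings.warn(
                    f"{self.sample_id}: provided density {self.density_g_cm3:.4f} "
                    f"differs from m/V = {computed:.4f} by > 0.01; using m/V",
                    stacklevel=2,
                )
        self.density_g_cm3 = computed


def preprocess_contact(
    raw_deformation: np.ndarray,
    raw_force: np.ndarray,
    threshold: float = 0.1,
    meta: CurveMeta | None = None,
) -> Curve:
    """Trim the approach phase and re-zero deformation at the contact point.

    All samples before the first index where ``force >= threshold`` are
    discarded; the first retained sample defines deformation 0. Forces are
    clipped at 0 from below. Idempotent: a curve already starting at or above
    the threshold is only re-zeroed.

    Raises
    ------
    ContactError
        If the force never reaches the threshold.
    """
    d = np.asarray(raw_deformation, dtype=float)
    f = np.asarray(raw_force, dtype=float)
    if meta is None:
        meta = CurveMeta(sample_id="", contact_threshold_n=threshold)
    above = np.nonzero(f >= threshold)[0]
    if above.size == 0:
        raise ContactError(
            f"{meta.sample_id}: force never reaches contact threshold {threshold} N"
        )
    i0 = above[0]
    curve = Curve(
        deformation=d[i0:] - d[i0],
        force=np.clip(f[i0:], 0.0, None),
        meta=meta,
        n_raw_rows=len(d),
    )
    return curve.validate()


def read_curve(path: str | Path, meta: CurveMeta) -> Curve:
    """Read one curve CSV and apply contact preprocessing.

    Extra columns (e.g. ``time_s``) are ignored; only ``deformation_mm``
    and ``force_N`` are required.
    """
    df = pd.read_csv(path)
    missing = {"deformation_mm", "force_N"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if len(df) < MIN_CURVE_LEN:
        raise DataError(f"{path}: fewer than {MIN_CURVE_LEN} rows")
    return preprocess_contact(
        df["deformation_mm"].to_numpy(),
        df["force_N"].to_numpy(),
        threshold=meta.contact_threshold_n,
        meta=meta,
    )


def write_curve(curve: Curve, path: str | Path) -> None:
    """Write a curve as ``deformation_mm,force_N`` CSV (full float precision)."""
    pd.DataFrame(
        {"deformation_mm": curve.deformation, "force_N": curve.force}
    ).to_csv(path, index=False, float_format="%.12g")


def read_manifest(path: str | Path) -> list[CurveMeta]:
    """Read the sample manifest; one :class:`CurveMeta` per row."""
    df = pd.read_csv(path)
    required = {"sample_id", "genotype", "year", "curve_file"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise DataError(f"{path}: empty manifest")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise DataError(f"{path}: duplicate sample_id {sorted(set(dup))}")
    metas = []
    for row in df.itertuples(index=False):
        kwargs = {}
        if "probe_diameter_mm" in df.columns and np.isfinite(row.probe_diameter_mm):
            kwargs["probe_diameter_mm"] = float(row.probe_diameter_mm)
        metas.append(
            CurveMeta(
                sample_id=str(row.sample_id),
                genotype=str(row.genotype),
                year=int(row.year),
                curve_file=str(row.curve_file),
                **kwargs,
            )
        )
    return metas


def read_morphology(path: str | Path) -> list[Morphology]:
    """Read the morphology table; density is recomputed from mass / volume.

    A provided ``density_g_cm3`` column is advisory only: it is cross-checked
    against m/V and a warning is issued when they differ by more than
    0.01 g/cm^3.
    """
    df = pd.read_csv(path)
    required = {"sample_id", "mass_g", "height_mm", "d1_mm", "d2_mm", "volume_cm3"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise DataError(f"{path}: empty morphology table")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise DataError(f"{path}: duplicate sample_id {sorted(set(dup))}")
    has_density = "density_g_cm3" in df.columns
    records = []
    for row in df.itertuples(index=False):
        records.append(
            Morphology(
                sample_id=str(row.sample_id),
                mass_g=float(row.mass_g),
                height_mm=float(row.height_mm),
                d1_mm=float(row.d1_mm),
                d2_mm=float(row.d2_mm),
                volume_cm3=float(row.volume_cm3),
                density_g_cm3=float(row.density_g_cm3) if has_density else 0.0,
            )
        )
    return records


def write_morphology(records: list[Morphology], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "mass_g": r.mass_g,
                "height_mm": r.height_mm,
                "d1_mm": r.d1_mm,
                "d2_mm": r.d2_mm,
                "volume_cm3": r.volume_cm3,
                "density_g_cm3": r.density_g_cm3,
            }
            for r in records
        ]
    ).to_csv(path, index=False, float_format="%.12g")
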
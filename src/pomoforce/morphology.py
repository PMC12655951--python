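"""Per-fruit density and per-genotype morphology summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .curve_io import Morphology
from .errors import DataError

__all__ = ["density", "summarize", "morphology_frame"]

TRAITS = ["mass_g", "height_mm", "d1_mm", "d2_mm", "volume_cm3", "density_g_cm3"]


def density(mass_g: float, volume_cm3: float) -> float:
    """Bulk density as the exact ratio mass / volume (g/cm^3)."""
    if mass_g <= 0 or volume_cm3 <= 0:
        raise DataError("mass and volume must be positive")
    return mass_g / volume_cm3


def morphology_frame(
    records: list[Morphology], genotype_of: dict[str, str] | None = None
) -> pd.DataFrame:
    """Tidy per-fruit table; genotype joined from a sample_id mapping if given."""
    df = pd.DataFrame(
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
    )
    if genotype_of is not None:
        df.insert(1, "genotype", df["sample_id"].map(genotype_of))
    return df


def summarize(morph: pd.DataFrame, by: str = "genotype") -> pd.DataFrame:
    """Per-genotype mean and sample SD (ddof=1) of each trait.

    Density is summarized as the mean of per-fruit ratios, matching its
    per-fruit definition (not the ratio of mean mass to mean volume). Groups
    with a single fruit report SD 0 and are flagged.
    """
    if by not in morph.columns:
        raise DataError(f"grouping column {by!r} not in morphology table")
    rows = []
    for group, sub in morph.groupby(by, sort=True):
        row: dict[str, object] = {by: group, "n": len(sub)}
        for trait in TRAITS:
            vals = sub[trait].to_numpy(dtype=float)
            row[f"{trait}_mean"] = vals.mean()
            row[f"{trait}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        row["single_fruit"] = len(sub) == 1
        rows.append(row)
    return pd.DataFrame(rows)
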
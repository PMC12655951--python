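"""Synthetic penetration-test curves and morphology with exact ground truth.

The generator emulates the phenomenology of quasi-static puncture tests on
apples: a short nonlinear contact segment while the flat probe face conforms
to the curved skin, a linear elastic rise ending in a small force drop at
the yield point, a recovery rise to the skin-rupture maximum, a drop to a
slowly declining plateau while the probe penetrates the flesh, out to 5 mm.

Construction is piecewise on a uniform deformation grid with every segment
breakpoint snapped to a grid node, so the emitted curve encodes its feature
values *exactly* and :class:`GroundTruth` records them; noiseless curves
round-trip through the extraction pipeline to machine precision.

The deformation axis starts at the contact point: the first sample carries
exactly the contact-threshold force (0.1 N), mirroring an instrument that
begins recording once full contact is declared. Contact-segment shape is a
power law ``F = th + (F_L - th) (d/d0)^n`` with the exponent derived from
slope continuity with the elastic line at ``d0`` — the contact prefix is
tangent to the line, which is what makes elastic-window selection a
nontrivial problem worth testing.

Genotype presets encode per-cultivar parameter distributions: the two
published mean yield pressures (1.1 MPa for HL648, 0.7 MPa for B217) anchor
the mechanical scale; the remaining cultivar means and all dispersion
parameters are this package's choices (see docs/methods.md). Morphology is
drawn from the published per-cultivar mean/SD table, with mass derived as
density x volume so that both mass and density track their published means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .curve_io import (
    Curve,
    CurveMeta,
    Morphology,
    preprocess_contact,
    write_curve,
    write_morphology,
)
from .errors import InfeasibleSpecError
from .features import ProbeGeometry

__all__ = [
    "SimSpec",
    "GroundTruth",
    "GenotypePreset",
    "generate_curve",
    "genotype_preset",
    "draw_spec",
    "draw_morphology",
    "simulate_batch",
    "generate_study",
    "worked_example_spec",
    "DEFAULT_COUNTS",
    "GENOTYPES",
]

_PROBE = ProbeGeometry(8.1)


@dataclass
class SimSpec:
    """Parameters of one simulated curve (N, mm; see module docstring)."""

    Fa_true: float = 35.0
    Fb_true: float = 45.0
    Fc_true: float = 20.0
    Ka_true: float = 38.0
    intercept_true: float = -3.1
    contact_span_mm: float = 0.3
    yield_drop_frac: float = 0.10
    yield_drop_span_mm: float = 0.05
    recovery_slope_frac: float = 0.5   # rise slope toward Fb, fraction of Ka
    rupture_drop_span_mm: float = 0.4
    plateau_slope_n_per_mm: float = -0.5
    noise_sigma_n: float = 0.0
    contact_threshold_n: float = 0.1
    step_mm: float = 0.005
    max_depth_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.Fa_true <= self.Fb_true:
            raise InfeasibleSpecError("need 0 < Fa_true <= Fb_true")
        if self.Fc_true >= self.Fb_true:
            raise InfeasibleSpecError("need Fc_true < Fb_true")
        if self.contact_span_mm <= 0 or self.noise_sigma_n < 0:
            raise InfeasibleSpecError("contact_span_mm > 0 and noise_sigma_n >= 0 required")
        if not 0 < self.recovery_slope_frac < 1:
            raise InfeasibleSpecError("recovery_slope_frac must be in (0, 1)")


@dataclass
class GroundTruth:
    """The spec plus the exact feature values the emitted grid encodes."""

    spec: SimSpec
    sample_id: str
    delta_yield_mm: float
    delta_rupture_mm: float
    Fa_n: float
    Fb_n: float
    Fc_n: float
    Ka_n_per_mm: float
    intercept_n: float
    Kf: float
    Pa_mpa: float = field(init=False)
    Pb_mpa: float = field(init=False)
    Pc_mpa: float = field(init=False)

    def __post_init__(self) -> None:
        self.Pa_mpa = self.Fa_n / _PROBE.area_mm2
        self.Pb_mpa = self.Fb_n / _PROBE.area_mm2
        self.Pc_mpa = self.Fc_n / _PROBE.area_mm2


def generate_curve(
    spec: SimSpec, sample_id: str = "sim", genotype: str = "", year: int = 0
) -> tuple[Curve, GroundTruth]:
    """Build one curve on the uniform grid; deterministic given ``spec.seed``.

    Returns the raw (unpreprocessed) curve — run it through
    :func:`pomoforce.curve_io.preprocess_contact` as real data would be — and
    the exact ground truth of the emitted samples. Breakpoints are snapped to
    grid nodes, so for ``noise_sigma_n = 0`` the ground-truth features are
    exact properties of the emitted series.
    """
    step, th = spec.step_mm, spec.contact_threshold_n
    n_pts = int(round(spec.max_depth_mm / step)) + 1
    d = np.arange(n_pts) * step

    i0 = max(int(round(spec.contact_span_mm / step)), 2)
    f_l = spec.Ka_true * (i0 * step) + spec.intercept_true
    if f_l <= th:
        raise InfeasibleSpecError(
            f"contact-segment end force {f_l:.3f} N <= threshold {th} N "
            "(contact exponent would be non-positive)"
        )
    n_exp = spec.Ka_true * (i0 * step) / (f_l - th)

    i_a = int(round((spec.Fa_true - spec.intercept_true) / spec.Ka_true / step))
    if i_a <= i0:
        raise InfeasibleSpecError("yield point falls inside the contact segment")
    delta_a = i_a * step
    fa = spec.Ka_true * delta_a + spec.intercept_true

    if spec.yield_drop_frac > 0:
        i_de = i_a + max(int(round(spec.yield_drop_span_mm / step)), 1)
        f_drop = fa * (1.0 - spec.yield_drop_frac)
    else:
        i_de, f_drop = i_a, fa
    if spec.Fb_true < f_drop:
        raise InfeasibleSpecError("Fb_true below post-yield force")
    rise_slope = spec.recovery_slope_frac * spec.Ka_true
    i_b = i_de + max(int(round((spec.Fb_true - f_drop) / rise_slope / step)), 1)
    i_p = i_b + max(int(round(spec.rupture_drop_span_mm / step)), 1)
    if i_p >= n_pts - 1:
        raise InfeasibleSpecError("rupture drop extends past max depth")
    delta_b = i_b * step

    f = np.empty(n_pts)
    f[: i0 + 1] = th + (f_l - th) * (d[: i0 + 1] / (i0 * step)) ** n_exp
    f[i0 + 1 : i_a + 1] = spec.Ka_true * d[i0 + 1 : i_a + 1] + spec.intercept_true
    if i_de > i_a:
        f[i_a + 1 : i_de + 1] = fa + (f_drop - fa) * (
            d[i_a + 1 : i_de + 1] - delta_a
        ) / (i_de * step - delta_a)
    f[i_de + 1 : i_b + 1] = f_drop + (spec.Fb_true - f_drop) * (
        d[i_de + 1 : i_b + 1] - i_de * step
    ) / (delta_b - i_de * step)
    f[i_b + 1 : i_p + 1] = spec.Fb_true + (spec.Fc_true - spec.Fb_true) * (
        d[i_b + 1 : i_p + 1] - delta_b
    ) / (i_p * step - delta_b)
    f[i_p:] = spec.Fc_true + spec.plateau_slope_n_per_mm * (d[i_p:] - i_p * step)

    if spec.noise_sigma_n > 0:
        rng = np.random.default_rng(spec.seed)
        f = f + rng.normal(0.0, spec.noise_sigma_n, n_pts)
    f = np.clip(f, 0.0, None)

    # exact plateau mean over the same window the extractor averages
    j_start = i_b + int(math.ceil(1.0 / step - 1e-9))
    if j_start <= n_pts - 1:
        mean_d = (j_start + (n_pts - 1)) / 2.0 * step
        fc = spec.Fc_true + spec.plateau_slope_n_per_mm * (mean_d - i_p * step)
    else:
        fc = math.nan

    meta = CurveMeta(
        sample_id=sample_id,
        genotype=genotype,
        year=year,
        contact_threshold_n=th,
        max_depth_mm=spec.max_depth_mm,
    )
    curve = Curve(deformation=d, force=f, meta=meta)
    gt = GroundTruth(
        spec=spec,
        sample_id=sample_id,
        delta_yield_mm=delta_a,
        delta_rupture_mm=delta_b,
        Fa_n=fa,
        Fb_n=spec.Fb_true,
        Fc_n=fc,
        Ka_n_per_mm=spec.Ka_true,
        intercept_n=spec.intercept_true,
        Kf=fa / spec.Fb_true,
    )
    return curve, gt


def worked_example_spec(noise_sigma_n: float = 0.0, seed: int = 0) -> SimSpec:
    """The noiseless worked-example curve ``b32-s9``.

    Its elastic segment is built on the line F = 38 d - 3.1 (N, mm), embedded
    between the tangent contact prefix and the post-yield segments, so the
    full pipeline should recover slope 38 and intercept -3.1.
    """
    return SimSpec(
        Fa_true=35.0,
        Fb_true=45.0,
        Fc_true=20.0,
        Ka_true=38.0,
        intercept_true=-3.1,
        noise_sigma_n=noise_sigma_n,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Genotype presets


@dataclass(frozen=True)
class GenotypePreset:
    """Per-cultivar parameter distributions for the simulator."""

    name: str
    year: int
    pa_mean_mpa: float          # mean yield pressure; anchors Fa
    pa_cv: float = 0.08
    kf_range: tuple[float, float] = (0.70, 0.95)
    fc_frac: float = 0.45       # Fc as a fraction of Fb
    fc_jitter: float = 0.10
    delta_a_mean_mm: float = 1.0
    delta_a_sd_mm: float = 0.08
    intercept_mean_n: float = -3.0
    intercept_sd_n: float = 0.6
    noise_sigma_n: float = 0.05
    # morphology: (mean, sd) per trait
    height_mm: tuple[float, float] = (70.0, 5.0)
    d1_mm: tuple[float, float] = (78.0, 4.0)
    d2_mm: tuple[float, float] = (79.0, 4.0)
    volume_cm3: tuple[float, float] = (240.0, 35.0)
    density_g_cm3: tuple[float, float] = (0.87, 0.08)


_PRESETS: dict[str, GenotypePreset] = {
    "B32": GenotypePreset(
        name="B32", year=2023, pa_mean_mpa=0.90,
        height_mm=(71.6, 4.9), d1_mm=(79.5, 3.9), d2_mm=(81.5, 4.3),
        volume_cm3=(268.0, 35.7), density_g_cm3=(0.85, 0.08),
    ),
    "HL648": GenotypePreset(
        name="HL648", year=2023, pa_mean_mpa=1.10,
        height_mm=(70.7, 7.0), d1_mm=(71.3, 2.7), d2_mm=(71.7, 3.1),
        volume_cm3=(213.3, 26.1), density_g_cm3=(0.89, 0.01),
    ),
    "B217": GenotypePreset(
        name="B217", year=2023, pa_mean_mpa=0.70,
        height_mm=(66.9, 3.9), d1_mm=(83.5, 3.8), d2_mm=(82.3, 3.1),
        volume_cm3=(270.5, 34.7), density_g_cm3=(0.80, 0.02),
    ),
    "B231": GenotypePreset(
        name="B231", year=2023, pa_mean_mpa=1.00,
        height_mm=(56.2, 5.7), d1_mm=(69.3, 6.2), d2_mm=(69.4, 5.8),
        volume_cm3=(159.9, 34.9), density_g_cm3=(0.93, 0.13),
    ),
    "B273": GenotypePreset(
        name="B273", year=2023, pa_mean_mpa=0.85,
        height_mm=(68.1, 6.5), d1_mm=(78.2, 4.8), d2_mm=(79.1, 3.4),
        volume_cm3=(239.7, 38.4), density_g_cm3=(0.88, 0.12),
    ),
    "HL648_24": GenotypePreset(
        name="HL648_24", year=2024, pa_mean_mpa=1.10,
        height_mm=(68.4, 4.4), d1_mm=(73.6, 5.2), d2_mm=(74.9, 3.6),
        volume_cm3=(220.1, 30.4), density_g_cm3=(0.90, 0.02),
    ),
}

GENOTYPES = tuple(_PRESETS)
DEFAULT_COUNTS: dict[str, int] = {
    "B32": 18, "HL648": 10, "B217": 10, "B231": 9, "B273": 9, "HL648_24": 24,
}


def genotype_preset(name: str) -> GenotypePreset:
    """Look up a cultivar preset by name (KeyError for unknown names)."""
    return _PRESETS[name]


def draw_spec(preset: GenotypePreset, rng: np.random.Generator) -> SimSpec:
    """Draw one curve spec from a cultivar's parameter distributions."""
    fa = rng.normal(preset.pa_mean_mpa * _PROBE.area_mm2,
                    preset.pa_cv * preset.pa_mean_mpa * _PROBE.area_mm2)
    fa = max(fa, 2.0)
    kf = rng.uniform(*preset.kf_range)
    fb = fa / kf
    fc = preset.fc_frac * fb * rng.uniform(1 - preset.fc_jitter, 1 + preset.fc_jitter)
    delta_a = float(np.clip(rng.normal(preset.delta_a_mean_mm, preset.delta_a_sd_mm),
                            0.6, 1.4))
    intercept = float(np.clip(rng.normal(preset.intercept_mean_n, preset.intercept_sd_n),
                              -6.0, -0.5))
    ka = (fa - intercept) / delta_a
    return SimSpec(
        Fa_true=fa,
        Fb_true=fb,
        Fc_true=fc,
        Ka_true=ka,
        intercept_true=intercept,
        noise_sigma_n=preset.noise_sigma_n,
        seed=int(rng.integers(2**31)),
    )


def draw_morphology(
    preset: GenotypePreset, sample_id: str, rng: np.random.Generator
) -> Morphology:
    """Draw one fruit's morphology; mass is density x volume by construction."""

    def trunc(mean_sd: tuple[float, float], lo: float, hi: float) -> float:
        return float(np.clip(rng.normal(*mean_sd), lo, hi))

    volume = trunc(preset.volume_cm3, 20.0, 600.0)
    rho = trunc(preset.density_g_cm3, 0.3, 1.4)
    return Morphology(
        sample_id=sample_id,
        mass_g=rho * volume,
        height_mm=trunc(preset.height_mm, 20.0, 150.0),
        d1_mm=trunc(preset.d1_mm, 20.0, 150.0),
        d2_mm=trunc(preset.d2_mm, 20.0, 150.0),
        volume_cm3=volume,
    )


def simulate_batch(
    counts: dict[str, int] | None = None,
    seed: int = 0,
    noise_sigma_n: float | None = None,
    preprocess: bool = True,
) -> tuple[list[Curve], list[GroundTruth], list[Morphology]]:
    """Simulate a whole study in memory.

    ``counts`` maps genotype name to number of fruits (default: the study
    design 18/10/10/9/9 + 24). ``noise_sigma_n`` overrides every preset's
    noise level when given. Curves are contact-preprocessed unless
    ``preprocess=False``.
    """
    counts = DEFAULT_COUNTS if counts is None else counts
    rng = np.random.default_rng(seed)
    curves: list[Curve] = []
    truths: list[GroundTruth] = []
    morphs: list[Morphology] = []
    for name, n in counts.items():
        preset = genotype_preset(name)
        if noise_sigma_n is not None:
            preset = replace(preset, noise_sigma_n=noise_sigma_n)
        for k in range(n):
            sid = f"{name}-s{k + 1:02d}"
            spec = draw_spec(preset, rng)
            curve, gt = generate_curve(spec, sample_id=sid, genotype=name,
                                       year=preset.year)
            if preprocess:
                curve = preprocess_contact(
                    curve.deformation, curve.force,
                    threshold=spec.contact_threshold_n, meta=curve.meta,
                )
            curves.append(curve)
            truths.append(gt)
            morphs.append(draw_morphology(preset, sid, rng))
    return curves, truths, morphs


def ground_truth_frame(truths: list[GroundTruth], genotypes: list[str]) -> pd.DataFrame:
    rows = []
    for gt, geno in zip(truths, genotypes):
        s = gt.spec
        rows.append(
            {
                "sample_id": gt.sample_id,
                "genotype": geno,
                "Fa_n": gt.Fa_n, "Fb_n": gt.Fb_n, "Fc_n": gt.Fc_n,
                "Ka_n_per_mm": gt.Ka_n_per_mm, "intercept_n": gt.intercept_n,
                "Kf": gt.Kf,
                "Pa_mpa": gt.Pa_mpa, "Pb_mpa": gt.Pb_mpa, "Pc_mpa": gt.Pc_mpa,
                "delta_yield_mm": gt.delta_yield_mm,
                "delta_rupture_mm": gt.delta_rupture_mm,
                "noise_sigma_n": s.noise_sigma_n,
                "seed": s.seed,
            }
        )
    return pd.DataFrame(rows)


def generate_study(
    out_dir: str | Path,
    counts: dict[str, int] | None = None,
    seed: int = 0,
    noise_sigma_n: float | None = None,
) -> Path:
    """Write a complete synthetic study to ``out_dir``.

    Emits one raw curve CSV per fruit, ``manifest.csv``, ``morphology.csv``
    and ``ground_truth.csv`` in the package's standard formats. Deterministic
    and byte-identical for a fixed seed. Genotypes with a zero count are
    omitted from the manifest.
    """
    out = Path(out_dir)
    (out / "curves").mkdir(parents=True, exist_ok=True)
    counts = DEFAULT_COUNTS if counts is None else counts
    counts = {g: n for g, n in counts.items() if n > 0}
    curves, truths, morphs = simulate_batch(
        counts, seed=seed, noise_sigma_n=noise_sigma_n, preprocess=False
    )
    manifest_rows = []
    for curve in curves:
        fname = f"curves/{curve.meta.sample_id}.csv"
        write_curve(curve, out / fname)
        manifest_rows.append(
            {
                "sample_id": curve.meta.sample_id,
                "genotype": curve.meta.genotype,
                "year": curve.meta.year,
                "curve_file": fname,
                "probe_diameter_mm": curve.meta.probe_diameter_mm,
            }
        )
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    write_morphology(morphs, out / "morphology.csv")
    ground_truth_frame(truths, [c.meta.genotype for c in curves]).to_csv(
        out / "ground_truth.csv", index=False, float_format="%.12g"
    )
    return out
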
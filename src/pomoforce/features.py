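"""Segmentation and parameterization of penetration-test curves.

A preprocessed curve is divided into three regions:

1. *elastic region* — after a short nonlinear contact segment the force rises
   approximately linearly with deformation; its end is the yield point
   (force ``Fa``), where subcutaneous tissue first fails permanently.
2. *failure region* — force climbs to the global maximum ``Fb``, at which
   the skin ruptures and the probe starts penetrating the flesh.
3. *penetration region* — force drops to a noisy plateau; ``Fc`` is the mean
   force from a fixed offset (1 mm) beyond the rupture point to test end.

Forces are converted to pressures (``Pa``, ``Pb``, ``Pc``, in MPa) by
dividing by the probe face area, ``Ka`` is the slope of the elastic line and
``Kf = Fa / Fb`` relates subcutaneous failure to skin rupture.

Yield detection is two-stage: stage 1 looks for a local drop of the smoothed
force (the visible "notch" most curves show at the yield point); stage 2,
for curves whose failure appears only as a slope break, fits the elastic
line first and takes the first sustained shortfall of the raw force below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FeatureConfig
from .curve_io import Curve
from .errors import FitError, PlateauError, YieldNotFoundError

__all__ = [
    "ProbeGeometry",
    "FeatureSet",
    "detect_rupture",
    "detect_yield",
    "fit_elastic",
    "mean_plateau",
    "stage2_line",
    "shortfall_scan",
    "to_pressure",
    "extract_features",
    "extract_table",
    "aggregate_curve",
]

FEATURE_COLUMNS = [
    "sample_id", "genotype", "year",
    "Fa_n", "Fb_n", "Fc_n", "Ka_n_per_mm", "intercept_n", "r2_elastic",
    "Kf", "Pa_mpa", "Pb_mpa", "Pc_mpa",
    "delta_yield_mm", "delta_rupture_mm", "flags",
]


@dataclass(frozen=True)
class ProbeGeometry:
    """Flat cylindrical probe; pressure = force / face area (N/mm^2 = MPa)."""

    diameter_mm: float = 8.1

    @property
    def area_mm2(self) -> float:
        return math.pi * (self.diameter_mm / 2.0) ** 2


@dataclass
class FeatureSet:
    """All mechanical parameters extracted from one curve.

    Fields that could not be determined (a failed detection stage) are NaN
    and the stage is named in ``flags``; the sample is then excluded from
    statistics of the affected parameters only.
    """

    sample_id: str
    Fa_n: float = np.nan
    Fb_n: float = np.nan
    Fc_n: float = np.nan
    Ka_n_per_mm: float = np.nan
    intercept_n: float = np.nan
    r2_elastic: float = np.nan
    Kf: float = np.nan
    Pa_mpa: float = np.nan
    Pb_mpa: float = np.nan
    Pc_mpa: float = np.nan
    idx_contact: int = 0
    idx_lin_start: int = -1
    idx_yield: int = -1
    idx_rupture: int = -1
    delta_yield_mm: float = np.nan
    delta_rupture_mm: float = np.nan
    yield_stage: int = 0
    flags: list[str] = field(default_factory=list)


def to_pressure(force_n: float | np.ndarray, probe: ProbeGeometry) -> float | np.ndarray:
    """Convert a force (N) to the pressure (MPa) on the probe face."""
    return force_n / probe.area_mm2


def detect_rupture(curve: Curve) -> tuple[int, float]:
    """Locate the skin-rupture point: the global force maximum.

    Ties are broken toward the first index attaining the maximum.
    """
    idx = int(np.argmax(curve.force))
    return idx, float(curve.force[idx])


def _smooth(force: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking edge windows."""
    if window <= 1:
        return force.astype(float)
    half = window // 2
    c = np.concatenate(([0.0], np.cumsum(force, dtype=float)))
    n = len(force)
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


class _LineFit:
    """Incremental OLS over index windows via prefix sums."""

    def __init__(self, x: np.ndarray, y: np.ndarray):
        self.n = len(x)
        z = np.zeros(1)
        self.cx = np.concatenate((z, np.cumsum(x)))
        self.cy = np.concatenate((z, np.cumsum(y)))
        self.cxx = np.concatenate((z, np.cumsum(x * x)))
        self.cyy = np.concatenate((z, np.cumsum(y * y)))
        self.cxy = np.concatenate((z, np.cumsum(x * y)))

    def fit(self, s: int, e: int) -> tuple[float, float, float, float]:
        """OLS on the inclusive index window [s, e].

        Returns (slope, intercept, r2, rmse). A window with zero force
        variance and zero residual has r2 defined as 1.
        """
        m = e - s + 1
        sx = self.cx[e + 1] - self.cx[s]
        sy = self.cy[e + 1] - self.cy[s]
        sxx = self.cxx[e + 1] - self.cxx[s]
        syy = self.cyy[e + 1] - self.cyy[s]
        sxy = self.cxy[e + 1] - self.cxy[s]
        vx = sxx - sx * sx / m
        vy = syy - sy * sy / m
        cov = sxy - sx * sy / m
        if vx <= 0:
            raise FitError("degenerate x window in elastic fit")
        slope = cov / vx
        intercept = (sy - slope * sx) / m
        ssr = max(vy - slope * cov, 0.0)
        r2 = 1.0 if vy <= 1e-300 else max(1.0 - ssr / vy, 0.0)
        rmse = math.sqrt(ssr / m)
        return slope, intercept, r2, rmse


def fit_elastic(
    curve: Curve, idx_yield: int, cfg: FeatureConfig | None = None
) -> tuple[float, float, float, int]:
    """Fit the elastic line on a backward-expanded window ending at the yield.

    The seed window spans ``min_span_mm`` back from ``idx_yield``. It is then
    grown toward index 0 one sample at a time while (a) the window R^2 stays
    at or above ``r2_min`` and (b) the candidate point's prediction residual
    stays within ``pred_resid_k`` times the current fit RMSE (floored at
    ``pred_resid_floor_n``). Gate (b) keeps out the contact segment, which is
    tangent to the elastic line and therefore nearly invisible to R^2 alone.

    Returns ``(Ka, intercept, r2, idx_lin_start)`` with the intercept quoted
    at deformation 0 (the contact point).
    """
    cfg = cfg or FeatureConfig()
    d, f = curve.deformation, curve.force
    if d[idx_yield] - d[0] < cfg.min_span_mm:
        raise FitError(
            f"{curve.meta.sample_id}: elastic span {d[idx_yield] - d[0]:.3f} mm "
            f"< min_span {cfg.min_span_mm} mm"
        )
    fitter = _LineFit(d, f)
    s = int(np.searchsorted(d, d[idx_yield] - cfg.min_span_mm, side="left"))
    s = min(s, idx_yield - 2)
    slope, intercept, r2, rmse = fitter.fit(s, idx_yield)
    while s > 0:
        pred = slope * d[s - 1] + intercept
        tol = max(cfg.pred_resid_k * rmse, cfg.pred_resid_floor_n)
        if abs(f[s - 1] - pred) > tol:
            break
        cand = fitter.fit(s - 1, idx_yield)
        if cand[2] < cfg.r2_min:
            break
        s -= 1
        slope, intercept, r2, rmse = cand
    return slope, intercept, r2, s


def _stage1_drop(
    d: np.ndarray, sm: np.ndarray, f: np.ndarray, idx_rupture: int, cfg: FeatureConfig
) -> tuple[int, float] | None:
    """First smoothed-force drop event before the rupture point.

    Fires at the first index ``i`` where the smoothed force falls by at least
    ``max(drop_frac * sm[i], drop_min_n)`` within the next ``drop_window_mm``
    (never looking past the rupture index). The yield index is the raw-force
    argmax between ``i`` and the sample achieving the drop.
    """
    if idx_rupture < 2:
        return None
    j_end = np.searchsorted(d, d + cfg.drop_window_mm, side="right")
    j_end = np.minimum(j_end, idx_rupture + 1)
    need = np.maximum(cfg.drop_frac * sm, cfg.drop_min_n)
    # windowed min of sm over (i, j_end): uniform-width fast path
    widths = j_end[:idx_rupture] - np.arange(idx_rupture)
    for i in range(idx_rupture):
        w = widths[i]
        if w <= 1:
            continue
        window = sm[i + 1 : i + w]
        drop = sm[i] - window.min()
        if drop >= need[i]:
            j_hit = i + 1 + int(np.argmax(sm[i] - window >= need[i]))
            idx_yield = i + int(np.argmax(f[i : j_hit + 1]))
            return idx_yield, float(f[idx_yield])
    return None


def _stage1_drop_fast(
    d: np.ndarray, sm: np.ndarray, f: np.ndarray, idx_rupture: int, cfg: FeatureConfig
) -> tuple[int, float] | None:
    """Vectorized stage-1 scan for (near-)uniform grids; falls back otherwise."""
    if idx_rupture < 2:
        return None
    steps = np.diff(d)
    if steps.size == 0 or steps.max() - steps.min() > 1e-9 * max(steps.max(), 1e-12):
        return _stage1_drop(d, sm, f, idx_rupture, cfg)
    step = steps[0]
    w = max(int(math.floor(cfg.drop_window_mm / step + 1e-9)), 1)
    need = np.maximum(cfg.drop_frac * sm, cfg.drop_min_n)
    # full-width windows: min of sm[i+1 .. i+w] for i where i+w <= idx_rupture
    n_full = idx_rupture - w
    if n_full > 0:
        view = np.lib.stride_tricks.sliding_window_view(sm[1 : idx_rupture + 1], w)
        mins = view.min(axis=1)  # mins[i] = min sm[i+1 .. i+w]
        fired = np.nonzero(sm[:n_full] - mins[:n_full] >= need[:n_full])[0]
    else:
        fired = np.array([], dtype=int)
    if fired.size:
        i = int(fired[0])
        window = sm[i + 1 : i + w + 1]
    else:
        # truncated windows near the rupture point
        for i in range(max(n_full, 0), idx_rupture):
            window = sm[i + 1 : idx_rupture + 1]
            if window.size and sm[i] - window.min() >= need[i]:
                break
        else:
            return None
    j_hit = i + 1 + int(np.argmax(sm[i] - window >= need[i]))
    idx_yield = i + int(np.argmax(f[i : j_hit + 1]))
    return idx_yield, float(f[idx_yield])


def stage2_line(
    curve: Curve, idx_rupture: int, cfg: FeatureConfig | None = None
) -> tuple[float, float, int, int] | None:
    """Elastic line for the stage-2 fallback, without a known yield index.

    The seed window is the ``min_span_mm`` window of maximal local slope
    before the rupture (the elastic region is the steepest sustained rise);
    it is expanded backward and forward under the same R^2 / prediction-
    residual gates as :func:`fit_elastic`. Returns
    ``(slope, intercept, idx_lin_start, idx_lin_end)`` or None when no
    window qualifies.
    """
    cfg = cfg or FeatureConfig()
    d, f = curve.deformation, curve.force
    if idx_rupture < 4 or d[idx_rupture] - d[0] <= cfg.min_span_mm:
        return None
    fitter = _LineFit(d, f)
    # local slope of min-span windows starting at each index before rupture
    ends = np.searchsorted(d, d + cfg.min_span_mm, side="left")
    best_s, best_slope = -1, -np.inf
    for s in range(idx_rupture):
        e = min(int(ends[s]), idx_rupture)
        if e - s < 2 or d[e] - d[s] < cfg.min_span_mm - 1e-12:
            continue
        try:
            slope = fitter.fit(s, e)[0]
        except FitError:
            continue
        if slope > best_slope:
            best_slope, best_s = slope, s
    if best_s < 0:
        return None
    s, e = best_s, min(int(ends[best_s]), idx_rupture)
    slope, intercept, r2, rmse = fitter.fit(s, e)

    def absorb(idx: int, s: int, e: int, fit):
        slope, intercept, r2, rmse = fit
        pred = slope * d[idx] + intercept
        if abs(f[idx] - pred) > max(cfg.pred_resid_k * rmse, cfg.pred_resid_floor_n):
            return None
        cand = fitter.fit(min(s, idx), max(e, idx))
        return cand if cand[2] >= cfg.r2_min else None

    while s > 0:
        cand = absorb(s - 1, s, e, (slope, intercept, r2, rmse))
        if cand is None:
            break
        s -= 1
        slope, intercept, r2, rmse = cand
    while e < idx_rupture:
        cand = absorb(e + 1, s, e, (slope, intercept, r2, rmse))
        if cand is None:
            break
        e += 1
        slope, intercept, r2, rmse = cand
    return slope, intercept, s, e


def shortfall_scan(
    deformation: np.ndarray,
    force: np.ndarray,
    slope: float,
    intercept: float,
    start: int,
    stop: int,
    resid_frac: float,
    resid_persist_mm: float,
) -> int | None:
    """First index in [start, stop] opening a sustained shortfall run.

    A run is a maximal stretch of consecutive samples whose raw force lies
    below the line ``slope * d + intercept`` by more than ``resid_frac`` of
    the (positive) fitted value; it qualifies once it spans at least
    ``resid_persist_mm`` of deformation within [start, stop].
    """
    run_start = -1
    for i in range(start, stop + 1):
        fitted = slope * deformation[i] + intercept
        short = fitted > 0 and force[i] < fitted * (1.0 - resid_frac)
        if short and run_start < 0:
            run_start = i
        elif not short:
            run_start = -1
        if run_start >= 0 and (
            deformation[i] - deformation[run_start] >= resid_persist_mm - 1e-12
        ):
            return run_start
    return None


def _stage2_residual(
    curve: Curve, idx_rupture: int, cfg: FeatureConfig
) -> tuple[int, float] | None:
    """Slope-break fallback: fitted elastic line, then sustained shortfall."""
    line = stage2_line(curve, idx_rupture, cfg)
    if line is None:
        return None
    slope, intercept, _, e = line
    d, f = curve.deformation, curve.force
    idx = shortfall_scan(
        d, f, slope, intercept, e, idx_rupture, cfg.resid_frac, cfg.resid_persist_mm
    )
    if idx is None:
        return None
    return idx, float(f[idx])


def detect_yield(
    curve: Curve, idx_rupture: int, cfg: FeatureConfig | None = None
) -> tuple[int, float, int]:
    """Locate the yield point (force ``Fa``) before the rupture index.

    Returns ``(idx_yield, Fa, stage)`` where stage is 1 (smoothed-force drop
    event) or 2 (sustained shortfall below the fitted elastic line).

    Raises
    ------
    YieldNotFoundError
        If neither stage fires; the sample should then be excluded from
        Fa/Pa/Kf statistics but keeps its other parameters.
    """
    cfg = cfg or FeatureConfig()
    d, f = curve.deformation, curve.force
    sm = _smooth(f, cfg.smooth_window)
    hit = _stage1_drop_fast(d, sm, f, idx_rupture, cfg)
    if hit is not None:
        return hit[0], hit[1], 1
    hit = _stage2_residual(curve, idx_rupture, cfg)
    if hit is not None:
        return hit[0], hit[1], 2
    raise YieldNotFoundError(f"{curve.meta.sample_id}: no yield event detected")


def mean_plateau(curve: Curve, idx_rupture: int, offset_mm: float = 1.0) -> float:
    """Mean raw force from ``offset_mm`` beyond the rupture point to test end."""
    d = curve.deformation
    target = d[idx_rupture] + offset_mm
    sel = d >= target - 1e-9
    if not np.any(sel):
        raise PlateauError(
            f"{curve.meta.sample_id}: no samples beyond rupture + {offset_mm} mm"
        )
    return float(curve.force[sel].mean())


def extract_features(
    curve: Curve, probe: ProbeGeometry | None = None, cfg: FeatureConfig | None = None
) -> FeatureSet:
    """Run the full parameterization on one curve; failures become flags.

    A failed stage never drops the sample: the affected parameters are NaN
    and the stage name is appended to ``flags``.
    """
    cfg = cfg or FeatureConfig()
    probe = probe or ProbeGeometry(curve.meta.probe_diameter_mm)
    fs = FeatureSet(sample_id=curve.meta.sample_id)
    n = len(curve)

    fs.idx_rupture, fs.Fb_n = detect_rupture(curve)
    fs.delta_rupture_mm = float(curve.deformation[fs.idx_rupture])
    fs.Pb_mpa = to_pressure(fs.Fb_n, probe)
    if fs.idx_rupture == n - 1:
        fs.flags.append("rupture_at_end")

    try:
        fs.idx_yield, fs.Fa_n, fs.yield_stage = detect_yield(curve, fs.idx_rupture, cfg)
        fs.delta_yield_mm = float(curve.deformation[fs.idx_yield])
        fs.Kf = fs.Fa_n / fs.Fb_n
        fs.Pa_mpa = to_pressure(fs.Fa_n, probe)
    except YieldNotFoundError:
        fs.flags.append("yield_not_found")

    if fs.idx_yield >= 0:
        try:
            fs.Ka_n_per_mm, fs.intercept_n, fs.r2_elastic, fs.idx_lin_start = fit_elastic(
                curve, fs.idx_yield, cfg
            )
        except FitError:
            fs.flags.append("elastic_fit_failed")

    try:
        fs.Fc_n = mean_plateau(curve, fs.idx_rupture, cfg.plateau_offset_mm)
        fs.Pc_mpa = to_pressure(fs.Fc_n, probe)
    except PlateauError:
        fs.flags.append("plateau_empty")

    return fs


def extract_table(
    curves: list[Curve], cfg: FeatureConfig | None = None
) -> pd.DataFrame:
    """Extract features for a batch of curves into one tidy table."""
    cfg = cfg or FeatureConfig()
    rows = []
    for curve in curves:
        fs = extract_features(curve, ProbeGeometry(curve.meta.probe_diameter_mm), cfg)
        rows.append(
            {
                "sample_id": fs.sample_id,
                "genotype": curve.meta.genotype,
                "year": curve.meta.year,
                "Fa_n": fs.Fa_n,
                "Fb_n": fs.Fb_n,
                "Fc_n": fs.Fc_n,
                "Ka_n_per_mm": fs.Ka_n_per_mm,
                "intercept_n": fs.intercept_n,
                "r2_elastic": fs.r2_elastic,
                "Kf": fs.Kf,
                "Pa_mpa": fs.Pa_mpa,
                "Pb_mpa": fs.Pb_mpa,
                "Pc_mpa": fs.Pc_mpa,
                "delta_yield_mm": fs.delta_yield_mm,
                "delta_rupture_mm": fs.delta_rupture_mm,
                "flags": ";".join(fs.flags),
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def aggregate_curve(
    curves: list[Curve], step_mm: float = 0.2, max_depth_mm: float = 5.0
) -> pd.DataFrame:
    """Mean +/- SD force on a fixed deformation grid across curves.

    Each curve is linearly interpolated onto the inclusive grid
    ``0, step, ..., max_depth``; grid points beyond a curve's own maximum
    deformation are excluded for that curve. SD is the sample standard
    deviation (ddof=1), NaN where only one curve contributes.
    """
    if len(curves) < 2:
        raise ValueError("aggregate_curve needs at least 2 curves")
    n_pts = int(round(max_depth_mm / step_mm)) + 1
    grid = np.linspace(0.0, step_mm * (n_pts - 1), n_pts)
    values = np.full((len(curves), n_pts), np.nan)
    for k, c in enumerate(curves):
        ok = grid <= c.deformation[-1] + 1e-9
        values[k, ok] = np.interp(grid[ok], c.deformation, c.force)
    counts = np.sum(~np.isnan(values), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(counts > 0, values, np.nan), axis=0)
        sd = np.full(n_pts, np.nan)
        for j in np.nonzero(counts > 1)[0]:
            sd[j] = np.nanstd(values[:, j], ddof=1)
    keep = counts > 0
    return pd.DataFrame(
        {
            "deformation_mm": grid[keep],
            "mean_force_n": mean[keep],
            "sd_force_n": sd[keep],
            "n_curves": counts[keep],
        }
    )
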
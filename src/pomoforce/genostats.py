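"""Multi-genotype statistical comparison of mechanical phenotypes.

The battery mirrors standard breeding-trial practice for non-normal
mechanical data: per-parameter Kruskal-Wallis across genotypes with Dunn's
pairwise post hoc (tie-corrected mean-rank z tests), a Pearson correlation
matrix masked at p < 0.05, and PCA of the standardized parameters.

Dunn's z for groups A, B on the pooled ranks of N observations:

    z = (Rbar_A - Rbar_B) / sqrt([N(N+1)/12 - T/(12(N-1))] (1/n_A + 1/n_B))

with tie term T = sum(t^3 - t) over tied groups. Raw p-values are two-sided
normal; adjustment defaults to Holm.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError

__all__ = [
    "TestResult",
    "PcaResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "correlation_matrix",
    "pca",
]


@dataclass
class TestResult:
    """Kruskal-Wallis H and p, optionally with the Dunn pairwise table."""

    statistic: float
    pvalue: float
    pairwise: pd.DataFrame | None = None


@dataclass
class PcaResult:
    """Loadings (variables x components), explained fractions, sample scores."""

    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame


def _clean_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        if len(arr) >= 2:
            out[name] = arr
    if len(out) < 2:
        raise DegenerateDataError("need >= 2 groups with >= 2 finite values each")
    return out


def kruskal_wallis(groups: dict[str, np.ndarray]) -> TestResult:
    """Rank-based H test across genotype groups (tie-corrected, chi-square p)."""
    clean = _clean_groups(groups)
    if np.ptp(np.concatenate(list(clean.values()))) == 0:
        raise DegenerateDataError("all values identical across groups")
    try:
        h, p = stats.kruskal(*clean.values())
    except ValueError as exc:  # scipy raises on degenerate input in some versions
        raise DegenerateDataError(str(exc)) from exc
    return TestResult(statistic=float(h), pvalue=float(p))


def dunn_posthoc(groups: dict[str, np.ndarray], adjust: str = "holm") -> pd.DataFrame:
    """Dunn's pairwise mean-rank z tests on the pooled ranks.

    Parameters
    ----------
    adjust : ``holm`` (default), ``bonferroni`` or ``none``.

    Returns a table with one row per unordered pair:
    ``group_a, group_b, z, p_raw, p_adjusted``.
    """
    if adjust not in ("holm", "bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    clean = _clean_groups(groups)
    names = list(clean)
    pooled = np.concatenate([clean[g] for g in names])
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all values identical across groups")
    n_tot = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        k = len(clean[g])
        mean_ranks[g] = ranks[start : start + k].mean()
        sizes[g] = k
        start += k
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term / (12.0 * (n_tot - 1))

    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": min(p_raw, 1.0)})
    table = pd.DataFrame(rows)
    if adjust == "none":
        table["p_adjusted"] = table["p_raw"]
    else:
        table["p_adjusted"] = multipletests(table["p_raw"], method=adjust)[1]
    return table


def correlation_matrix(
    features: pd.DataFrame,
    variables: list[str] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations with a significance mask.

    Flagged samples contribute to every pair for which both of their values
    are finite (pairwise-complete, not listwise). Returns ``(r, p, mask)``
    where ``mask`` is True for p < alpha; the diagonal is r = 1, unmasked.
    Variables with zero variance (or < 3 complete pairs) yield NaN r and a
    False mask.
    """
    if variables is None:
        variables = [c for c in features.columns if features[c].dtype.kind == "f"]
    k = len(variables)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    mask = np.zeros((k, k), dtype=bool)
    for i in range(k):
        r[i, i], p[i, i], mask[i, i] = 1.0, 0.0, True
        for j in range(i + 1, k):
            x = features[variables[i]].to_numpy(dtype=float)
            y = features[variables[j]].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                continue
            res = stats.pearsonr(x[ok], y[ok])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
            mask[i, j] = mask[j, i] = res.pvalue < alpha
    idx = pd.Index(variables)
    return (
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
        pd.DataFrame(mask, index=idx, columns=idx),
    )


def pca(
    features: pd.DataFrame,
    variables: list[str] | None = None,
    n_components: int | None = None,
) -> PcaResult:
    """PCA of z-scored parameters over complete cases.

    Rows with any non-finite value in ``variables`` are dropped (complete
    cases). Variables are standardized to zero mean and unit variance, so
    the decomposition is of the correlation matrix — appropriate because the
    parameters span different units (MPa, N/mm, g/cm^3, cm^3). Components
    are ordered by explained variance; each loading column is sign-fixed so
    its largest-magnitude entry is positive.
    """
    if variables is None:
        variables = [c for c in features.columns if features[c].dtype.kind == "f"]
    data = features[variables].astype(float)
    complete = data.dropna()
    complete = complete[np.isfinite(complete).all(axis=1)]
    if len(complete) < 3:
        raise DegenerateDataError("PCA needs >= 3 complete rows")
    if len(complete) < len(variables):
        warnings.warn(
            f"only {len(complete)} complete rows for {len(variables)} variables; "
            "components truncated to the data rank",
            stacklevel=2,
        )
    x = complete.to_numpy()
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise DegenerateDataError(f"zero-variance variables: {bad}")
    z = (x - x.mean(axis=0)) / sd
    max_rank = min(len(complete) - 1, len(variables))
    k = max_rank if n_components is None else min(n_components, max_rank)
    model = PCA(n_components=k)
    scores = model.fit_transform(z)
    loadings = model.components_.T.copy()  # variables x components
    for c in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, c])), c] < 0:
            loadings[:, c] *= -1.0
            scores[:, c] *= -1.0
    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PcaResult(
        loadings=pd.DataFrame(loadings, index=variables, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
        scores=pd.DataFrame(scores, index=complete.index, columns=comp_names),
    )
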
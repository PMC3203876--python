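"""Climatic niche summaries: value extraction, per-pair PCA, Mann-Whitney.

Environmental values are read at each locality's grid cell; sister-species
pairs are compared in a shared principal-component space (PCA of the
pooled, standardized localities of both species) with a nonparametric
Mann-Whitney U test per component.  Parametric ANOVA-family tests are
deliberately not offered: heterogeneous climate variables routinely
violate their normality and variance-homogeneity assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .containers import EnvStack, InvalidArgumentError, OccurrenceSet

#: pooled-sample size at or below which the exact permutation null is used
EXACT_MW_LIMIT = 20

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_code(p: float) -> str:
    """Conventional star coding: * p<0.05, ** p<0.01, *** p<0.001, else NS."""
    for thr, code in STAR_THRESHOLDS:
        if p < thr:
            return code
    return "NS"


class EmptyTableError(ValueError):
    pass


@dataclass
class TraitTable:
    """Per-locality environmental values for one species."""

    species_id: str
    values: pd.DataFrame  # rows = retained localities, columns = layers
    n_dropped: int = 0  # localities that fell on nodata cells


def extract_values(env: EnvStack, occ: OccurrenceSet) -> TraitTable:
    """Read every layer at the cell containing each locality.

    Localities on nodata cells (or outside the grid) are dropped and
    counted in ``n_dropped``.
    """
    row, col = env.xy_to_rc(occ.points)
    rows, cols = env.shape
    inside = (row >= 0) & (row < rows) & (col >= 0) & (col < cols)
    ok = inside.copy()
    ok[inside] &= ~env.nodata_mask[row[inside], col[inside]]
    if not ok.any():
        raise EmptyTableError(f"all localities of {occ.species_id} fall on nodata")
    vals = env.values_at_cells(row[ok], col[ok])
    df = pd.DataFrame(vals, columns=env.layer_names)
    return TraitTable(occ.species_id, df, n_dropped=int((~ok).sum()))


def species_summary(
    tables: dict[str, TraitTable], statistic: str = "mean"
) -> pd.DataFrame:
    """One row per species, one column per layer (mean or median)."""
    if statistic not in ("mean", "median"):
        raise InvalidArgumentError("statistic must be 'mean' or 'median'")
    rows = {}
    for sp, tt in sorted(tables.items()):
        agg = tt.values.mean() if statistic == "mean" else tt.values.median()
        rows[sp] = agg
    out = pd.DataFrame(rows).T
    if not np.isfinite(out.to_numpy()).all():
        raise InvalidArgumentError("non-finite trait summary")
    return out


@dataclass
class PCAPairResult:
    loadings: pd.DataFrame  # layer x component
    scores: pd.DataFrame  # locality x component, with a species column
    pct_variance: np.ndarray
    dropped_layers: list[str] = field(default_factory=list)


def pair_pca(tt_a: TraitTable, tt_b: TraitTable) -> PCAPairResult:
    """PCA of the pooled, standardized localities of two species.

    Standardization (correlation-matrix PCA) puts heterogeneous units —
    tenths of degrees C next to millimetres of rain — on a common scale.
    Zero-variance layers are dropped with a note.
    """
    pooled = pd.concat([tt_a.values, tt_b.values], ignore_index=True)
    if len(pooled) < 3:
        raise InvalidArgumentError("need at least 3 pooled localities")
    sd = pooled.std(ddof=0)
    dropped = list(sd.index[sd == 0])
    keep = [c for c in pooled.columns if c not in dropped]
    if len(keep) < 2:
        raise InvalidArgumentError("need at least 2 non-constant layers")
    X = (pooled[keep] - pooled[keep].mean()) / pooled[keep].std(ddof=0)
    pca = PCA()
    scores = pca.fit_transform(X.to_numpy())
    comps = [f"PC{i + 1}" for i in range(scores.shape[1])]
    species = [tt_a.species_id] * len(tt_a.values) + [tt_b.species_id] * len(tt_b.values)
    score_df = pd.DataFrame(scores, columns=comps)
    score_df.insert(0, "species", species)
    loadings = pd.DataFrame(pca.components_.T, index=keep, columns=comps)
    return PCAPairResult(
        loadings=loadings,
        scores=score_df,
        pct_variance=100.0 * pca.explained_variance_ratio_,
        dropped_layers=dropped,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: number of (a, b) pairs with a > b, ties counted 1/2."""
    ranks = stats.rankdata(np.concatenate([a, b]))
    ra = ranks[: len(a)].sum()
    return ra - len(a) * (len(a) + 1) / 2.0


def mann_whitney_pc(
    scores_a: np.ndarray, scores_b: np.ndarray, method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test on one component's scores.

    ``method='exact'`` enumerates every assignment of the pooled values to
    the two groups (tie-safe); ``'normal'`` uses the tie-corrected normal
    approximation; ``'auto'`` picks exact when the pooled size is at most
    20.  Returns (U of group a, two-sided p).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InvalidArgumentError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    u_obs = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return u_obs, 1.0
    if method == "auto":
        method = "exact" if n_a + n_b <= EXACT_MW_LIMIT else "normal"
    if method == "exact":
        mid = n_a * n_b / 2.0
        dev_obs = abs(u_obs - mid)
        ranks = stats.rankdata(pooled)
        count = 0
        total = comb(n_a + n_b, n_a)
        offset = n_a * (n_a + 1) / 2.0
        for idx in combinations(range(n_a + n_b), n_a):
            u = ranks[list(idx)].sum() - offset
            if abs(u - mid) >= dev_obs - 1e-12:
                count += 1
        return u_obs, count / total
    # tie-corrected normal approximation with continuity correction
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def pair_component_tests(
    pca: PCAPairResult, components: tuple[str, ...] = ("PC1", "PC2", "PC3")
) -> pd.DataFrame:
    """Mann-Whitney comparison of the two species on each component."""
    species = pca.scores["species"].unique()
    if len(species) != 2:
        raise InvalidArgumentError("scores must carry exactly two species")
    rows = []
    for pc in components:
        if pc not in pca.scores.columns:
            continue
        a = pca.scores.loc[pca.scores["species"] == species[0], pc].to_numpy()
        b = pca.scores.loc[pca.scores["species"] == species[1], pc].to_numpy()
        u, p = mann_whitney_pc(a, b)
        rows.append({"component": pc, "U": u, "p": p, "code": significance_code(p)})
    return pd.DataFrame(rows)
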
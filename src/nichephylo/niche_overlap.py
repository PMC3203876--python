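"""Niche overlap (Schoener's D, Hellinger-based I) and randomization tests.

Both metrics compare two suitability surfaces normalized to sum to 1 over
the study area:

    D = 1 - 0.5 * sum_i |p_i - q_i|
    I = 1 - 0.5 * sum_i (sqrt(p_i) - sqrt(q_i))^2

Each ranges from 0 (disjoint niches) to 1 (identical niches), and
I >= D always (the Hellinger/total-variation inequality).

The *identity test* asks whether two species' niches are equivalent: pool
their localities, re-partition at random into the original sample sizes,
rebuild both models, and compare the observed overlap to that null
(one-tailed low: a significantly *smaller* observed overlap rejects
equivalence).  The *background test* asks whether the observed overlap
differs from what models built on random draws from the sister species'
geographic background would give (two-tailed on the null's 2.5/97.5
percentiles), and is run in both directions for every pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .climate_niche import significance_code
from .containers import EnvStack, InvalidArgumentError, OccurrenceSet
from .enm_maxent import (
    FeatureSet,
    ModelSettings,
    NicheModel,
    build_features,
    fit_maxent,
    range_fallback_surface,
    sample_background,
)
from .geo_ranges import BufferRange

#: fewer unique localities than this and a species is represented by its
#: geographic range (uniform surface) instead of a fitted model
MIN_MODEL_POINTS = 5


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def normalize_surface(raw: np.ndarray) -> np.ndarray:
    """Divide a non-negative grid by its total so it sums to 1."""
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise InvalidArgumentError("surface must be non-negative")
    total = raw.sum()
    if total <= 0:
        raise InvalidArgumentError("all-zero surface cannot be normalized")
    return raw / total


def _check_pair(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise InvalidArgumentError("surfaces must share grid geometry")
    return p, q


def schoener_d(p: np.ndarray, q: np.ndarray) -> float:
    p, q = _check_pair(p, q)
    return float(1.0 - 0.5 * np.abs(p - q).sum())


def hellinger_i(p: np.ndarray, q: np.ndarray) -> float:
    p, q = _check_pair(p, q)
    return float(1.0 - 0.5 * ((np.sqrt(p) - np.sqrt(q)) ** 2).sum())


@dataclass
class OverlapStat:
    pair: tuple[str, str]
    D: float
    I: float


def overlap_stat(pair: tuple[str, str], p: np.ndarray, q: np.ndarray) -> OverlapStat:
    return OverlapStat(pair, schoener_d(p, q), hellinger_i(p, q))


@dataclass
class RandomizationResult:
    observed: OverlapStat
    null_D: np.ndarray
    null_I: np.ndarray
    test: str  # "identity" | "background"
    direction: str  # "pooled" | "<focal>_vs_<sister>_background"
    p_D: float
    p_I: float
    code_D: str
    code_I: str
    ci_D: tuple[float, float] | None = None
    ci_I: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# Model building helpers
# ---------------------------------------------------------------------------


def fit_species_surface(
    env: EnvStack,
    occ: OccurrenceSet,
    features: FeatureSet,
    settings: ModelSettings,
    fallback_range: BufferRange | None = None,
) -> np.ndarray:
    """Normalized suitability surface for one species.

    Species below the modelling threshold are represented by the uniform
    surface over their geographic range when one is supplied.
    """
    occ = occ if occ.deduplicated else occ.dedup()
    if len(occ) < MIN_MODEL_POINTS and fallback_range is not None:
        return range_fallback_surface(fallback_range, env).raw_surface
    model = fit_maxent(
        features, occ, settings.reg_multiplier, settings.max_iter, settings.tol
    )
    return model.raw_surface


def _fit_cells_surface(
    features: FeatureSet, cells: tuple[np.ndarray, np.ndarray], settings: ModelSettings
) -> np.ndarray:
    model = fit_maxent(
        features, cells, settings.reg_multiplier, settings.max_iter, settings.tol
    )
    return model.raw_surface


# ---------------------------------------------------------------------------
# Identity test
# ---------------------------------------------------------------------------


def identity_test(
    occ_a: OccurrenceSet,
    occ_b: OccurrenceSet,
    env: EnvStack,
    settings: ModelSettings | None = None,
    n_reps: int = 100,
    seed: int = 0,
    features: FeatureSet | None = None,
    fallback_ranges: dict[str, BufferRange] | None = None,
) -> RandomizationResult:
    """Niche-equivalence randomization test on pooled localities.

    The pooled localities are sorted into a canonical order before each
    seeded re-partition, so swapping the two species yields the same null
    sample.  p = (1 + #{null <= observed}) / (n_reps + 1), one-tailed low.
    """
    settings = settings or ModelSettings()
    occ_a, occ_b = occ_a.dedup(), occ_b.dedup()
    n_a, n_b = len(occ_a), len(occ_b)
    if n_a + n_b < 4:
        raise InvalidArgumentError("pooled localities must number at least 4")
    if features is None:
        brc = sample_background(env, settings.background_n, seed)
        features = build_features(env, settings.kinds, brc)
    fallback_ranges = fallback_ranges or {}

    surf_a = fit_species_surface(env, occ_a, features, settings, fallback_ranges.get(occ_a.species_id))
    surf_b = fit_species_surface(env, occ_b, features, settings, fallback_ranges.get(occ_b.species_id))
    observed = overlap_stat((occ_a.species_id, occ_b.species_id), surf_a, surf_b)

    pool = np.concatenate([occ_a.points, occ_b.points])
    order = np.lexsort((pool[:, 1], pool[:, 0]))
    pool = pool[order]  # canonical order: label-swap invariant
    rng = np.random.default_rng(seed)
    null_D = np.empty(n_reps)
    null_I = np.empty(n_reps)
    for r in range(n_reps):
        perm = rng.permutation(len(pool))
        pa = OccurrenceSet("nullA", pool[perm[:n_a]]).dedup()
        pb = OccurrenceSet("nullB", pool[perm[n_a:]]).dedup()
        sa = fit_species_surface(env, pa, features, settings)
        sb = fit_species_surface(env, pb, features, settings)
        null_D[r] = schoener_d(sa, sb)
        null_I[r] = hellinger_i(sa, sb)

    p_D = (1 + np.sum(null_D <= observed.D)) / (n_reps + 1)
    p_I = (1 + np.sum(null_I <= observed.I)) / (n_reps + 1)
    return RandomizationResult(
        observed=observed,
        null_D=null_D,
        null_I=null_I,
        test="identity",
        direction="pooled",
        p_D=float(p_D),
        p_I=float(p_I),
        code_D=significance_code(p_D),
        code_I=significance_code(p_I),
    )


# ---------------------------------------------------------------------------
# Background test
# ---------------------------------------------------------------------------


def cells_in_range(env: EnvStack, range_: BufferRange) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = env.unmasked_rc()
    xy = env.rc_to_xy(rows, cols)
    inside = range_.contains_points(xy)
    return rows[inside], cols[inside]


def background_test(
    focal_occ: OccurrenceSet,
    sister_occ: OccurrenceSet,
    sister_range: BufferRange,
    env: EnvStack,
    settings: ModelSettings | None = None,
    n_reps: int = 100,
    seed: int = 0,
    features: FeatureSet | None = None,
    fallback_ranges: dict[str, BufferRange] | None = None,
) -> RandomizationResult:
    """Background-similarity test of the focal niche vs the sister's range.

    Null models are fitted to n_sister cells drawn uniformly from within
    the sister's buffered range; two-tailed at the 2.5th/97.5th null
    percentiles.  "more"/"less" label observed overlap above/below the
    interval; stars come from the two-tailed pseudo-p.
    """
    settings = settings or ModelSettings()
    focal_occ, sister_occ = focal_occ.dedup(), sister_occ.dedup()
    n_sister = len(sister_occ)
    if features is None:
        brc = sample_background(env, settings.background_n, seed)
        features = build_features(env, settings.kinds, brc)
    fallback_ranges = fallback_ranges or {}

    rrows, rcols = cells_in_range(env, sister_range)
    if len(rrows) < max(n_sister, 2):
        raise InvalidArgumentError("sister range holds fewer cells than its sample size")

    focal_surf = fit_species_surface(
        env, focal_occ, features, settings, fallback_ranges.get(focal_occ.species_id)
    )
    sister_surf = fit_species_surface(
        env, sister_occ, features, settings, fallback_ranges.get(sister_occ.species_id)
    )
    observed = overlap_stat(
        (focal_occ.species_id, sister_occ.species_id), focal_surf, sister_surf
    )

    rng = np.random.default_rng(seed)
    n_draw = max(n_sister, 2)
    null_D = np.empty(n_reps)
    null_I = np.empty(n_reps)
    for r in range(n_reps):
        idx = rng.choice(len(rrows), size=n_draw, replace=False)
        surf = _fit_cells_surface(features, (rrows[idx], rcols[idx]), settings)
        null_D[r] = schoener_d(focal_surf, surf)
        null_I[r] = hellinger_i(focal_surf, surf)

    def summarize(obs: float, null: np.ndarray) -> tuple[float, str, tuple[float, float]]:
        lo, hi = np.percentile(null, [2.5, 97.5])
        n_ge = np.sum(null >= obs)
        n_le = np.sum(null <= obs)
        p = min(1.0, 2.0 * (1 + min(n_ge, n_le)) / (n_reps + 1))
        if obs > hi:
            label = "more"
        elif obs < lo:
            label = "less"
        else:
            return p, "NS", (float(lo), float(hi))
        stars = significance_code(p)
        return p, f"{label} {stars}" if stars != "NS" else "NS", (float(lo), float(hi))

    p_D, code_D, ci_D = summarize(observed.D, null_D)
    p_I, code_I, ci_I = summarize(observed.I, null_I)
    return RandomizationResult(
        observed=observed,
        null_D=null_D,
        null_I=null_I,
        test="background",
        direction=f"{focal_occ.species_id}_vs_{sister_occ.species_id}_background",
        p_D=p_D,
        p_I=p_I,
        code_D=code_D,
        code_I=code_I,
        ci_D=ci_D,
        ci_I=ci_I,
    )
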
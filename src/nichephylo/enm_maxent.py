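"""A minimal maximum-entropy (Maxent-style) suitability model.

The model fits an exponential-family (Gibbs) distribution over grid cells:
p(cell) is proportional to exp(lambda . f(cell)), where f are min-max
scaled linear and quadratic features of the environmental layers.  The
weights minimize the L1-regularized negative mean log-probability of the
presence cells,

    loss(lambda) = -mean_presence[lambda . f] + log Z(lambda)
                   + sum_j beta_j |lambda_j|,

with beta_j = reg_multiplier * sd_j(background) / sqrt(m) for m presence
points — the classic Maxent relaxation of the feature-expectation
constraints.  The problem is convex; it is solved by proximal-gradient
descent (ISTA) with Armijo backtracking, which decreases the objective
monotonically and shares its minimizers with any convex solver.

The feature family is fixed to linear + quadratic: it keeps the objective
small and convex while still allowing unimodal (bell-shaped) response
curves, which is what climatic suitability needs.  Hinge/threshold/product
features and Maxent's logistic calibration are deliberately omitted —
overlap statistics downstream use only the normalized raw surface, which a
monotone output transform cannot affect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EnvStack, InvalidArgumentError, OccurrenceSet

DEFAULT_BACKGROUND_N = 10_000
DEFAULT_REG_MULTIPLIER = 1.0
DEFAULT_MAX_ITER = 500
DEFAULT_TOL = 1e-6


class ModelFallbackError(RuntimeError):
    """Too few presences for a model; use range_fallback_surface instead."""


class EmptySurfaceError(ValueError):
    pass


@dataclass
class ModelSettings:
    """Fitting knobs shared by every model-building call."""

    background_n: int = DEFAULT_BACKGROUND_N
    reg_multiplier: float = DEFAULT_REG_MULTIPLIER
    max_iter: int = DEFAULT_MAX_ITER
    tol: float = DEFAULT_TOL
    n_reps: int = 100
    train_frac: float = 0.75
    kinds: tuple[str, ...] = ("linear", "quadratic")


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


@dataclass
class FeatureSet:
    """Min-max scaled features anchored to a background cell sample."""

    env: EnvStack
    definitions: list[tuple[str, str]]  # (layer, kind in {linear, quadratic})
    scaling: dict[str, tuple[float, float]]  # layer -> (min, max) on background
    background_rc: tuple[np.ndarray, np.ndarray]

    @property
    def n_features(self) -> int:
        return len(self.definitions)

    def _scaled_layer(self, layer: str, values: np.ndarray) -> np.ndarray:
        lo, hi = self.scaling[layer]
        return np.clip((values - lo) / (hi - lo), 0.0, 1.0)

    def matrix(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        """Feature matrix (n_cells, n_features) at the given cells."""
        raw = {
            layer: self.env.layer(layer)[row, col]
            for layer in {l for l, _ in self.definitions}
        }
        cols = []
        for layer, kind in self.definitions:
            s = self._scaled_layer(layer, raw[layer])
            cols.append(s if kind == "linear" else s**2)
        if not cols:
            return np.zeros((len(row), 0))
        return np.column_stack(cols)

    def restrict(self, layers: list[str]) -> "FeatureSet":
        """A feature subset over the named layers (same scaling/background)."""
        defs = [(l, k) for l, k in self.definitions if l in layers]
        return FeatureSet(self.env, defs, self.scaling, self.background_rc)


def sample_background(
    env: EnvStack, n: int = DEFAULT_BACKGROUND_N, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform sample of up to ``n`` unmasked cells (without replacement)."""
    rows, cols = env.unmasked_rc()
    total = len(rows)
    if total <= n:
        return rows, cols
    idx = np.random.default_rng(seed).choice(total, size=n, replace=False)
    return rows[idx], cols[idx]


def build_features(
    env: EnvStack,
    kinds: tuple[str, ...] = ("linear", "quadratic"),
    background_cells: tuple[np.ndarray, np.ndarray] | None = None,
) -> FeatureSet:
    """Scale each layer to [0, 1] on the background; derive feature columns.

    Layers constant on the background carry no information and are dropped
    with a warning.
    """
    bad = set(kinds) - {"linear", "quadratic"}
    if bad:
        raise InvalidArgumentError(f"unknown feature kinds: {sorted(bad)}")
    if background_cells is None:
        background_cells = env.unmasked_rc()
    brow, bcol = background_cells
    if len(brow) == 0:
        raise InvalidArgumentError("background must be non-empty")
    scaling, defs = {}, []
    for layer in env.layer_names:
        vals = env.layer(layer)[brow, bcol]
        lo, hi = float(vals.min()), float(vals.max())
        if hi <= lo:
            warnings.warn(f"layer {layer} is constant on the background; dropped")
            continue
        scaling[layer] = (lo, hi)
        for kind in ("linear", "quadratic"):
            if kind in kinds:
                defs.append((layer, kind))
    return FeatureSet(env, defs, scaling, (brow, bcol))


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------


@dataclass
class NicheModel:
    """Fitted weights plus the suitability surface they induce.

    ``raw_surface`` is a full grid, zero on nodata cells, normalized so the
    unmasked cells sum to 1; ``logistic_surface`` is a monotone [0, 1]
    rescaling for display only.
    """

    weights: np.ndarray
    feature_definitions: list[tuple[str, str]]
    raw_surface: np.ndarray
    training_gain: float
    converged: bool = True
    objective_path: np.ndarray | None = None
    replicate_sd: np.ndarray | None = None

    @property
    def logistic_surface(self) -> np.ndarray:
        peak = self.raw_surface.max()
        return self.raw_surface / peak if peak > 0 else self.raw_surface


def _presence_cells(
    env: EnvStack, presences: OccurrenceSet | tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(presences, OccurrenceSet):
        return env.xy_to_rc(presences.points)
    return presences


def _raw_surface(env: EnvStack, features: FeatureSet, lam: np.ndarray) -> np.ndarray:
    rows, cols = env.unmasked_rc()
    F = features.matrix(rows, cols)
    eta = F @ lam if lam.size else np.zeros(len(rows))
    eta -= eta.max()
    p = np.exp(eta)
    p /= p.sum()
    grid = np.zeros(env.shape)
    grid[rows, cols] = p
    return grid


def fit_maxent(
    features: FeatureSet,
    presences: OccurrenceSet | tuple[np.ndarray, np.ndarray],
    reg_multiplier: float = DEFAULT_REG_MULTIPLIER,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> NicheModel:
    """Fit the L1-penalized maximum-entropy weights.

    The normalizer during optimization runs over the background sample plus
    the presence cells; the returned surface re-evaluates the fitted
    weights on every unmasked cell of the grid.
    """
    env = features.env
    prow, pcol = _presence_cells(env, presences)
    if len(prow) < 2:
        raise ModelFallbackError("need at least 2 presence cells")
    m = len(prow)

    brow, bcol = features.background_rc
    # support of the optimization distribution: background plus presences
    srow = np.concatenate([brow, prow])
    scol = np.concatenate([bcol, pcol])
    uniq = np.unique(np.column_stack([srow, scol]), axis=0)
    srow, scol = uniq[:, 0], uniq[:, 1]

    Fp = features.matrix(prow, pcol)
    Fs = features.matrix(srow, scol)
    k = features.n_features
    if k == 0:
        surface = _raw_surface(env, features, np.zeros(0))
        return NicheModel(np.zeros(0), [], surface, 0.0, True, np.zeros(1))

    Fb = features.matrix(brow, bcol)
    beta = reg_multiplier * Fb.std(axis=0, ddof=0) / np.sqrt(m)
    beta = np.maximum(beta, 1e-12)
    fbar = Fp.mean(axis=0)

    def smooth_parts(lam: np.ndarray) -> tuple[float, np.ndarray]:
        eta = Fs @ lam
        shift = eta.max()
        w = np.exp(eta - shift)
        z = w.sum()
        loss = -fbar @ lam + shift + np.log(z)
        p = w / z
        grad = Fs.T @ p - fbar
        return loss, grad

    lam = np.zeros(k)
    sm, grad = smooth_parts(lam)
    obj = sm + beta @ np.abs(lam)
    path = [obj]
    L = 1.0
    converged = False
    for _ in range(max_iter):
        # backtracking proximal step
        while True:
            cand = lam - grad / L
            cand = np.sign(cand) * np.maximum(np.abs(cand) - beta / L, 0.0)
            step = cand - lam
            sm_new, grad_new = smooth_parts(cand)
            if sm_new <= sm + grad @ step + 0.5 * L * step @ step + 1e-12:
                break
            L *= 2.0
        new_obj = sm_new + beta @ np.abs(cand)
        delta = obj - new_obj
        lam, sm, grad, obj = cand, sm_new, grad_new, new_obj
        path.append(obj)
        L = max(L * 0.9, 1e-3)
        if 0 <= delta < tol:
            converged = True
            break

    surface = _raw_surface(env, features, lam)
    n_cells = int((~env.nodata_mask).sum())
    gain = float(np.mean(np.log(surface[prow, pcol])) + np.log(n_cells))
    return NicheModel(lam, list(features.definitions), surface, max(gain, 0.0), converged, np.array(path))


def regularized_objective(
    features: FeatureSet,
    presences: OccurrenceSet | tuple[np.ndarray, np.ndarray],
    lam: np.ndarray,
    reg_multiplier: float = DEFAULT_REG_MULTIPLIER,
) -> float:
    """Evaluate the fitting objective at arbitrary weights (for cross-checks)."""
    env = features.env
    prow, pcol = _presence_cells(env, presences)
    brow, bcol = features.background_rc
    srow = np.concatenate([brow, prow])
    scol = np.concatenate([bcol, pcol])
    uniq = np.unique(np.column_stack([srow, scol]), axis=0)
    Fs = features.matrix(uniq[:, 0], uniq[:, 1])
    Fp = features.matrix(prow, pcol)
    Fb = features.matrix(brow, bcol)
    beta = np.maximum(
        reg_multiplier * Fb.std(axis=0, ddof=0) / np.sqrt(len(prow)), 1e-12
    )
    eta = Fs @ lam
    shift = eta.max()
    return float(
        -Fp.mean(axis=0) @ lam + shift + np.log(np.exp(eta - shift).sum()) + beta @ np.abs(lam)
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class ModelEval:
    auc: float
    auc_sd: float | None
    n_train: int
    n_test: int


def auc(
    model: NicheModel,
    test_presences: tuple[np.ndarray, np.ndarray],
    background: tuple[np.ndarray, np.ndarray],
) -> float:
    """Rank AUC: P(random presence outscores random background), ties 1/2."""
    ps = model.raw_surface[test_presences]
    bs = model.raw_surface[background]
    if len(ps) == 0 or len(bs) == 0:
        raise InvalidArgumentError("both cell sets must be non-empty")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([ps, bs]))
    u = ranks[: len(ps)].sum() - len(ps) * (len(ps) + 1) / 2.0
    return float(u / (len(ps) * len(bs)))


MIN_PRESENCES_FOR_SD = 8


def replicate_models(
    features: FeatureSet,
    presences: OccurrenceSet | tuple[np.ndarray, np.ndarray],
    n_reps: int = 100,
    train_frac: float = 0.75,
    seed: int = 0,
    reg_multiplier: float = DEFAULT_REG_MULTIPLIER,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> tuple[NicheModel, ModelEval]:
    """Bootstrap-replicate fitting with train/test AUC evaluation.

    Each replicate takes a fresh random train/test partition, bootstraps
    the training presences with replacement, fits, and scores AUC on the
    held-out cells against the background.  The averaged raw surface is
    renormalized to sum 1.  A per-cell SD grid is only produced when the
    presence count reaches 8; below that a single training partition
    leaves nothing to estimate spread from.
    """
    env = features.env
    prow, pcol = _presence_cells(env, presences)
    m = len(prow)
    if m < 2:
        raise ModelFallbackError("need at least 2 presence cells")
    rng = np.random.default_rng(seed)
    n_train = max(2, int(round(train_frac * m)))
    if m >= 3:
        n_train = min(n_train, m - 1)  # keep at least one test point
    else:
        n_train = m
    surfaces = []
    aucs = []
    for _ in range(n_reps):
        perm = rng.permutation(m)
        train, test = perm[:n_train], perm[n_train:]
        boot = rng.choice(train, size=len(train), replace=True)
        model = fit_maxent(
            features, (prow[boot], pcol[boot]), reg_multiplier, max_iter, tol
        )
        surfaces.append(model.raw_surface)
        if len(test) > 0:
            aucs.append(auc(model, (prow[test], pcol[test]), features.background_rc))
    stack = np.array(surfaces)
    mean_surface = stack.mean(axis=0)
    total = mean_surface[~env.nodata_mask].sum()
    mean_surface = np.where(~env.nodata_mask, mean_surface / total, 0.0)
    sd_grid = stack.std(axis=0, ddof=0) if m >= MIN_PRESENCES_FOR_SD else None
    final = fit_maxent(features, (prow, pcol), reg_multiplier, max_iter, tol)
    avg = NicheModel(
        final.weights,
        list(features.definitions),
        mean_surface,
        final.training_gain,
        final.converged,
        final.objective_path,
        replicate_sd=sd_grid,
    )
    ev = ModelEval(
        auc=float(np.mean(aucs)) if aucs else float("nan"),
        auc_sd=float(np.std(aucs, ddof=0)) if (aucs and m >= MIN_PRESENCES_FOR_SD) else None,
        n_train=n_train,
        n_test=m - n_train,
    )
    return avg, ev


def jackknife_contribution(
    features: FeatureSet,
    presences: OccurrenceSet | tuple[np.ndarray, np.ndarray],
    reg_multiplier: float = DEFAULT_REG_MULTIPLIER,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> pd.DataFrame:
    """Training gain with each layer alone and with each layer excluded.

    The layer whose with-only-this-layer gain is highest is the
    conventional "top variable" of a jackknife report.
    """
    layers = sorted({l for l, _ in features.definitions})
    if len(layers) < 2:
        raise InvalidArgumentError("jackknife needs at least 2 layers")
    rows = []
    for layer in layers:
        only = fit_maxent(features.restrict([layer]), presences, reg_multiplier, max_iter, tol)
        rest = fit_maxent(
            features.restrict([l for l in layers if l != layer]),
            presences,
            reg_multiplier,
            max_iter,
            tol,
        )
        rows.append(
            {"layer": layer, "gain_alone": only.training_gain, "gain_without": rest.training_gain}
        )
    df = pd.DataFrame(rows)
    df.attrs["top_layer"] = df.loc[df["gain_alone"].idxmax(), "layer"]
    return df


def range_fallback_surface(range_, env: EnvStack) -> NicheModel:
    """Uniform suitability over the cells of a geographic range.

    Stand-in surface for species with too few localities to model: raw
    probability 1/k on each of the k unmasked cells whose centers fall
    inside the range geometry, zero elsewhere.
    """
    rows, cols = env.unmasked_rc()
    xy = env.rc_to_xy(rows, cols)
    inside = range_.contains_points(xy)
    k = int(inside.sum())
    if k == 0:
        raise EmptySurfaceError("no grid cells inside the range")
    grid = np.zeros(env.shape)
    grid[rows[inside], cols[inside]] = 1.0 / k
    return NicheModel(np.zeros(0), [], grid, 0.0, True, None)
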
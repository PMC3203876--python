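"""Phylogenetic signal of continuous niche variables: QVI and Blomberg's K.

QVI (quantitative convergence index) rescales the linear-parsimony cost of
a continuous trait on a tree between its theoretical extremes:

    QVI = (Obs - Min) / (Max - Min)

with Obs the minimal total |child - parent| change over internal-node
assignments, Min = max(x) - min(x) (the unavoidable change), and
Max = sum_i |x_i - median(x)| (the star-tree cost).  QVI = 0 when
trait-similar species are sisters, 1 when they are phylogenetically
scattered.  Branch lengths are ignored (a retention-index analogue);
significance comes from tip randomizations across a posterior tree sample.

Blomberg's K compares the observed ratio of trait variance to
phylogenetically corrected variance against its Brownian-motion
expectation on the same tree; K = 1 under BM, K > 1 means stronger
clustering than BM predicts.  Significance comes from tip shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .containers import Chronogram, InvalidArgumentError


# ---------------------------------------------------------------------------
# Linear parsimony
# ---------------------------------------------------------------------------


def _tree_struct(tree: dendropy.Tree) -> tuple[list[tuple[int, list[int]]], dict[str, int]]:
    """Postorder node list as (node_slot, child_slots); tips map to slots."""
    slots: dict[int, int] = {}
    order: list[tuple[int, list[int]]] = []
    tip_slot: dict[str, int] = {}
    for node in tree.postorder_node_iter():
        slot = len(slots)
        slots[id(node)] = slot
        if node.is_leaf():
            tip_slot[node.taxon.label] = slot
            order.append((slot, []))
        else:
            order.append((slot, [slots[id(c)] for c in node.child_nodes()]))
    return order, tip_slot


def _sankoff_cost(
    order: list[tuple[int, list[int]]],
    tip_slot: dict[str, int],
    x: dict[str, float],
) -> float:
    """Exact L1 parsimony cost by Sankoff DP over candidate states.

    An optimal linear-parsimony reconstruction always exists with internal
    states drawn from the tip values, so the DP over that finite state set
    is exact.
    """
    states = np.unique(np.array([x[t] for t in tip_slot], dtype=float))
    S = len(states)
    absdiff = np.abs(states[:, None] - states[None, :])
    cost = np.zeros((len(order), S))
    for label, slot in tip_slot.items():
        leaf_cost = np.full(S, np.inf)
        leaf_cost[np.searchsorted(states, x[label])] = 0.0
        cost[slot] = leaf_cost
    for slot, children in order:  # postorder: children precede parents
        if children:
            total = np.zeros(S)
            for c in children:
                total += np.min(cost[c][None, :] + absdiff, axis=1)
            cost[slot] = total
    root_slot = order[-1][0]
    return float(cost[root_slot].min())


def l1_parsimony_cost(tree: Chronogram | dendropy.Tree, x: dict[str, float]) -> float:
    """Minimal total |child - parent| trait change over the tree."""
    t = tree.tree if isinstance(tree, Chronogram) else tree
    order, tip_slot = _tree_struct(t)
    missing = set(tip_slot) - set(x)
    if missing:
        raise InvalidArgumentError(f"tips without trait values: {sorted(missing)}")
    return _sankoff_cost(order, tip_slot, x)


def qvi(tree: Chronogram | dendropy.Tree, x: dict[str, float]) -> float:
    """Quantitative convergence index in [0, 1]; 0 for a constant trait."""
    vals = np.array(list(x.values()), dtype=float)
    rng_ = vals.max() - vals.min()
    if rng_ == 0:
        return 0.0
    max_cost = np.abs(vals - np.median(vals)).sum()
    obs = l1_parsimony_cost(tree, x)
    if max_cost - rng_ <= 0:
        return 0.0
    return float((obs - rng_) / (max_cost - rng_))


def qvi_posterior_test(
    chron: Chronogram,
    x: dict[str, float],
    n_rand: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
    max_posterior: int = 1000,
) -> tuple[float, float, bool, np.ndarray]:
    """Mean QVI over a posterior tree sample against a tip-shuffle null.

    The observed statistic is the mean QVI across (up to ``max_posterior``
    randomly chosen) posterior trees; each null replicate shuffles the tip
    values on a randomly drawn posterior tree.  The trait shows signal
    when the observed mean falls below the null's ``alpha`` quantile.
    Returns (mean_QVI, mean_QVI_random, significant, null_values).
    """
    rng = np.random.default_rng(seed)
    trees = chron.posterior_sample or [chron.tree]
    if len(trees) > max_posterior:
        pick = rng.choice(len(trees), size=max_posterior, replace=False)
        trees = [trees[i] for i in pick]
    structs = [_tree_struct(t) for t in trees]
    labels = sorted(x)
    vals = np.array([x[l] for l in labels], dtype=float)

    def _qvi(order, tip_slot, values: np.ndarray) -> float:
        xv = dict(zip(labels, values))
        rng_ = values.max() - values.min()
        if rng_ == 0:
            return 0.0
        max_cost = np.abs(values - np.median(values)).sum()
        if max_cost - rng_ <= 0:
            return 0.0
        return (_sankoff_cost(order, tip_slot, xv) - rng_) / (max_cost - rng_)

    observed = float(np.mean([_qvi(o, ts, vals) for o, ts in structs]))
    null = np.empty(n_rand)
    for r in range(n_rand):
        o, ts = structs[rng.integers(len(structs))]
        null[r] = _qvi(o, ts, rng.permutation(vals))
    significant = observed < np.quantile(null, alpha)
    return observed, float(null.mean()), bool(significant), null


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------


@dataclass
class BMContext:
    """Precomputed pieces of the K statistic for one tree."""

    labels: list[str]
    V: np.ndarray
    Vinv: np.ndarray
    ones_Vinv: np.ndarray
    denom: float  # 1' Vinv 1
    expected_ratio: float

    @classmethod
    def from_tree(cls, chron: Chronogram) -> "BMContext":
        labels, V = chron.vcv()
        n = len(labels)
        if n < 4:
            raise InvalidArgumentError("K needs at least 4 tips")
        try:
            Vinv = np.linalg.inv(V)
        except np.linalg.LinAlgError as exc:
            raise InvalidArgumentError("singular BM covariance (bad tree)") from exc
        ones = np.ones(n)
        ones_Vinv = ones @ Vinv
        denom = float(ones_Vinv @ ones)
        expected = (np.trace(V) - n / denom) / (n - 1)
        return cls(labels, V, Vinv, ones_Vinv, denom, float(expected))

    def k(self, x: np.ndarray) -> float:
        """K for trait values aligned with ``labels``."""
        n = len(x)
        ahat = float(self.ones_Vinv @ x) / self.denom
        d = x - ahat
        mse0 = d @ d / (n - 1)
        mse = d @ self.Vinv @ d / (n - 1)
        if mse <= 0:
            raise InvalidArgumentError("degenerate (constant) trait")
        return float((mse0 / mse) / self.expected_ratio)


def blomberg_k(chron: Chronogram, x: dict[str, float]) -> float:
    """Blomberg's K of a continuous trait on an ultrametric tree."""
    ctx = BMContext.from_tree(chron)
    vals = np.array([x[l] for l in ctx.labels], dtype=float)
    return ctx.k(vals)


def k_randomization_test(
    chron: Chronogram, x: dict[str, float], n_rand: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Tip-shuffle significance of K: p = (1 + #{K_shuf >= K_obs}) / (n + 1)."""
    ctx = BMContext.from_tree(chron)
    vals = np.array([x[l] for l in ctx.labels], dtype=float)
    k_obs = ctx.k(vals)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_rand):
        if ctx.k(rng.permutation(vals)) >= k_obs:
            count += 1
    return k_obs, (1 + count) / (n_rand + 1)


# ---------------------------------------------------------------------------
# Per-variable signal table
# ---------------------------------------------------------------------------


@dataclass
class SignalResult:
    variable: str
    mean_qvi: float
    mean_qvi_random: float
    qvi_significant: bool
    k: float
    k_p: float


def signal_table(
    chron: Chronogram,
    traits: pd.DataFrame,
    n_rand: int = 1000,
    n_k_rand: int = 999,
    seed: int = 0,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-variable phylogenetic-signal summary (QVI and K columns).

    ``traits`` has one row per species (index = tip labels) and one column
    per variable.  Constant variables get QVI = 0 and a flagged, skipped K.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for var, child in zip(traits.columns, ss.spawn(len(traits.columns))):
        x = traits[var].to_dict()
        s1, s2 = child.spawn(2)
        vals = np.array(list(x.values()))
        if vals.max() == vals.min():
            rows.append(SignalResult(var, 0.0, 0.0, False, float("nan"), float("nan")))
            continue
        mean_qvi, mean_rand, sig, _ = qvi_posterior_test(
            chron, x, n_rand=n_rand, seed=s1.generate_state(1)[0] % (2**31), alpha=alpha
        )
        k_obs, k_p = k_randomization_test(
            chron, x, n_rand=n_k_rand, seed=s2.generate_state(1)[0] % (2**31)
        )
        rows.append(SignalResult(var, mean_qvi, mean_rand, sig, k_obs, k_p))
    return pd.DataFrame([r.__dict__ for r in rows])
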
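"""Synthetic inputs: climate-like rasters, occurrences, trees, study fixture.

The generators replace field inputs the pipeline would otherwise need —
bioclim-style raster layers, herbarium localities, and a dated phylogeny —
with controlled equivalents whose ground truth is known, so every
downstream statistic can be tested for parameter recovery and calibration.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import Chronogram, EnvStack, InvalidArgumentError, OccurrenceSet


@dataclass
class TrueNiche:
    """Ground-truth Gaussian niche in environment space.

    ``optimum`` and ``breadth`` are vectors over the stack's layers;
    suitability of a cell is exp(-0.5 * sum(((env - optimum) / breadth)^2)).
    """

    optimum: np.ndarray
    breadth: np.ndarray

    def __post_init__(self) -> None:
        self.optimum = np.atleast_1d(np.asarray(self.optimum, dtype=float))
        self.breadth = np.atleast_1d(np.asarray(self.breadth, dtype=float))
        if self.breadth.shape != self.optimum.shape:
            raise InvalidArgumentError("optimum and breadth must have equal length")
        if np.any(self.breadth <= 0):
            raise InvalidArgumentError("breadth must be strictly positive")


# ---------------------------------------------------------------------------
# Environmental layers
# ---------------------------------------------------------------------------


def generate_env_stack(
    n_layers: int,
    shape: tuple[int, int],
    corr_length_km: float = 10.0,
    inter_layer_corr: float = 0.0,
    cell_size_km: float = 1.0,
    seed: int = 0,
) -> EnvStack:
    """Gaussian random field layers with controlled correlation structure.

    Each layer is white noise smoothed by a Gaussian kernel of scale
    ``corr_length_km`` (spatial autocorrelation) and standardized to zero
    mean / unit variance.  Pairwise inter-layer correlation near
    ``inter_layer_corr`` is induced by mixing one shared field with
    per-layer private fields.  Negative target correlation is only
    achievable for two layers (a set of three or more fields cannot all be
    mutually negatively correlated at arbitrary strength).
    """
    rows, cols = shape
    if rows <= 0 or cols <= 0 or cell_size_km <= 0:
        raise InvalidArgumentError("shape and cell size must be positive")
    if n_layers < 1:
        raise InvalidArgumentError("n_layers must be >= 1")
    if corr_length_km < 0:
        raise InvalidArgumentError("corr_length_km must be >= 0")
    if not -1.0 <= inter_layer_corr <= 1.0:
        raise InvalidArgumentError("inter_layer_corr must be in [-1, 1]")
    if inter_layer_corr < 0 and n_layers > 2:
        raise InvalidArgumentError(
            "negative inter-layer correlation is only supported for 2 layers"
        )

    rng = np.random.default_rng(seed)
    shared = rng.standard_normal(shape)
    rho = inter_layer_corr
    a = np.sqrt(abs(rho))
    b = np.sqrt(1.0 - abs(rho))
    layers = np.empty((n_layers, rows, cols))
    for i in range(n_layers):
        private = rng.standard_normal(shape)
        sign = -1.0 if (rho < 0 and i == 1) else 1.0
        field = sign * a * shared + b * private
        if corr_length_km > 0:
            field = ndimage.gaussian_filter(field, sigma=corr_length_km / cell_size_km)
        field = (field - field.mean()) / field.std()
        layers[i] = field
    names = [f"env{i + 1}" for i in range(n_layers)]
    return EnvStack(layer_names=names, data=layers, cell_size_km=cell_size_km)


# ---------------------------------------------------------------------------
# Occurrences from a known niche
# ---------------------------------------------------------------------------


def suitability_grid(env: EnvStack, niche: TrueNiche) -> np.ndarray:
    """Analytic suitability of every cell (0 on nodata cells)."""
    if niche.optimum.shape[0] != env.n_layers:
        raise InvalidArgumentError("niche dimension must equal the layer count")
    z = (env.data - niche.optimum[:, None, None]) / niche.breadth[:, None, None]
    suit = np.exp(-0.5 * np.sum(z**2, axis=0))
    suit[env.nodata_mask] = 0.0
    return suit


def sample_cells(
    env: EnvStack, niche: TrueNiche, n_draws: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw cells (with replacement) with probability prop. to suitability."""
    if n_draws < 1:
        raise InvalidArgumentError("n_draws must be >= 1")
    suit = suitability_grid(env, niche)
    probs = suit[~env.nodata_mask]
    total = probs.sum()
    if total <= 0:
        raise InvalidArgumentError("suitability vanishes on every unmasked cell")
    rng = np.random.default_rng(seed)
    rows, cols = env.unmasked_rc()
    draws = rng.choice(len(probs), size=n_draws, replace=True, p=probs / total)
    return rows[draws], cols[draws]


def simulate_species(
    env: EnvStack,
    niche: TrueNiche,
    n_points: int,
    seed: int = 0,
    species_id: str = "species",
) -> OccurrenceSet:
    """Sample occurrence cells with probability proportional to suitability.

    Points are cell centers; the returned set is deduplicated, so it can
    hold fewer than ``n_points`` localities when draws repeat cells.
    """
    rows, cols = sample_cells(env, niche, n_points, seed)
    xy = env.rc_to_xy(rows, cols)
    return OccurrenceSet(species_id, xy).dedup()


def simulate_clade(
    tree: Chronogram,
    sigma2: float,
    root_optimum: np.ndarray,
    env: EnvStack,
    n_points_per_tip: int,
    seed: int = 0,
    breadth: float | np.ndarray = 1.0,
) -> dict[str, tuple[TrueNiche, OccurrenceSet]]:
    """Evolve tip niche optima by Brownian motion, then sample occurrences.

    ``sigma2`` is the BM rate per Ma per layer; ``breadth`` (scalar or
    per-layer) is shared by all tips.  One sub-seed per tip keeps the
    output deterministic and independent of traversal details.
    """
    if sigma2 < 0:
        raise InvalidArgumentError("sigma2 must be >= 0")
    root_optimum = np.atleast_1d(np.asarray(root_optimum, dtype=float))
    if root_optimum.shape[0] != env.n_layers:
        raise InvalidArgumentError("root_optimum dimension must equal the layer count")
    breadth_vec = np.broadcast_to(np.atleast_1d(breadth), root_optimum.shape).astype(float)

    ss = np.random.SeedSequence(seed)
    bm_seed, occ_seed = ss.spawn(2)
    optima = tree.simulate_bm(sigma2, root_optimum, np.random.default_rng(bm_seed))
    out: dict[str, tuple[TrueNiche, OccurrenceSet]] = {}
    tip_seeds = occ_seed.spawn(len(optima))
    for (label, opt), child in zip(sorted(optima.items()), tip_seeds):
        niche = TrueNiche(optimum=opt, breadth=breadth_vec.copy())
        occ = simulate_species(
            env, niche, n_points_per_tip, seed=child.generate_state(1)[0] % (2**31), species_id=label
        )
        out[label] = (niche, occ)
    return out


def jitter_posterior(
    chron: Chronogram, n_trees: int, sigma: float = 0.1, seed: int = 0
) -> Chronogram:
    """Emulate a posterior tree sample by multiplicative lognormal age jitter.

    Node ages are perturbed root-down by lognormal(0, sigma) factors,
    clipped so every child stays younger than its parent; topology is
    unchanged.  Returns a new chronogram carrying the sample.
    """
    rng = np.random.default_rng(seed)
    posterior = []
    for _ in range(n_trees):
        t = chron.tree.clone(depth=1)
        ages: dict[int, float] = {}
        for node in t.preorder_node_iter():
            if node.is_leaf():
                ages[id(node)] = 0.0
                continue
            jittered = node.age * rng.lognormal(0.0, sigma)
            if node.parent_node is not None:
                jittered = min(jittered, ages[id(node.parent_node)] * 0.999)
            ages[id(node)] = jittered
        for node in t.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = ages[id(node.parent_node)] - ages[id(node)]
        posterior.append(t)
    return Chronogram(tree=chron.tree.clone(depth=1), posterior_sample=posterior)


def random_ultrametric_tree(
    n_tips: int, seed: int = 0, mean_depth_ma: float = 10.0, prefix: str = "sp"
) -> Chronogram:
    """Random coalescent-style ultrametric tree with ages scaled to Ma.

    Lineages merge pairwise at exponentially spaced times; node depths are
    rescaled so the root age equals ``mean_depth_ma``.
    """
    if n_tips < 2:
        raise InvalidArgumentError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    nodes = [(f"{prefix}{i + 1}", 0.0) for i in range(n_tips)]  # (newick, age)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (nwk_j, age_j) = nodes.pop(j)
        (nwk_i, age_i) = nodes.pop(i)
        merged = f"({nwk_i}:{t - age_i:.10g},{nwk_j}:{t - age_j:.10g})"
        nodes.append((merged, t))
    newick, root_age = nodes[0]
    scale = mean_depth_ma / root_age
    chron = Chronogram.from_newick(newick + ";")
    for edge in chron.tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return Chronogram(tree=chron.tree)


# ---------------------------------------------------------------------------
# Study fixture: two African tree genera, 27 sampled species
# ---------------------------------------------------------------------------

# Topology constraints fixed by the study: the 11 sister pairs (one
# unresolved trio kept as a polytomy), a monophyletic Malagasy clade, the
# 14.9 Ma crown age, and the pair MRCA ages.  Deeper node ages are not
# printed anywhere and are synthetic interpolations chosen to keep the
# tree ultrametric; they carry no analysis weight (pair ages come from the
# pair table).
STUDY_TREE_NEWICK = (
    "(((Isolona_capuronii:4.0,(Isolona_ghesquierei:2.0,Isolona_perrierii:2.0):2.0):8.0,"
    "(((Isolona_congolana:6.0,Isolona_hexaloba:6.0):2.0,"
    "(Isolona_pleurocarpa:4.5,Isolona_zenkeri:4.5):3.5):2.0,"
    "(Isolona_cauliflora:9.0,((Isolona_dewevrei:2.5,Isolona_thonneri:2.5):4.5,"
    "((Isolona_heinsenii:2.6,Isolona_linearis:2.6):2.4,"
    "(Isolona_campanulata:2.8,Isolona_cooperi:2.8):2.2):2.0):2.0):1.0):2.0):2.9,"
    "((Monodora_angolensis:9.0,((Monodora_laurentii:2.4,Monodora_myristica:2.4,"
    "Monodora_undulata:2.4):3.6,(Monodora_crispata:3.8,Monodora_tenuifolia:3.8):2.2):3.0):2.0,"
    "(Monodora_grandidieri:8.0,(Monodora_minor:7.0,(Monodora_globiflora:6.0,"
    "((Monodora_carolinae:2.6,Monodora_stenopetala:2.6):1.4,"
    "(Monodora_hastipetala:1.5,Monodora_junodii:1.5):2.5):2.0):1.0):1.0):3.0):3.9);"
)

MALAGASY_CLADE = ["Isolona_capuronii", "Isolona_ghesquierei", "Isolona_perrierii"]

# species_a, species_b, genus, % geographic overlap, smaller-range species,
# mean MRCA age (Ma) — the published sister-pair comparison table.
_PAIR_ROWS = [
    ("Isolona_pleurocarpa", "Isolona_zenkeri", "Isolona", 19.6, "Isolona_pleurocarpa", 4.5),
    ("Isolona_dewevrei", "Isolona_thonneri", "Isolona", 8.9, "Isolona_dewevrei", 2.5),
    ("Isolona_heinsenii", "Isolona_linearis", "Isolona", 32.0, "Isolona_linearis", 2.6),
    ("Isolona_campanulata", "Isolona_cooperi", "Isolona", 16.0, "Isolona_cooperi", 2.8),
    ("Isolona_congolana", "Isolona_hexaloba", "Isolona", 12.6, "Isolona_congolana", 6.0),
    ("Monodora_carolinae", "Monodora_stenopetala", "Monodora", 0.0, "no overlap", 2.6),
    ("Monodora_hastipetala", "Monodora_junodii", "Monodora", 89.3, "Monodora_hastipetala", 1.5),
    ("Monodora_laurentii", "Monodora_myristica", "Monodora", 14.3, "Monodora_laurentii", 2.4),
    ("Monodora_myristica", "Monodora_undulata", "Monodora", 35.7, "Monodora_undulata", 1.6),
    ("Monodora_crispata", "Monodora_tenuifolia", "Monodora", 43.0, "Monodora_crispata", 3.8),
    ("Monodora_laurentii", "Monodora_undulata", "Monodora", 0.0, "no overlap", 2.4),
]


def study_fixture() -> tuple[Chronogram, pd.DataFrame]:
    """The study system: 27-species chronogram and the 11 sister-pair table.

    The pair table columns are species_a, species_b, genus, overlap_pct,
    smaller_range_species, mrca_age_ma.  Ages and overlaps transcribe the
    published comparison table; the chronogram encodes the sampled
    topology with the unresolved trio as a polytomy.
    """
    chron = Chronogram.from_newick(STUDY_TREE_NEWICK)
    table = pd.DataFrame(
        _PAIR_ROWS,
        columns=[
            "species_a",
            "species_b",
            "genus",
            "overlap_pct",
            "smaller_range_species",
            "mrca_age_ma",
        ],
    )
    return chron, table
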
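"""Core data containers shared across the pipeline.

Everything lives on a planar km grid: an :class:`EnvStack` of environmental
layers, per-species :class:`OccurrenceSet` localities, and a time-calibrated
:class:`Chronogram`.  Geographic (lon/lat) inputs are converted once, up
front, by :func:`nichephylo.geo_ranges.project_lonlat`.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd


class InvalidArgumentError(ValueError):
    """Raised when an operation's preconditions are violated."""


# ---------------------------------------------------------------------------
# Environmental grid stack
# ---------------------------------------------------------------------------


@dataclass
class EnvStack:
    """A stack of co-registered environmental layers on a planar km grid.

    ``data`` has shape ``(n_layers, rows, cols)``.  Row 0 is the *bottom*
    row: the cell (0, 0) has its lower-left corner at ``origin`` and its
    center at ``origin + cell_size_km / 2``.  ``nodata_mask`` is True on
    cells excluded from every analysis (shared by all layers).
    """

    layer_names: list[str]
    data: np.ndarray
    cell_size_km: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidArgumentError("data must be (n_layers, rows, cols)")
        if len(self.layer_names) != self.data.shape[0]:
            raise InvalidArgumentError("layer_names length != number of layers")
        if self.cell_size_km <= 0:
            raise InvalidArgumentError("cell_size_km must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.data.shape[1:], dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.data.shape[1:]:
            raise InvalidArgumentError("nodata_mask shape mismatch")
        if self.nodata_mask.all():
            raise InvalidArgumentError("at least one unmasked cell required")

    # -- geometry ----------------------------------------------------------

    @property
    def n_layers(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in km."""
        rows, cols = self.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + cols * self.cell_size_km, y0 + rows * self.cell_size_km)

    def xy_to_rc(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map planar points (n, 2) to (row, col) indices of containing cells."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        x0, y0 = self.origin
        col = np.floor((xy[:, 0] - x0) / self.cell_size_km).astype(int)
        row = np.floor((xy[:, 1] - y0) / self.cell_size_km).astype(int)
        rows, cols = self.shape
        # points exactly on the top/right edge belong to the last cell
        col = np.where((xy[:, 0] - x0 == cols * self.cell_size_km), cols - 1, col)
        row = np.where((xy[:, 1] - y0 == rows * self.cell_size_km), rows - 1, row)
        return row, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates: (x of every column, y of every row)."""
        rows, cols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(cols) + 0.5) * self.cell_size_km
        ys = y0 + (np.arange(rows) + 0.5) * self.cell_size_km
        return xs, ys

    def rc_to_xy(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size_km
        y = y0 + (np.asarray(row) + 0.5) * self.cell_size_km
        return np.column_stack([x, y])

    def unmasked_rc(self) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(~self.nodata_mask)

    def layer(self, name: str) -> np.ndarray:
        return self.data[self.layer_names.index(name)]

    def values_at_cells(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        """Layer values at cells -> array (n_points, n_layers)."""
        return self.data[:, row, col].T

    # -- I/O: ESRI ASCII grid, one file per layer --------------------------

    NODATA_VALUE = -9999.0

    def write_ascii(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        rows, cols = self.shape
        for name, grid in zip(self.layer_names, self.data):
            out = grid.copy()
            out[self.nodata_mask] = self.NODATA_VALUE
            path = directory / f"{name}.asc"
            with open(path, "w") as fh:
                fh.write(
                    f"ncols {cols}\nnrows {rows}\n"
                    f"xllcorner {self.origin[0]}\nyllcorner {self.origin[1]}\n"
                    f"cellsize {self.cell_size_km}\nNODATA_value {self.NODATA_VALUE}\n"
                )
                # ASCII grids store the top row first
                np.savetxt(fh, out[::-1], fmt="%.10g")
            paths.append(path)
        return paths

    @classmethod
    def read_ascii(cls, paths: Sequence[str | Path]) -> "EnvStack":
        names, grids = [], []
        header = None
        for path in paths:
            path = Path(path)
            with open(path) as fh:
                hdr = {}
                for _ in range(6):
                    key, val = fh.readline().split()
                    hdr[key.lower()] = float(val)
                grid = np.loadtxt(fh)[::-1]
            if header is None:
                header = hdr
            names.append(path.stem)
            grids.append(grid)
        data = np.array(grids)
        mask = np.any(data == header.get("nodata_value", cls.NODATA_VALUE), axis=0)
        data[:, mask] = np.nan
        return cls(
            layer_names=names,
            data=data,
            cell_size_km=header["cellsize"],
            origin=(header["xllcorner"], header["yllcorner"]),
            nodata_mask=mask,
        )


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------


@dataclass
class OccurrenceSet:
    """One species' localities in planar km coordinates."""

    species_id: str
    points: np.ndarray
    deduplicated: bool = False

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 2)
        if self.points.shape[1] != 2:
            raise InvalidArgumentError("points must be (n, 2)")

    def __len__(self) -> int:
        return self.points.shape[0]

    def dedup(self) -> "OccurrenceSet":
        """Remove coordinate-exact duplicates; result order is canonical."""
        if len(self) == 0:
            return OccurrenceSet(self.species_id, self.points, deduplicated=True)
        unique = np.unique(self.points, axis=0)
        return OccurrenceSet(self.species_id, unique, deduplicated=True)


def read_occurrences(path: str | Path) -> dict[str, OccurrenceSet]:
    """Read a CSV with columns species, x_km, y_km (or lon, lat)."""
    df = pd.read_csv(path)
    if {"lon", "lat"} <= set(df.columns):
        from .geo_ranges import project_lonlat

        xy = project_lonlat(df[["lon", "lat"]].to_numpy())
        df = pd.DataFrame({"species": df["species"], "x_km": xy[:, 0], "y_km": xy[:, 1]})
    out = {}
    for sp, grp in df.groupby("species", sort=True):
        out[str(sp)] = OccurrenceSet(str(sp), grp[["x_km", "y_km"]].to_numpy())
    return out


def write_occurrences(occs: Iterable[OccurrenceSet], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"species": o.species_id, "x_km": o.points[:, 0], "y_km": o.points[:, 1]})
        for o in occs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Chronogram
# ---------------------------------------------------------------------------


@dataclass
class Chronogram:
    """Ultrametric time tree (ages in Ma) with an optional posterior sample."""

    tree: dendropy.Tree
    posterior_sample: list[dendropy.Tree] = field(default_factory=list)

    ULTRAMETRIC_RTOL = 1e-6

    def __post_init__(self) -> None:
        self._assign_ages()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, posterior_newick: str | None = None) -> "Chronogram":
        tns = dendropy.TaxonNamespace()
        tree = dendropy.Tree.get(
            data=newick, schema="newick", taxon_namespace=tns, preserve_underscores=True
        )
        tree.is_rooted = True
        posterior: list[dendropy.Tree] = []
        if posterior_newick:
            posterior = list(
                dendropy.TreeList.get(
                    data=posterior_newick,
                    schema="newick",
                    taxon_namespace=tns,
                    preserve_underscores=True,
                )
            )
            for p in posterior:
                p.is_rooted = True
        return cls(tree=tree, posterior_sample=posterior)

    @classmethod
    def read(cls, path: str | Path, posterior_path: str | Path | None = None) -> "Chronogram":
        newick = Path(path).read_text()
        post = Path(posterior_path).read_text() if posterior_path else None
        return cls.from_newick(newick, post)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.as_newick())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True)

    # -- ages --------------------------------------------------------------

    def _assign_ages(self) -> None:
        """Set node.age = max distance to a descendant tip; check ultrametricity."""
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node.age = 0.0
            else:
                ages = [c.age + (c.edge.length or 0.0) for c in node.child_nodes()]
                node.age = max(ages)
        root_age = self.tree.seed_node.age
        tol = max(self.ULTRAMETRIC_RTOL * max(root_age, 1.0), 1e-9)
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                continue
            for c in node.child_nodes():
                depth = c.age + (c.edge.length or 0.0)
                if abs(depth - node.age) > tol:
                    raise InvalidArgumentError(
                        f"tree is not ultrametric (node age {node.age} vs child depth {depth})"
                    )

    @property
    def root_age(self) -> float:
        return float(self.tree.seed_node.age)

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def mrca_age(self, a: str, b: str) -> float:
        mrca = self.tree.mrca(taxon_labels=[a, b])
        return float(mrca.age)

    def prune_to(self, labels: Sequence[str]) -> "Chronogram":
        tree = self.tree.clone(depth=1)
        tree.retain_taxa_with_labels(list(labels))
        posterior = []
        for p in self.posterior_sample:
            pc = p.clone(depth=1)
            pc.retain_taxa_with_labels(list(labels))
            posterior.append(pc)
        return Chronogram(tree=tree, posterior_sample=posterior)

    # -- Brownian-motion machinery ----------------------------------------

    def vcv(self) -> tuple[list[str], np.ndarray]:
        """Brownian-motion tip covariance structure.

        V[i, j] is the shared path length from the root to the MRCA of tips
        i and j; V[i, i] is the root age.  Returned with the tip label order.
        """
        leaves = list(self.tree.leaf_node_iter())
        labels = [lf.taxon.label for lf in leaves]
        index = {id(lf): k for k, lf in enumerate(leaves)}
        n = len(leaves)
        V = np.zeros((n, n))
        root_age = self.root_age
        # leaf sets per node, filling shared depth for cross-child pairs
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node._leaf_idx = [index[id(node)]]
                continue
            children = node.child_nodes()
            shared = root_age - node.age
            for i, ci in enumerate(children):
                for cj in children[i + 1 :]:
                    for a in ci._leaf_idx:
                        for b in cj._leaf_idx:
                            V[a, b] = V[b, a] = shared
            node._leaf_idx = [k for c in children for k in c._leaf_idx]
        np.fill_diagonal(V, root_age)
        return labels, V

    def simulate_bm(
        self, sigma2: float, root_value: np.ndarray, rng: np.random.Generator
    ) -> dict[str, np.ndarray]:
        """Evolve a (possibly multivariate) trait by Brownian motion.

        Each branch adds N(0, sigma2 * branch_length) independently per
        dimension.  Returns tip label -> trait vector.
        """
        if sigma2 < 0:
            raise InvalidArgumentError("sigma2 must be >= 0")
        root_value = np.atleast_1d(np.asarray(root_value, dtype=float))
        values: dict[int, np.ndarray] = {id(self.tree.seed_node): root_value}
        out: dict[str, np.ndarray] = {}
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                val = root_value
            else:
                parent = values[id(node.parent_node)]
                bl = node.edge.length or 0.0
                val = parent + rng.normal(0.0, np.sqrt(sigma2 * bl), size=root_value.shape)
                values[id(node)] = val
            if node.is_leaf():
                out[node.taxon.label] = val
            else:
                values[id(node)] = val
        return out
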
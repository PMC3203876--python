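"""Study orchestration: sister-pair enumeration and the full workflow.

`run_study` drives the whole comparative analysis on synthetic inputs (or
files, when paths are supplied): simulate climate-like layers and clades,
estimate geographic ranges and overlaps, compare sister niches by PCA and
Mann-Whitney, fit maximum-entropy niche models, run the identity and
background randomization tests, score phylogenetic signal per variable,
and fit the age-range correlation — emitting one CSV per report table.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arc as arc_mod
from . import climate_niche as cn
from . import geo_ranges as gr
from . import niche_overlap as no
from . import phylo_signal as ps
from . import synthetic_data as sd
from .containers import Chronogram, EnvStack, InvalidArgumentError, OccurrenceSet
from .enm_maxent import ModelSettings, build_features, replicate_models, sample_background


# ---------------------------------------------------------------------------
# Sister-pair enumeration
# ---------------------------------------------------------------------------


@dataclass
class PairPlan:
    pairs: pd.DataFrame  # species_a, species_b, mrca_age_ma
    excluded: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)


def enumerate_pairs(
    chron: Chronogram, exclude_clades: list[str] | None = None
) -> PairPlan:
    """Topological sister pairs: cherries, plus all tip-pair combinations
    under each multifurcation.

    ``exclude_clades`` lists tip labels to drop (e.g. a clade outside the
    study's geographic focus) before enumeration.  MRCA ages are averaged
    over the posterior sample when one is attached.
    """
    excluded = list(exclude_clades or [])
    work = chron
    if excluded:
        keep = [t for t in chron.tip_labels if t not in set(excluded)]
        if len(keep) < 2:
            raise InvalidArgumentError("fewer than 2 tips remain after exclusion")
        work = chron.prune_to(keep)

    rows = []
    for node in work.tree.postorder_internal_node_iter():
        children = node.child_nodes()
        tip_children = [c.taxon.label for c in children if c.is_leaf()]
        if len(children) == 2 and len(tip_children) == 2:
            combos = [tuple(sorted(tip_children))]
        elif len(children) >= 3 and len(tip_children) >= 2:
            combos = [tuple(sorted(p)) for p in combinations(sorted(tip_children), 2)]
        else:
            continue
        for a, b in combos:
            if work.posterior_sample:
                ages = []
                for t in work.posterior_sample:
                    post = Chronogram(tree=t.clone(depth=1))
                    ages.append(post.mrca_age(a, b))
                age = float(np.mean(ages))
            else:
                age = work.mrca_age(a, b)
            rows.append({"species_a": a, "species_b": b, "mrca_age_ma": age})
    pairs = pd.DataFrame(rows, columns=["species_a", "species_b", "mrca_age_ma"])
    if pairs.empty:
        warnings.warn("no sister pairs qualify")
    return PairPlan(pairs=pairs, excluded=excluded)


def plan_background_tests(plan: PairPlan) -> pd.DataFrame:
    """Expand a pair plan into its background-test rows.

    Each pair yields 2 metrics x 2 directions = 4 result rows.
    """
    rows = []
    for _, p in plan.pairs.iterrows():
        for metric in ("D", "I"):
            for focal, sister in ((p.species_a, p.species_b), (p.species_b, p.species_a)):
                rows.append(
                    {
                        "species_a": p.species_a,
                        "species_b": p.species_b,
                        "metric": metric,
                        "focal": focal,
                        "sister_background": sister,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Settings for one end-to-end run (synthetic demo by default).

    When ``occurrences_csv``/``raster_dir``/``tree_file`` are set the
    corresponding inputs are loaded from disk instead of simulated.
    """

    seed: int = 0
    # synthetic environment
    grid_rows: int = 40
    grid_cols: int = 40
    n_layers: int = 3
    corr_length_km: float = 15.0
    inter_layer_corr: float = 0.3
    cell_size_km: float = 5.0
    # synthetic clades: name -> number of tips
    clades: dict = field(default_factory=lambda: {"genusA": 8, "genusB": 6})
    mean_depth_ma: float = 8.0
    sigma2: float = 0.2
    niche_breadth: float = 1.0
    n_points_per_tip: int = 30
    # optional file inputs
    occurrences_csv: str | None = None
    raster_dir: str | None = None
    tree_file: str | None = None
    # geographic ranges
    buffer_radius_km: float = 20.0
    # niche models
    background_n: int = 10_000
    reg_multiplier: float = 1.0
    max_iter: int = 200
    tol: float = 1e-5
    enm_reps: int = 10
    train_frac: float = 0.75
    # randomization tests
    identity_reps: int = 30
    background_reps: int = 30
    qvi_n_rand: int = 200
    n_posterior: int = 100
    posterior_sigma: float = 0.1
    k_rand: int = 199
    arc_sims: int = 200

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise InvalidArgumentError("train_frac must be in (0, 1)")
        for name in (
            "enm_reps",
            "identity_reps",
            "background_reps",
            "qvi_n_rand",
            "n_posterior",
            "k_rand",
            "arc_sims",
            "n_points_per_tip",
        ):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def model_settings(self) -> ModelSettings:
        return ModelSettings(
            background_n=self.background_n,
            reg_multiplier=self.reg_multiplier,
            max_iter=self.max_iter,
            tol=self.tol,
            n_reps=self.enm_reps,
            train_frac=self.train_frac,
        )


# ---------------------------------------------------------------------------
# The study driver
# ---------------------------------------------------------------------------


def _load_or_simulate(config: RunConfig, seeds: list[np.random.SeedSequence]):
    """Returns (env, {clade: (chron, {species: occ})})."""
    s_env, s_clades = seeds
    if config.raster_dir:
        paths = sorted(Path(config.raster_dir).glob("*.asc"))
        env = EnvStack.read_ascii(paths)
    else:
        env = sd.generate_env_stack(
            config.n_layers,
            (config.grid_rows, config.grid_cols),
            corr_length_km=config.corr_length_km,
            inter_layer_corr=config.inter_layer_corr,
            cell_size_km=config.cell_size_km,
            seed=s_env.generate_state(1)[0] % (2**31),
        )
    clades: dict[str, tuple[Chronogram, dict[str, OccurrenceSet]]] = {}
    if config.tree_file and config.occurrences_csv:
        from .containers import read_occurrences

        chron = Chronogram.read(config.tree_file)
        occs = read_occurrences(config.occurrences_csv)
        clades["study"] = (chron, occs)
    else:
        for (name, n_tips), child in zip(
            sorted(config.clades.items()), s_clades.spawn(len(config.clades))
        ):
            t_seed, c_seed = child.spawn(2)
            tree = sd.random_ultrametric_tree(
                int(n_tips),
                seed=t_seed.generate_state(1)[0] % (2**31),
                mean_depth_ma=config.mean_depth_ma,
                prefix=f"{name}_sp",
            )
            sim = sd.simulate_clade(
                tree,
                config.sigma2,
                np.zeros(env.n_layers),
                env,
                config.n_points_per_tip,
                seed=c_seed.generate_state(1)[0] % (2**31),
                breadth=config.niche_breadth,
            )
            clades[name] = (tree, {sp: occ for sp, (niche, occ) in sim.items()})
    return env, clades


def run_study(config: RunConfig, out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Execute the full workflow; write report CSVs and return the tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    log_path = out / "run_log.jsonl"
    log_fh = open(log_path, "w")

    def log(stage: str, **kv) -> None:
        log_fh.write(json.dumps({"stage": stage, "time": time.time(), **kv}) + "\n")
        log_fh.flush()

    master = np.random.SeedSequence(config.seed)
    s_inputs, s_tests = master.spawn(2)
    env, clades = _load_or_simulate(config, list(s_inputs.spawn(2)))
    log("inputs", seed=config.seed, n_layers=env.n_layers, shape=list(env.shape))

    settings = config.model_settings()
    brc = sample_background(env, config.background_n, seed=config.seed)
    features = build_features(env, settings.kinds, brc)

    pair_rows = []
    enm_rows = []
    bg_rows = []
    signal_frames = []
    arc_results: dict[str, dict[str, arc_mod.ARCResult]] = {}

    for (clade_name, (tree, occs)), clade_seed in zip(
        sorted(clades.items()), s_tests.spawn(len(clades))
    ):
        seeds = clade_seed.spawn(6)

        def sub(seq: np.random.SeedSequence) -> int:
            return int(seq.generate_state(1)[0] % (2**31))

        occs = {sp: o.dedup() for sp, o in occs.items()}
        ranges = {
            sp: gr.buffer_range(o, config.buffer_radius_km)
            for sp, o in occs.items()
            if len(o) > 0
        }
        plan = enumerate_pairs(tree)
        log("pairs", clade=clade_name, n_pairs=len(plan))

        # per-species ENM replicates
        surfaces: dict[str, np.ndarray] = {}
        for sp, rep_seed in zip(sorted(occs), seeds[0].spawn(len(occs))):
            o = occs[sp]
            if len(o) < no.MIN_MODEL_POINTS:
                surfaces[sp] = no.fit_species_surface(
                    env, o, features, settings, ranges.get(sp)
                )
                enm_rows.append(
                    {"clade": clade_name, "species": sp, "n_points": len(o),
                     "auc": np.nan, "auc_sd": np.nan, "fallback": True}
                )
                continue
            model, ev = replicate_models(
                features,
                o,
                n_reps=config.enm_reps,
                train_frac=config.train_frac,
                seed=sub(rep_seed),
                reg_multiplier=config.reg_multiplier,
                max_iter=config.max_iter,
                tol=config.tol,
            )
            surfaces[sp] = model.raw_surface
            enm_rows.append(
                {"clade": clade_name, "species": sp, "n_points": len(o),
                 "auc": ev.auc, "auc_sd": ev.auc_sd, "fallback": False}
            )
        log("enm", clade=clade_name, n_species=len(surfaces))

        # pair table: geography, PCA + Mann-Whitney, identity, background
        trait_tables = {sp: cn.extract_values(env, o) for sp, o in occs.items()}
        for (_, pr), pair_seed in zip(plan.pairs.iterrows(), seeds[1].spawn(len(plan))):
            a, b = pr.species_a, pr.species_b
            id_seed, bg_seed_a, bg_seed_b = pair_seed.spawn(3)
            pct = gr.range_overlap_pct(ranges[a], ranges[b])
            smaller = a if ranges[a].area_km2 <= ranges[b].area_km2 else b
            pca = cn.pair_pca(trait_tables[a], trait_tables[b])
            mw = cn.pair_component_tests(pca)
            codes = dict(zip(mw["component"], mw["code"]))
            ident = no.identity_test(
                occs[a], occs[b], env, settings,
                n_reps=config.identity_reps, seed=sub(id_seed),
                features=features, fallback_ranges=ranges,
            )
            row = {
                "clade": clade_name,
                "species_a": a,
                "species_b": b,
                "overlap_pct": pct,
                "smaller_range_species": smaller if pct > 0 else "no overlap",
                "mrca_age_ma": pr.mrca_age_ma,
                "PC1": codes.get("PC1", ""),
                "PC2": codes.get("PC2", ""),
                "PC3": codes.get("PC3", ""),
                "identity_D": ident.observed.D,
                "identity_I": ident.observed.I,
                "identity_code_D": ident.code_D,
                "identity_code_I": ident.code_I,
            }
            for direction, (focal, sister, bseed) in zip(
                ("a_vs_b", "b_vs_a"), ((a, b, bg_seed_a), (b, a, bg_seed_b))
            ):
                res = no.background_test(
                    occs[focal], occs[sister], ranges[sister], env, settings,
                    n_reps=config.background_reps, seed=sub(bseed),
                    features=features, fallback_ranges=ranges,
                )
                for metric in ("D", "I"):
                    bg_rows.append(
                        {
                            "clade": clade_name,
                            "species_a": a,
                            "species_b": b,
                            "focal": focal,
                            "sister_background": sister,
                            "metric": metric,
                            "observed": getattr(res.observed, metric),
                            "p": getattr(res, f"p_{metric}"),
                            "code": getattr(res, f"code_{metric}"),
                        }
                    )
                row[f"background_{direction}_D"] = res.code_D
                row[f"background_{direction}_I"] = res.code_I
            pair_rows.append(row)
        log("pair_tests", clade=clade_name)

        # phylogenetic signal per variable
        traits = cn.species_summary(trait_tables)
        post = sd.jitter_posterior(
            tree, config.n_posterior, sigma=config.posterior_sigma, seed=sub(seeds[2])
        )
        sig = ps.signal_table(
            post,
            traits,
            n_rand=config.qvi_n_rand,
            n_k_rand=config.k_rand,
            seed=sub(seeds[3]),
        )
        sig.insert(0, "clade", clade_name)
        signal_frames.append(sig)
        log("signal", clade=clade_name)

        # age-range correlation (needs >= 3 species and >= 2 node ages)
        if len(surfaces) >= 3:
            arc_results[clade_name] = {}
            for metric, aseed in zip(("D", "I"), seeds[4].spawn(2)):
                M = arc_mod.overlap_matrix(surfaces, metric=metric)
                arc_results[clade_name][metric] = arc_mod.arc_mc_test(
                    tree, M, n_sims=config.arc_sims, seed=sub(aseed), metric=metric
                )
            log("arc", clade=clade_name)

    tables = {
        "pair_table": pd.DataFrame(pair_rows),
        "enm_table": pd.DataFrame(enm_rows),
        "background_table": pd.DataFrame(bg_rows),
        "signal_table": pd.concat(signal_frames, ignore_index=True)
        if signal_frames
        else pd.DataFrame(),
        "arc_table": arc_mod.arc_table(arc_results),
    }
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    log("done", tables={k: len(v) for k, v in tables.items()})
    log_fh.close()
    return tables
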
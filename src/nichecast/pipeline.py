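"""End-to-end orchestration of the synthetic invasion-risk analysis.

One declarative config drives the full sequence: simulate the world (or
load real grids), average GCM realisations per scenario, fit the shared PCA
niche space and hull overlaps, build one AUC-weighted ensemble per species,
project current and future suitability, standardize, compute change maps
over the invaded and long-distance-dispersal potential ranges, summarize by
protection regime and compare groups. Every stochastic stage carries an
explicit seed and all outputs are plain-text, so a rerun of the same config
reproduces byte-identical tables; the manifest records file digests.
"""
from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .change import (
    change_map,
    compare_groups,
    potential_range,
    regime_summary,
    standardize,
)
from .exceptions import ConfigError, DegenerateTestError, StageError
from .gridio import (
    read_env_stack,
    read_occurrences,
    read_protection,
    read_strata,
    write_env_stack,
    write_hulls_geojson,
    write_occurrences,
    write_protection,
    write_strata,
)
from .nichespace import (
    convex_hull,
    fit_pca_env,
    overlap,
    points_outside,
    project_env_cells,
)
from .sdm import (
    FAMILIES,
    build_ensemble,
    evaluate_transfer,
    predict_suitability,
)
from .synthetic import (
    CLIMATE_VARIABLES,
    EnvStack,
    OccurrenceSet,
    VirtualSpecies,
    average_climate_models,
    generate_env_stack,
    generate_protection_mask,
    generate_strata,
    make_future_stack,
    sample_occurrences,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SampleSpec:
    region: str
    design: str
    n: int


@dataclass
class SpeciesConfig:
    name: str
    role: str  # 'invader' | 'native'
    response: dict[str, tuple[float, float]]
    prevalence: float = 1.0
    samples: list[SampleSpec] = field(default_factory=list)

    def virtual(self) -> VirtualSpecies:
        return VirtualSpecies(
            name=self.name,
            response={k: tuple(v) for k, v in self.response.items()},
            prevalence_scale=self.prevalence,
        )


@dataclass
class RunConfig:
    grid_rows: int = 80
    grid_cols: int = 80
    cell_size: float = 10.0
    autocorrelation_length: float = 20.0
    strata_k: int = 6
    protection_coverage: float = 0.20
    protection_targeted: float = 0.05
    scenario_deltas: dict[str, dict[str, float]] = field(default_factory=dict)
    gcm_count: int = 6
    gcm_jitter: dict[str, float] = field(default_factory=dict)
    species: list[SpeciesConfig] = field(default_factory=list)
    sdm_replicates: int = 10
    sdm_families: tuple[str, ...] = FAMILIES
    auc_threshold: float = 0.7
    train_fraction: float = 0.7
    seeds: dict[str, int] = field(default_factory=dict)
    out_dir: str = "results/run"

    def validate(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ConfigError("species labels must be unique")
        if not any(s.role == "invader" for s in self.species):
            raise ConfigError("config needs one invader species")
        if sum(s.role == "invader" for s in self.species) > 1:
            raise ConfigError("config allows a single invader")
        required = {"env", "strata", "protection", "occurrences", "sdm", "gcm", "transfer"}
        missing = required - set(self.seeds)
        if missing:
            raise ConfigError(f"seeds missing for stages: {sorted(missing)}")
        for label, deltas in self.scenario_deltas.items():
            for v in CLIMATE_VARIABLES:
                if v not in deltas:
                    raise ConfigError(f"scenario {label} missing delta for {v}")
        unknown = [f for f in self.sdm_families if f not in FAMILIES]
        if unknown:
            raise ConfigError(f"unknown model families: {unknown}")

    @property
    def invader(self) -> SpeciesConfig:
        return next(s for s in self.species if s.role == "invader")

    @property
    def natives(self) -> list[SpeciesConfig]:
        return [s for s in self.species if s.role == "native"]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sdm_families"] = list(self.sdm_families)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def to_yaml(self, path: Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["species"] = [
            SpeciesConfig(
                name=s["name"], role=s["role"],
                response={k: tuple(v) for k, v in s["response"].items()},
                prevalence=s.get("prevalence", 1.0),
                samples=[SampleSpec(**ss) for ss in s.get("samples", [])],
            )
            for s in d.get("species", [])
        ]
        if "sdm_families" in d:
            d["sdm_families"] = tuple(d["sdm_families"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def derive_seeds(master_seed: int) -> dict[str, int]:
    """Named per-stage seeds deterministically derived from one master."""
    names = ("env", "strata", "protection", "occurrences", "sdm", "gcm", "transfer")
    state = np.random.SeedSequence(master_seed).generate_state(len(names))
    return {n: int(s % (2**31)) for n, s in zip(names, state)}


def default_config(out_dir: str = "results/run", master_seed: int = 20220) -> RunConfig:
    """The default synthetic study conditions.

    An invader with a native (western) and an invaded (eastern) range plus
    three native species confined to the invaded range; Gaussian climate
    niches on BIO5/BIO6/BIO12; presence-only sampling in the invader's
    native range and atlas sampling elsewhere; two future scenarios, a mild
    and a severe warming-plus-drying shift, each averaged over six jittered
    GCM realisations.
    """
    species = [
        SpeciesConfig(
            name="invader", role="invader",
            response={"BIO5": (33.0, 5.0), "BIO6": (5.0, 5.0), "BIO12": (650.0, 400.0)},
            samples=[SampleSpec("native", "presence_only", 200),
                     SampleSpec("invaded", "atlas", 450)],
        ),
        SpeciesConfig(
            name="native_a", role="native",
            response={"BIO5": (31.0, 5.0), "BIO6": (4.0, 5.0), "BIO12": (800.0, 420.0)},
            samples=[SampleSpec("invaded", "atlas", 600)],
        ),
        SpeciesConfig(
            name="native_b", role="native",
            response={"BIO5": (35.0, 4.5), "BIO6": (7.0, 4.5), "BIO12": (500.0, 320.0)},
            samples=[SampleSpec("invaded", "atlas", 600)],
        ),
        SpeciesConfig(
            name="native_c", role="native",
            response={"BIO5": (30.0, 6.0), "BIO6": (2.0, 5.0), "BIO12": (900.0, 500.0)},
            samples=[SampleSpec("invaded", "atlas", 600)],
        ),
    ]
    return RunConfig(
        scenario_deltas={
            "rcp26": {"BIO5": 1.5, "BIO6": 1.5, "BIO12": -50.0},
            "rcp85": {"BIO5": 4.5, "BIO6": 4.5, "BIO12": -200.0},
        },
        gcm_jitter={"BIO5": 0.3, "BIO6": 0.3, "BIO12": 30.0},
        species=species,
        seeds=derive_seeds(master_seed),
        out_dir=out_dir,
    )


# ---------------------------------------------------------------------------
# manifest


@dataclass
class RunManifest:
    config_hash: str
    versions: dict[str, str]
    stages: list[dict] = field(default_factory=list)
    files: dict[str, str] = field(default_factory=dict)
    failed_stage: str | None = None

    def record_file(self, out_dir: Path, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.files[str(Path(path).relative_to(out_dir))] = digest

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class WorldState:
    """In-memory handles shared between stages."""

    current: EnvStack = None
    futures: dict[str, EnvStack] = field(default_factory=dict)
    strata: object = None
    protection: object = None
    occurrences: dict[tuple[str, str], OccurrenceSet] = field(default_factory=dict)
    ensembles: dict = field(default_factory=dict)
    suitability: dict[tuple[str, str], object] = field(default_factory=dict)
    summary: pd.DataFrame = None


def stage_simulate(cfg: RunConfig, out: Path, world: WorldState) -> dict:
    current = generate_env_stack(
        (cfg.grid_rows, cfg.grid_cols), cfg.cell_size,
        cfg.autocorrelation_length, seed=cfg.seeds["env"])
    world.current = current
    world.strata = generate_strata(current.grid_shape, cfg.strata_k, seed=cfg.seeds["strata"])
    world.protection = generate_protection_mask(
        current.grid_shape, cfg.protection_coverage, cfg.protection_targeted,
        [s.name for s in cfg.natives] or [cfg.invader.name],
        seed=cfg.seeds["protection"])

    gcm_rng = np.random.default_rng(cfg.seeds["gcm"])
    sigma_cells = cfg.autocorrelation_length / cfg.cell_size
    for label, deltas in sorted(cfg.scenario_deltas.items()):
        gcms = []
        for _ in range(cfg.gcm_count):
            jittered = {}
            for v in CLIMATE_VARIABLES:
                amp = cfg.gcm_jitter.get(v, 0.0)
                if amp > 0:
                    from scipy.ndimage import gaussian_filter
                    noise = gaussian_filter(
                        gcm_rng.standard_normal(current.grid_shape), sigma_cells,
                        mode="reflect")
                    scale = noise.std() or 1.0
                    jittered[v] = deltas[v] + amp * noise / scale
                else:
                    jittered[v] = deltas[v]
            gcms.append(make_future_stack(current, jittered, label))
        world.futures[label] = average_climate_models(gcms)

    occ_base = cfg.seeds["occurrences"]
    n_records = 0
    for i, sp in enumerate(cfg.species):
        vs = sp.virtual()
        for j, spec in enumerate(sp.samples):
            occ = sample_occurrences(vs, current, spec.n, spec.design,
                                     spec.region, seed=occ_base + 97 * i + j)
            world.occurrences[(sp.name, spec.region)] = occ
            n_records += len(occ)

    write_env_stack(out / "grids", current)
    for label, stack in world.futures.items():
        write_env_stack(out / "grids", stack)
    write_strata(out / "strata.asc", world.strata, cfg.cell_size)
    write_protection(out / "protection", world.protection, cfg.cell_size)
    write_occurrences(out / "occurrences.csv", list(world.occurrences.values()))
    return {"n_occurrence_records": n_records,
            "n_future_scenarios": len(world.futures)}


def stage_niche(cfg: RunConfig, out: Path, world: WorldState) -> dict:
    ns = fit_pca_env(world.current)
    inv = cfg.invader.name
    native_occ = world.occurrences[(inv, "native")]
    invaded_occ = world.occurrences[(inv, "invaded")]
    scores = {}
    hulls = {}
    for (name, region), occ in world.occurrences.items():
        sc = project_env_cells(ns, world.current, occ.presence_cells)
        scores[(name, region)] = sc
        hulls[(name, region)] = convex_hull(sc, species=f"{name}:{region}")

    rows = []
    inv_invaded_hull = hulls[(inv, "invaded")]
    inv_native_hull = hulls[(inv, "native")]
    for sp in cfg.natives:
        res = overlap(hulls[(sp.name, "invaded")], inv_invaded_hull)
        rows.append({
            "species_a": res.species_a, "species_b": res.species_b,
            "area_a": res.area_a, "area_b": res.area_b,
            "area_intersection": res.area_intersection,
            "fraction_of_a": res.fraction_of_a, "fraction_of_b": res.fraction_of_b,
        })
    res = overlap(inv_invaded_hull, inv_native_hull)
    rows.append({
        "species_a": res.species_a, "species_b": res.species_b,
        "area_a": res.area_a, "area_b": res.area_b,
        "area_intersection": res.area_intersection,
        "fraction_of_a": res.fraction_of_a, "fraction_of_b": res.fraction_of_b,
    })
    n_out, frac_out = points_outside(scores[(inv, "invaded")], inv_native_hull)

    pd.DataFrame(rows).to_csv(out / "overlap.csv", index=False)
    ns.variable_correlations().to_csv(out / "pca_loadings.csv")
    score_rows = []
    for (name, region), sc in sorted(scores.items()):
        score_rows.append(pd.DataFrame(
            {"species": name, "region": region, "PC1": sc[:, 0], "PC2": sc[:, 1]}))
    pd.concat(score_rows, ignore_index=True).to_csv(out / "pca_scores.csv", index=False)
    write_hulls_geojson(out / "hulls.geojson", list(hulls.values()))
    with open(out / "niche_summary.json", "w") as fh:
        json.dump({
            "explained_fraction": ns.explained_fraction.tolist(),
            "pc12_explained": float(ns.explained_fraction[:2].sum()),
            "invader_outside_native_hull_n": n_out,
            "invader_outside_native_hull_fraction": frac_out,
        }, fh, indent=1, sort_keys=True)
    world.niche = ns
    return {"pc12_explained": float(ns.explained_fraction[:2].sum()),
            "n_outside": n_out, "fraction_outside": frac_out}


def stage_sdm(cfg: RunConfig, out: Path, world: WorldState) -> dict:
    inv = cfg.invader.name
    sdm_base = cfg.seeds["sdm"]
    tables = []
    from .gridio import write_ascii_grid
    (out / "suitability").mkdir(parents=True, exist_ok=True)
    for i, sp in enumerate(cfg.species):
        occ = (world.occurrences[(sp.name, "native")] if sp.role == "invader"
               else world.occurrences[(sp.name, "invaded")])
        ens = build_ensemble(
            occ, world.current, world.strata,
            R=cfg.sdm_replicates, families=cfg.sdm_families,
            auc_threshold=cfg.auc_threshold, seed=sdm_base + 131 * i,
            train_fraction=cfg.train_fraction,
        )
        world.ensembles[sp.name] = ens
        t = ens.member_table.copy()
        t.insert(0, "species", sp.name)
        tables.append(t)
        for label, stack in [("current", world.current)] + sorted(world.futures.items()):
            smap = predict_suitability(ens, stack)
            world.suitability[(sp.name, label)] = smap
            write_ascii_grid(out / "suitability" / f"{sp.name}_{label}.asc",
                             smap.values, cfg.cell_size)

    transfer = evaluate_transfer(
        world.ensembles[inv], world.occurrences[(inv, "invaded")],
        world.current, world.strata, seed=cfg.seeds["transfer"])
    pd.concat(tables, ignore_index=True).to_csv(out / "sdm_members.csv", index=False)
    eval_rows = []
    for sp in cfg.species:
        ens = world.ensembles[sp.name]
        eval_rows.append({"species": sp.name, "mean_auc": ens.mean_auc,
                          "sd_auc": ens.sd_auc,
                          "n_retained": len(ens.members),
                          "n_members": len(ens.all_members)})
    pd.DataFrame(eval_rows).to_csv(out / "sdm_eval.csv", index=False)
    with open(out / "transfer.json", "w") as fh:
        json.dump({"invader_transfer_auc": transfer}, fh, indent=1)
    world.transfer_auc = transfer
    return {"invader_transfer_auc": transfer,
            "n_members_total": int(sum(len(world.ensembles[s.name].all_members)
                                       for s in cfg.species))}


def stage_change(cfg: RunConfig, out: Path, world: WorldState) -> dict:
    inv = cfg.invader.name
    shape = world.current.grid_shape
    projection_region = world.current.region_mask == "invaded"

    inv_occ = world.occurrences[(inv, "invaded")]
    invaded_mask = np.zeros(shape, dtype=bool)
    pc = inv_occ.presence_cells
    invaded_mask[pc[:, 0], pc[:, 1]] = True
    natives_occ = [world.occurrences[(s.name, "invaded")] for s in cfg.natives]
    potential_mask = potential_range(natives_occ, shape)

    zmaps: dict[tuple[str, str], np.ndarray] = {}
    for sp in cfg.species:
        ref = world.suitability[(sp.name, "current")]
        for label in ["current"] + sorted(world.futures):
            zmaps[(sp.name, label)] = standardize(
                world.suitability[(sp.name, label)], ref, cells=projection_region)

    def species_masks(sp: SpeciesConfig) -> dict[str, np.ndarray]:
        if sp.role == "invader":
            return {"invaded": invaded_mask, "potential": potential_mask}
        occ = world.occurrences[(sp.name, "invaded")]
        own = np.zeros(shape, dtype=bool)
        cells = occ.presence_cells
        own[cells[:, 0], cells[:, 1]] = True
        return {"invaded": own & invaded_mask, "potential": own & potential_mask}

    summary_rows = []
    cmaps: dict[tuple[str, str, str], object] = {}
    for sp in cfg.species:
        for scenario in sorted(world.futures):
            for range_label, mask in species_masks(sp).items():
                if not mask.any():
                    logger.info("range %s empty for %s; skipped", range_label, sp.name)
                    continue
                cm = change_map(zmaps[(sp.name, scenario)], zmaps[(sp.name, "current")],
                                mask, sp.name, scenario)
                cmaps[(sp.name, scenario, range_label)] = cm
                rs = regime_summary(cm, world.protection)
                if rs.empty:
                    continue
                rs.insert(2, "range", range_label)
                summary_rows.append(rs)
    summary = pd.concat(summary_rows, ignore_index=True)
    summary.to_csv(out / "change_summary.csv", index=False)
    world.summary = summary

    comparisons = []
    for sp in cfg.species:
        for range_label in ("invaded", "potential"):
            a = cmaps.get((sp.name, "rcp26", range_label))
            b = cmaps.get((sp.name, "rcp85", range_label))
            if a is not None and b is not None:
                try:
                    res = compare_groups(a.delta, b.delta, paired=True,
                                         grouping=f"{sp.name}/{range_label}/rcp26-vs-rcp85")
                    comparisons.append(res)
                except DegenerateTestError:
                    logger.info("degenerate paired test skipped for %s", sp.name)
        for scenario in sorted(world.futures):
            cm = cmaps.get((sp.name, scenario, "potential"))
            if cm is None:
                continue
            r, c = cm.cells[:, 0], cm.cells[:, 1]
            protected = world.protection.protected[r, c]
            targeted = world.protection.targeted_for(sp.name)[r, c]
            pairs = [("outside-vs-n2000", ~protected, protected & ~targeted),
                     ("n2000-vs-targeted", protected & ~targeted, protected & targeted)]
            for tag, sel_a, sel_b in pairs:
                if sel_a.sum() >= 2 and sel_b.sum() >= 2:
                    try:
                        res = compare_groups(
                            cm.delta[sel_a], cm.delta[sel_b], paired=False,
                            grouping=f"{sp.name}/potential/{scenario}/{tag}")
                        comparisons.append(res)
                    except DegenerateTestError:
                        logger.info("degenerate Welch test skipped (%s)", tag)
    logger.info("ran %d group comparisons (uncorrected p-values)", len(comparisons))
    pd.DataFrame([asdict(cr) for cr in comparisons]).to_csv(
        out / "comparisons.csv", index=False)
    return {"n_summary_rows": len(summary), "n_comparisons": len(comparisons)}


_STAGES = [
    ("simulate", stage_simulate),
    ("niche", stage_niche),
    ("sdm", stage_sdm),
    ("change", stage_change),
]


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Run every stage in order, writing outputs and a manifest under out_dir."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    manifest = RunManifest(
        config_hash=cfg.config_hash(),
        versions={
            "nichecast": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    )
    world = WorldState()
    for name, fn in _STAGES:
        t0 = time.perf_counter()
        try:
            info = fn(cfg, out, world)
        except Exception as exc:
            manifest.failed_stage = name
            manifest.write(out / "manifest.json")
            raise StageError(name, exc) from exc
        manifest.stages.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3),
                                **{k: v for k, v in info.items()}})
        logger.info("stage %s done (%.1fs): %s", name, time.perf_counter() - t0, info)
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest.record_file(out, path)
    manifest.write(out / "manifest.json")
    return manifest


def load_real_data(directory: Path, merge_map: dict[str, str] | None = None):
    """Load a written world back into domain objects (real-data mode).

    Expects the layout the simulate stage writes: ``grids/`` with per-
    variable ASCII layers and a region grid, ``occurrences.csv``,
    ``strata.asc`` and ``protection/``. A species merge map (taxonomic
    pooling rule) is applied to occurrence labels before assembly.
    """
    directory = Path(directory)
    env = read_env_stack(directory / "grids", "current")
    occ_sets = read_occurrences(directory / "occurrences.csv", env.grid_shape, merge_map)
    strata = read_strata(directory / "strata.asc")
    species = sorted({o.species for o in occ_sets})
    protection = read_protection(directory / "protection", species)
    return env, occ_sets, protection, strata
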
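"""Synthetic study worlds: environmental grids, virtual species, samples.

Generates every input the analysis needs — spatially autocorrelated
environmental layers for a current and two future greenhouse-gas scenarios,
virtual species with known Gaussian niche responses, presence-only and atlas
occurrence samples, ecoregion-like strata, and a protected-area mask with a
targeted subset per species. Every generator is a pure function of its seed
and parameters.

Grid convention: row-major indexing, cell-centre coordinates, abstract
kilometre cell size, no map projection.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import AlignmentError, ParameterError, SizeError

logger = logging.getLogger(__name__)

#: Layer names, in canonical order.
VARIABLES = ("BIO5", "BIO6", "BIO12", "ALT", "SLOPE")
#: The subset projected under climate scenarios (relief is static).
CLIMATE_VARIABLES = ("BIO5", "BIO6", "BIO12")

#: Realistic value ranges used to rescale smoothed noise fields:
#: max temperature of warmest month (degC), min temperature of coldest month
#: (degC), annual precipitation (mm), altitude (m), slope (deg).
VARIABLE_RANGES = {
    "BIO5": (15.0, 45.0),
    "BIO6": (-15.0, 15.0),
    "BIO12": (100.0, 2000.0),
    "ALT": (0.0, 3000.0),
    "SLOPE": (0.0, 30.0),
}

REGIONS = ("native", "invaded", "other")
SCENARIOS = ("current", "rcp26", "rcp85")


@dataclass
class EnvStack:
    """Aligned gridded environmental variables for one scenario."""

    grid_shape: tuple[int, int]
    cell_size: float
    variables: dict[str, np.ndarray]
    scenario: str
    region_mask: np.ndarray  # str array, values in REGIONS

    def validate(self) -> None:
        rows, cols = self.grid_shape
        for name, layer in self.variables.items():
            if layer.shape != (rows, cols):
                raise AlignmentError(f"layer {name} shape {layer.shape} != {self.grid_shape}")
            if not np.all(np.isfinite(layer)):
                raise ParameterError(f"layer {name} contains non-finite values")
        if self.region_mask.shape != (rows, cols):
            raise AlignmentError("region_mask shape mismatch")
        if "BIO12" in self.variables and np.any(self.variables["BIO12"] < 0):
            raise ParameterError("BIO12 must be non-negative")
        if "SLOPE" in self.variables and np.any(self.variables["SLOPE"] < 0):
            raise ParameterError("SLOPE must be non-negative")
        if "BIO5" in self.variables and "BIO6" in self.variables:
            if np.any(self.variables["BIO5"] < self.variables["BIO6"]):
                raise ParameterError("BIO5 must be >= BIO6 cellwise")

    @property
    def n_cells(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def to_matrix(self, variables: tuple[str, ...] = VARIABLES) -> np.ndarray:
        """Cells x variables matrix in row-major cell order."""
        try:
            cols = [self.variables[v].ravel() for v in variables]
        except KeyError as exc:  # pragma: no cover - defensive
            raise AlignmentError(f"missing variable {exc}") from exc
        return np.column_stack(cols)

    def region_cells(self, region: str | None) -> np.ndarray:
        """(k, 2) array of (row, col) indices in a region (None = all)."""
        if region is None:
            mask = np.ones(self.grid_shape, dtype=bool)
        else:
            if region not in REGIONS:
                raise ParameterError(f"unknown region {region!r}")
            mask = self.region_mask == region
        return np.argwhere(mask)

    def copy(self) -> "EnvStack":
        return EnvStack(
            grid_shape=self.grid_shape,
            cell_size=self.cell_size,
            variables={k: v.copy() for k, v in self.variables.items()},
            scenario=self.scenario,
            region_mask=self.region_mask.copy(),
        )


@dataclass(frozen=True)
class VirtualSpecies:
    """A species with a known product-Gaussian suitability function.

    ``response`` maps variable name to (optimum, breadth). Suitability of an
    environmental vector x is

        prevalence_scale * prod_v exp(-(x_v - mu_v)^2 / (2 sigma_v^2)),

    which lies in [0, 1] and equals ``prevalence_scale`` at the optimum.
    """

    name: str
    response: dict[str, tuple[float, float]]
    prevalence_scale: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.prevalence_scale <= 1.0):
            raise ParameterError("prevalence_scale must be in (0, 1]")
        for v, (_, sigma) in self.response.items():
            if sigma <= 0:
                raise ParameterError(f"breadth for {v} must be > 0")

    def suitability(self, env: EnvStack) -> np.ndarray:
        """Per-cell suitability grid in [0, 1]."""
        log_s = np.zeros(env.grid_shape)
        for v, (mu, sigma) in self.response.items():
            x = env.variables[v]
            log_s -= (x - mu) ** 2 / (2.0 * sigma**2)
        return self.prevalence_scale * np.exp(log_s)


@dataclass
class OccurrenceSet:
    """Species records on the grid for one region and sampling design."""

    species: str
    rows: np.ndarray
    cols: np.ndarray
    presence: np.ndarray
    region: str
    design: str  # presence_only | atlas

    def __post_init__(self):
        if self.design not in ("presence_only", "atlas"):
            raise ParameterError(f"unknown design {self.design!r}")
        if self.design == "presence_only" and np.any(self.presence == 0):
            raise ParameterError("presence_only sets cannot contain absences")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def presence_cells(self) -> np.ndarray:
        """(k, 2) (row, col) indices of presence records."""
        keep = self.presence == 1
        return np.column_stack([self.rows[keep], self.cols[keep]])

    @property
    def absence_cells(self) -> np.ndarray:
        keep = self.presence == 0
        return np.column_stack([self.rows[keep], self.cols[keep]])


@dataclass
class StrataMap:
    """Per-cell environmental stratum id in 1..K."""

    labels: np.ndarray  # int grid
    k: int

    def stratum_of(self, cells: np.ndarray) -> np.ndarray:
        return self.labels[cells[:, 0], cells[:, 1]]


REGIME_OUTSIDE, REGIME_N2000, REGIME_TARGETED = 0, 1, 2


@dataclass
class ProtectionMask:
    """Per-cell protection regime with per-species targeted flags.

    ``regime`` holds 0 = outside, 1 = protected (n2000), 2 = protected and
    targeted for at least one species; ``targeted`` maps species label to a
    boolean grid of cells where that species is an explicit conservation
    target. Targeted cells are always protected.
    """

    regime: np.ndarray
    targeted: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def protected(self) -> np.ndarray:
        return self.regime >= REGIME_N2000

    def targeted_for(self, species: str) -> np.ndarray:
        grid = self.targeted.get(species)
        if grid is None:
            return np.zeros(self.regime.shape, dtype=bool)
        return grid

    def species_at(self, row: int, col: int) -> set[str]:
        return {s for s, g in self.targeted.items() if g[row, col]}


def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if sigma_cells > 1e-9:
        noise = gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
    return noise


def _rescale(field: np.ndarray, lo: float, hi: float) -> np.ndarray:
    fmin, fmax = field.min(), field.max()
    if fmax - fmin < 1e-12:
        return np.full_like(field, 0.5 * (lo + hi))
    return lo + (field - fmin) * (hi - lo) / (fmax - fmin)


def _default_region_mask(shape: tuple[int, int]) -> np.ndarray:
    """Native west, invaded east, a thin 'other' band between."""
    rows, cols = shape
    mask = np.full((rows, cols), "other", dtype="<U8")
    native_end = max(1, int(0.4 * cols))
    invaded_start = min(cols - 1, int(0.6 * cols))
    mask[:, :native_end] = "native"
    mask[:, invaded_start:] = "invaded"
    return mask


def generate_env_stack(
    grid_shape: tuple[int, int],
    cell_size: float = 10.0,
    autocorrelation_length: float = 20.0,
    seed: int = 0,
) -> EnvStack:
    """Spatially autocorrelated environmental layers for the current scenario.

    Each layer is Gaussian-kernel-filtered white noise (kernel sd =
    ``autocorrelation_length / cell_size`` cells) rescaled to a realistic
    range; BIO5 >= BIO6 is enforced cellwise afterwards. Deterministic given
    ``seed``.
    """
    rows, cols = grid_shape
    if rows < 10 or cols < 10:
        raise ParameterError("grid must be at least 10x10")
    if cell_size <= 0 or autocorrelation_length <= 0:
        raise ParameterError("cell_size and autocorrelation_length must be > 0")
    sigma_cells = autocorrelation_length / cell_size
    rng = np.random.default_rng(seed)
    layers: dict[str, np.ndarray] = {}
    for name in VARIABLES:
        lo, hi = VARIABLE_RANGES[name]
        layers[name] = _rescale(_smooth_field(rng, grid_shape, sigma_cells), lo, hi)
    # warmest-month max can never fall below coldest-month min
    layers["BIO5"] = np.maximum(layers["BIO5"], layers["BIO6"] + 0.1)
    stack = EnvStack(
        grid_shape=grid_shape,
        cell_size=cell_size,
        variables=layers,
        scenario="current",
        region_mask=_default_region_mask(grid_shape),
    )
    stack.validate()
    return stack


def make_future_stack(
    current: EnvStack,
    deltas: dict[str, float | np.ndarray],
    scenario_label: str,
) -> EnvStack:
    """Additive climate shift; relief layers are carried over unchanged.

    ``deltas`` must provide a scalar or per-cell field for each climate
    variable. BIO12 falling below zero after the shift is clamped at zero
    with a logged warning.
    """
    missing = [v for v in CLIMATE_VARIABLES if v not in deltas]
    if missing:
        raise ParameterError(f"deltas missing for climate variables: {missing}")
    out = current.copy()
    out.scenario = scenario_label
    for v in CLIMATE_VARIABLES:
        shifted = current.variables[v] + np.asarray(deltas[v], dtype=float)
        if shifted.shape != current.grid_shape:
            raise AlignmentError(f"delta field for {v} does not match grid shape")
        if v == "BIO12":
            n_clamped = int(np.sum(shifted < 0))
            if n_clamped:
                logger.warning(
                    "BIO12 clamped at 0 in %d cells for scenario %s",
                    n_clamped,
                    scenario_label,
                )
                shifted = np.maximum(shifted, 0.0)
        out.variables[v] = shifted
    out.variables["BIO5"] = np.maximum(out.variables["BIO5"], out.variables["BIO6"])
    out.validate()
    return out


def average_climate_models(stacks: list[EnvStack]) -> EnvStack:
    """Cellwise arithmetic mean per variable across GCM realisations.

    Produces one single layer for each predictor and scenario, the standard
    multi-model ensemble mean used to reduce GCM uncertainty.
    """
    if not stacks:
        raise ParameterError("need at least one stack to average")
    first = stacks[0]
    for s in stacks[1:]:
        if s.grid_shape != first.grid_shape:
            raise AlignmentError("stacks have mismatched grids")
        if set(s.variables) != set(first.variables):
            raise AlignmentError("stacks have mismatched variable sets")
        if s.scenario != first.scenario:
            raise AlignmentError("stacks belong to different scenarios")
    out = first.copy()
    for v in first.variables:
        out.variables[v] = np.mean([s.variables[v] for s in stacks], axis=0)
    out.validate()
    return out


def sample_occurrences(
    sp: VirtualSpecies,
    env: EnvStack,
    n: int,
    design: str = "presence_only",
    region_filter: str | None = None,
    seed: int = 0,
) -> OccurrenceSet:
    """Draw an occurrence sample under a presence-only or atlas design.

    presence-only: ``n`` cells drawn without replacement with probability
    proportional to suitability (zero-suitability cells are never drawn).
    atlas: ``n`` cells drawn uniformly without replacement, each labelled
    present by a Bernoulli draw with p = suitability.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    cells = env.region_cells(region_filter)
    if len(cells) == 0:
        raise ParameterError(f"region filter {region_filter!r} selects no cells")
    rng = np.random.default_rng(seed)
    suit = sp.suitability(env)[cells[:, 0], cells[:, 1]]
    if design == "presence_only":
        positive = suit > 0
        if n > int(positive.sum()):
            raise SizeError(
                f"requested {n} presences but only {int(positive.sum())} cells "
                "have positive suitability"
            )
        p = np.where(positive, suit, 0.0)
        idx = rng.choice(len(cells), size=n, replace=False, p=p / p.sum())
        chosen = cells[idx]
        presence = np.ones(n, dtype=int)
    elif design == "atlas":
        if n > len(cells):
            raise SizeError(f"requested {n} atlas cells but region has {len(cells)}")
        idx = rng.choice(len(cells), size=n, replace=False)
        chosen = cells[idx]
        presence = (rng.random(n) < suit[idx]).astype(int)
    else:
        raise ParameterError(f"unknown design {design!r}")
    return OccurrenceSet(
        species=sp.name,
        rows=chosen[:, 0],
        cols=chosen[:, 1],
        presence=presence,
        region=region_filter or "all",
        design=design,
    )


def _voronoi_partition(grid_shape, n_seeds: int, rng: np.random.Generator) -> np.ndarray:
    """Partition the grid into compact patches by nearest seeded centre."""
    rows, cols = grid_shape
    n_cells = rows * cols
    seed_idx = rng.choice(n_cells, size=n_seeds, replace=False)
    sr, sc = np.unravel_index(seed_idx, grid_shape)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    d2 = (rr[..., None] - sr) ** 2 + (cc[..., None] - sc) ** 2
    return np.argmin(d2, axis=-1)  # ties -> lowest seed index


def generate_strata(grid_shape: tuple[int, int], k: int, seed: int = 0) -> StrataMap:
    """K contiguous-ish environmental strata via seeded growth regions."""
    rows, cols = grid_shape
    if not (1 <= k <= rows * cols):
        raise ParameterError("K must be in [1, number of cells]")
    rng = np.random.default_rng(seed)
    labels = _voronoi_partition(grid_shape, k, rng) + 1
    return StrataMap(labels=labels, k=k)


def generate_protection_mask(
    grid_shape: tuple[int, int],
    coverage_fraction: float,
    targeted_fraction: float,
    species_list: list[str],
    seed: int = 0,
) -> ProtectionMask:
    """Compact protected patches covering ~``coverage_fraction`` of cells.

    The grid is partitioned into small compact patches; patches are added to
    the protected set in random order until coverage is reached, and a random
    subset of the protected patches is flagged targeted (each assigned at
    least one species from ``species_list``) until ``targeted_fraction`` of
    all cells is targeted.
    """
    if not (0.0 < targeted_fraction <= coverage_fraction <= 1.0):
        raise ParameterError("need 0 < targeted_fraction <= coverage_fraction <= 1")
    if not species_list:
        raise ParameterError("species_list must be non-empty")
    rows, cols = grid_shape
    n_cells = rows * cols
    rng = np.random.default_rng(seed)
    # patch granularity ~1% of the grid keeps the realised coverage close to
    # the requested fraction while patches stay spatially compact
    n_patches = int(np.clip(n_cells // 100, 8, 400))
    patch_of = _voronoi_partition(grid_shape, n_patches, rng)
    patch_order = rng.permutation(n_patches)
    patch_sizes = np.bincount(patch_of.ravel(), minlength=n_patches)

    regime = np.zeros(grid_shape, dtype=int)
    protected_patches: list[int] = []
    covered = 0
    target = coverage_fraction * n_cells
    for p in patch_order:
        if covered >= target:
            break
        size = int(patch_sizes[p])
        # skip a patch whose addition would overshoot the target by more
        # than the current shortfall; keeps realised coverage ~requested
        if covered + size - target > target - covered:
            continue
        regime[patch_of == p] = REGIME_N2000
        protected_patches.append(int(p))
        covered += size

    targeted: dict[str, np.ndarray] = {s: np.zeros(grid_shape, dtype=bool) for s in species_list}
    targeted_cells = 0
    for p in rng.permutation(protected_patches):
        if targeted_cells >= targeted_fraction * n_cells:
            break
        members = patch_of == p
        regime[members] = REGIME_TARGETED
        n_species = 1 + int(rng.integers(0, min(2, len(species_list))))
        for s in rng.choice(species_list, size=n_species, replace=False):
            targeted[s][members] = True
        targeted_cells += int(patch_sizes[p])

    return ProtectionMask(regime=regime, targeted=targeted)
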
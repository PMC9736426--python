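"""Environmental (niche) space: correlation PCA, convex hulls, overlap.

Species environmental spaces are delimited as maximum convex polygons of
their occurrences projected into the first two principal components of the
standardized environmental variables; the intersection of two species'
polygons measures their niche overlap, and the count of one range's
occurrences falling strictly outside another range's hull diagnoses niche
shift versus conservatism.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Polygon
from shapely.geometry.polygon import orient

from .exceptions import (
    DegenerateHullError,
    DegenerateInputError,
    ParameterError,
    SchemaError,
)
from .synthetic import EnvStack, VARIABLES


@dataclass
class NicheSpace:
    """Standardization constants and loadings of the environmental PCA.

    The PCA is computed on centred, unit-variance variables (correlation
    PCA) because the predictors carry incommensurable units. Loadings are
    orthonormal eigenvector columns ordered by explained variance.
    """

    variable_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # variables x components
    explained_fraction: np.ndarray
    retained_k: int = 2

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.explained_fraction * len(self.variable_names)

    def variable_correlations(self) -> pd.DataFrame:
        """Correlation r between each variable and each component score."""
        r = self.loadings * np.sqrt(self.eigenvalues)[None, :]
        return pd.DataFrame(
            r,
            index=list(self.variable_names),
            columns=[f"PC{i + 1}" for i in range(r.shape[1])],
        )


def fit_pca(
    X: np.ndarray,
    variable_names: tuple[str, ...] = VARIABLES,
    retained_k: int = 2,
) -> NicheSpace:
    """Correlation PCA of a cells x variables calibration matrix.

    Implemented by SVD of the standardized matrix (sample sd, n-1), so score
    variances equal eigenvalues of the correlation matrix exactly.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < retained_k + 1:
        raise ParameterError(f"need at least {retained_k + 1} calibration cells")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    for j, s in enumerate(sds):
        if s <= 0:
            raise DegenerateInputError(f"variable {variable_names[j]} has zero variance")
    Z = (X - means) / sds
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = s**2 / (n - 1)
    loadings = vt.T
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    total = eigvals.sum()
    return NicheSpace(
        variable_names=tuple(variable_names),
        means=means,
        sds=sds,
        loadings=loadings,
        explained_fraction=eigvals / total,
        retained_k=retained_k,
    )


def fit_pca_env(env: EnvStack, calibration_cells: np.ndarray | None = None,
                variable_names: tuple[str, ...] = VARIABLES, retained_k: int = 2) -> NicheSpace:
    """PCA calibrated on all cells of the study area (or a given subset)."""
    X = env.to_matrix(variable_names)
    if calibration_cells is not None:
        flat = calibration_cells[:, 0] * env.grid_shape[1] + calibration_cells[:, 1]
        X = X[flat]
    return fit_pca(X, variable_names, retained_k)


def project(ns: NicheSpace, points: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Project environmental vectors into the retained components.

    Standardization uses the calibration means/sds stored in ``ns``, never
    the points' own statistics, so projections from different regions are
    comparable.
    """
    if isinstance(points, pd.DataFrame):
        missing = [v for v in ns.variable_names if v not in points.columns]
        if missing:
            raise SchemaError(f"points missing variables: {missing}")
        points = points[list(ns.variable_names)].to_numpy(dtype=float)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != len(ns.variable_names):
        raise SchemaError(
            f"expected {len(ns.variable_names)} variables, got {points.shape[1]}"
        )
    Z = (points - ns.means) / ns.sds
    return Z @ ns.loadings[:, : ns.retained_k]


def project_env_cells(ns: NicheSpace, env: EnvStack, cells: np.ndarray) -> np.ndarray:
    """Scores of specific grid cells."""
    X = np.column_stack([env.variables[v][cells[:, 0], cells[:, 1]] for v in ns.variable_names])
    return project(ns, X)


@dataclass
class HullPolygon:
    """Maximum convex polygon of a species' projected occurrences."""

    species: str
    vertices: np.ndarray  # (k, 2), counterclockwise

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area


def convex_hull(scores: np.ndarray, species: str = "") -> HullPolygon:
    """Minimal convex polygon containing every score point."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ParameterError("scores must be (n, 2)")
    if len(scores) < 3:
        raise ParameterError("need at least 3 points for a hull")
    hull = MultiPoint(scores).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0.0:
        raise DegenerateHullError("all points collinear; hull has no area")
    hull = orient(hull, sign=1.0)  # counterclockwise
    verts = np.asarray(hull.exterior.coords)[:-1]
    return HullPolygon(species=species, vertices=verts)


@dataclass
class OverlapResult:
    """Pairwise hull intersection in PC-space units squared."""

    species_a: str
    species_b: str
    area_a: float
    area_b: float
    area_intersection: float
    fraction_of_a: float
    fraction_of_b: float
    n_outside: int | None = None
    fraction_outside: float | None = None


def overlap(a: HullPolygon, b: HullPolygon) -> OverlapResult:
    """Convex-polygon intersection area as the niche-overlap measure.

    Fractions divide the intersection by each species' own hull area, so
    both readings of "X% of a species' environmental space" are available.
    Disjoint hulls give zero intersection, not an error.
    """
    pa, pb = a.polygon, b.polygon
    inter = pa.intersection(pb).area
    return OverlapResult(
        species_a=a.species,
        species_b=b.species,
        area_a=pa.area,
        area_b=pb.area,
        area_intersection=inter,
        fraction_of_a=inter / pa.area if pa.area > 0 else 0.0,
        fraction_of_b=inter / pb.area if pb.area > 0 else 0.0,
    )


def points_outside(scores: np.ndarray, hull: HullPolygon) -> tuple[int, float]:
    """Count score points strictly outside a hull (boundary counts inside)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    pts = shapely.points(scores[:, 0], scores[:, 1])
    inside = shapely.covers(hull.polygon, pts)
    n_out = int(np.sum(~inside))
    return n_out, n_out / len(scores)
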
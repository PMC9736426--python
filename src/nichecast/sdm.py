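"""Ensemble climatic-suitability models.

Five presence/absence classifier families (GLM, GAM, MARS, GBM, FDA) are
fitted on replicated, environmentally stratified presence-absence samples,
evaluated by test AUC on a random 70/30 split, and combined into a single
consensus: members with test AUC > 0.7 are retained and averaged with their
AUC values as weights. Predictors are the three climate variables (BIO5,
BIO6, BIO12); relief enters only the niche-space PCA, because projecting
altitude and slope to a future climate is meaningless. A config flag
(``predictor_names``) can add static relief covariates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler

from .exceptions import (
    EmptyEnsembleError,
    FitError,
    ParameterError,
    SchemaError,
    SizeError,
    SplitError,
    UndefinedAUCError,
)
from .synthetic import CLIMATE_VARIABLES, EnvStack, OccurrenceSet, StrataMap

logger = logging.getLogger(__name__)

FAMILIES = ("GLM", "GAM", "MARS", "GBM", "FDA")

#: Fixed family hyperparameters; the analysis favours reproducibility over
#: per-dataset tuning, so these are constants, not search spaces.
DEFAULT_HYPERPARAMS = {
    "GLM": {"C": 1e4, "max_iter": 5000},
    "GAM": {"n_knots": 5, "degree": 3, "C": 1.0, "max_iter": 5000},
    "MARS": {"max_terms": 11, "n_knot_candidates": 7},
    "GBM": {"n_estimators": 150, "learning_rate": 0.05, "max_depth": 3},
    "FDA": {"n_knots": 5, "degree": 2},
}


# ---------------------------------------------------------------------------
# training data


@dataclass
class TrainingSample:
    """Presence/absence records with their climate predictor vectors."""

    X: np.ndarray  # (n, p)
    y: np.ndarray  # (n,) in {0, 1}
    cells: np.ndarray  # (n, 2) grid indices
    provenance: np.ndarray  # 'presence' | 'true_absence' | 'pseudo_absence'
    predictor_names: tuple[str, ...] = CLIMATE_VARIABLES

    def __post_init__(self):
        if not np.all(np.isfinite(self.X)):
            raise ParameterError("predictors must be finite")
        if self.y.sum() == 0 or self.y.sum() == len(self.y):
            raise ParameterError("need at least one presence and one absence")


def predictor_matrix(env: EnvStack, cells: np.ndarray,
                     predictor_names: tuple[str, ...] = CLIMATE_VARIABLES) -> np.ndarray:
    try:
        return np.column_stack(
            [env.variables[v][cells[:, 0], cells[:, 1]] for v in predictor_names]
        )
    except KeyError as exc:
        raise SchemaError(f"environment missing predictor {exc}") from exc


def _largest_remainder(weights: np.ndarray, n: int, caps: np.ndarray) -> np.ndarray:
    """Apportion n among groups proportionally to weights, capped by size.

    Floors of the exact quotas are taken first; remaining units go to the
    largest fractional remainders (ties broken toward the larger group, then
    lower index), never exceeding a group's cap.
    """
    quotas = n * weights / weights.sum()
    alloc = np.minimum(np.floor(quotas).astype(int), caps)
    remainders = quotas - np.floor(quotas)
    order = np.lexsort((np.arange(len(weights)), -weights, -remainders))
    i = 0
    while alloc.sum() < n:
        g = order[i % len(order)]
        if alloc[g] < caps[g]:
            alloc[g] += 1
        i += 1
        if i > 10 * len(order) and alloc.sum() < n:  # caps too tight
            raise SizeError("cannot apportion sample within stratum caps")
    return alloc


def stratified_cell_sample(cells: np.ndarray, strata: StrataMap, n: int,
                           seed: int = 0) -> np.ndarray:
    """Sample n cells, allocated across strata by largest-remainder rule."""
    cells = np.asarray(cells)
    if n > len(cells):
        raise SizeError(f"pool ({len(cells)}) smaller than n ({n})")
    labels = strata.stratum_of(cells)
    ids = np.unique(labels)
    sizes = np.array([(labels == s).sum() for s in ids])
    alloc = _largest_remainder(sizes.astype(float), n, sizes)
    rng = np.random.default_rng(seed)
    chosen = []
    for s, k in zip(ids, alloc):
        if k == 0:
            continue
        pool = cells[labels == s]
        idx = rng.choice(len(pool), size=k, replace=False)
        chosen.append(pool[idx])
    return np.vstack(chosen)


def stratified_pseudoabsences(
    presences: OccurrenceSet,
    strata: StrataMap,
    background_cells: np.ndarray,
    n: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Pseudo-absence cells, stratified across ecoregion-like strata.

    Allocation across strata is proportional to each stratum's background
    size (largest-remainder rounding); within a stratum cells are sampled
    uniformly without replacement. ``n`` defaults to the presence count, the
    equal-size convention for presence-only data. Presence cells are always
    excluded from the background.
    """
    pres = presences.presence_cells
    if n is None:
        n = len(pres)
    background_cells = np.asarray(background_cells)
    pres_flat = set(map(tuple, pres))
    keep = [i for i, c in enumerate(map(tuple, background_cells)) if c not in pres_flat]
    background_cells = background_cells[keep]
    if n > len(background_cells):
        raise SizeError(f"background ({len(background_cells)}) smaller than n ({n})")
    return stratified_cell_sample(background_cells, strata, n, seed)


def build_training_sample(
    env: EnvStack,
    presence_cells: np.ndarray,
    absence_cells: np.ndarray,
    absence_provenance: str = "pseudo_absence",
    predictor_names: tuple[str, ...] = CLIMATE_VARIABLES,
) -> TrainingSample:
    cells = np.vstack([presence_cells, absence_cells])
    y = np.concatenate([np.ones(len(presence_cells), int), np.zeros(len(absence_cells), int)])
    prov = np.array(["presence"] * len(presence_cells) + [absence_provenance] * len(absence_cells))
    return TrainingSample(
        X=predictor_matrix(env, cells, predictor_names),
        y=y,
        cells=cells,
        provenance=prov,
        predictor_names=predictor_names,
    )


def split_sample(sample: TrainingSample, train_fraction: float = 0.7,
                 seed: int = 0) -> tuple[TrainingSample, TrainingSample]:
    """Random 70/30 split, stratified by the presence/absence label."""
    if not (0 < train_fraction < 1):
        raise ParameterError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for label in (0, 1):
        idx = np.flatnonzero(sample.y == label)
        if len(idx) < 2:
            raise SplitError(f"class {label} has fewer than 2 records")
        idx = rng.permutation(idx)
        k = int(round(train_fraction * len(idx)))
        k = min(max(k, 1), len(idx) - 1)  # both classes in both parts
        train_idx.append(idx[:k])
        test_idx.append(idx[k:])
    train_idx = np.concatenate(train_idx)
    test_idx = np.concatenate(test_idx)

    def subset(idx):
        return TrainingSample(
            X=sample.X[idx], y=sample.y[idx], cells=sample.cells[idx],
            provenance=sample.provenance[idx], predictor_names=sample.predictor_names,
        )

    return subset(train_idx), subset(test_idx)


# ---------------------------------------------------------------------------
# AUC


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve as the normalized Mann-Whitney statistic.

    Equals the probability that a random presence outscores a random
    absence; tied scores contribute one half. 0.5 is chance, 1 perfect.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedAUCError("AUC undefined: only one class present")
    ranks = rankdata(scores)  # average ranks on ties
    r1 = ranks[labels == 1].sum()
    return (r1 - n1 * (n1 + 1) / 2) / (n1 * n0)


# ---------------------------------------------------------------------------
# model families


class MarsLogistic:
    """Multivariate adaptive regression splines with a logistic link.

    Forward pass: greedily add reflected hinge pairs max(x-t, 0)/max(t-x, 0)
    at quantile knots, choosing the pair with the largest residual
    sum-of-squares drop. Backward pass: prune single basis columns while the
    generalized cross-validation score improves. The selected basis is then
    calibrated with a ridge-penalized logistic regression so outputs are
    probabilities in [0, 1].
    """

    def __init__(self, max_terms: int = 11, n_knot_candidates: int = 7, penalty: float = 3.0):
        self.max_terms = max_terms
        self.n_knot_candidates = n_knot_candidates
        self.penalty = penalty
        self.basis_: list[tuple[int, float, int]] = []  # (var, knot, sign)

    def _design(self, X: np.ndarray, basis) -> np.ndarray:
        cols = [np.ones(len(X))]
        for var, knot, sign in basis:
            cols.append(np.maximum(sign * (X[:, var] - knot), 0.0))
        return np.column_stack(cols)

    @staticmethod
    def _rss(B: np.ndarray, y: np.ndarray) -> float:
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        r = y - B @ coef
        return float(r @ r)

    def _gcv(self, B: np.ndarray, y: np.ndarray) -> float:
        n, m = B.shape
        c = m + self.penalty * (m - 1) / 2.0
        if c >= n:
            return np.inf
        return (self._rss(B, y) / n) / (1.0 - c / n) ** 2

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        qs = np.linspace(0.1, 0.9, self.n_knot_candidates)
        candidates = [
            (v, float(k))
            for v in range(X.shape[1])
            for k in np.unique(np.quantile(X[:, v], qs))
        ]
        basis: list[tuple[int, float, int]] = []
        best_rss = self._rss(self._design(X, basis), y)
        used: set[tuple[int, float]] = set()
        while len(basis) + 2 <= self.max_terms:
            best = None
            for v, k in candidates:
                if (v, k) in used:
                    continue
                trial = basis + [(v, k, 1), (v, k, -1)]
                rss = self._rss(self._design(X, trial), y)
                if best is None or rss < best[0]:
                    best = (rss, v, k)
            if best is None or best[0] > best_rss - 1e-10:
                break
            best_rss = best[0]
            basis += [(best[1], best[2], 1), (best[1], best[2], -1)]
            used.add((best[1], best[2]))
        # backward prune by GCV
        improved = True
        while improved and basis:
            gcv_full = self._gcv(self._design(X, basis), y)
            improved = False
            for i in range(len(basis)):
                trial = basis[:i] + basis[i + 1:]
                if self._gcv(self._design(X, trial), y) < gcv_full:
                    basis = trial
                    improved = True
                    break
        self.basis_ = basis
        B = self._design(X, basis)[:, 1:]  # logistic supplies its own intercept
        if B.shape[1] == 0:
            B = X  # no hinge survived; fall back to the raw predictors
            self._fallback = True
        else:
            self._fallback = False
        self._logit = Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(C=1.0, max_iter=5000)),
        ])
        self._logit.fit(B, y.astype(int))
        return self

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        B = X if self._fallback else self._design(X, self.basis_)[:, 1:]
        return self._logit.predict_proba(B)[:, 1]


class _SklearnProbModel:
    """Wrap a fitted sklearn classifier into the member contract."""

    def __init__(self, model):
        self.model = model

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(np.asarray(X, float))[:, 1]


@dataclass
class FittedMember:
    """One fitted classifier of one family in one replicate."""

    family: str
    replicate: int
    model: object
    test_auc: float = np.nan

    def predict(self, X: np.ndarray) -> np.ndarray:
        p = self.model.predict_proba_pos(X)
        return np.clip(p, 0.0, 1.0)


def _make_glm(hp) -> Pipeline:
    return Pipeline([
        ("poly", PolynomialFeatures(degree=2, include_bias=False)),
        ("scale", StandardScaler()),
        ("clf", LogisticRegression(C=hp["C"], max_iter=hp["max_iter"])),
    ])


def _make_gam(hp) -> Pipeline:
    return Pipeline([
        ("spline", SplineTransformer(n_knots=hp["n_knots"], degree=hp["degree"],
                                     include_bias=False)),
        ("scale", StandardScaler()),
        ("clf", LogisticRegression(C=hp["C"], max_iter=hp["max_iter"])),
    ])


def _make_fda(hp) -> Pipeline:
    return Pipeline([
        ("spline", SplineTransformer(n_knots=hp["n_knots"], degree=hp["degree"],
                                     include_bias=False)),
        ("scale", StandardScaler()),
        ("clf", LinearDiscriminantAnalysis()),
    ])


def glm_linear_coefficients(member: FittedMember) -> np.ndarray:
    """Input-scale coefficients of a GLM member's linear terms."""
    if member.family != "GLM":
        raise ParameterError("linear coefficients only defined for GLM members")
    pipe = member.model.model
    poly, scale, clf = pipe["poly"], pipe["scale"], pipe["clf"]
    p = int(np.sum(poly.powers_.sum(axis=1) == 1))
    return clf.coef_[0, :p] / scale.scale_[:p]


def fit_member(family: str, train: TrainingSample, seed: int = 0,
               replicate: int = 0, hyperparams: dict | None = None) -> FittedMember:
    """Fit one [0,1]-valued presence/absence classifier of the given family."""
    if family not in FAMILIES:
        raise ParameterError(f"unknown family {family!r}; valid: {FAMILIES}")
    hp = dict(DEFAULT_HYPERPARAMS[family])
    if hyperparams:
        hp.update(hyperparams)
    try:
        if family == "GLM":
            model = _SklearnProbModel(_make_glm(hp).fit(train.X, train.y))
        elif family == "GAM":
            model = _SklearnProbModel(_make_gam(hp).fit(train.X, train.y))
        elif family == "FDA":
            model = _SklearnProbModel(_make_fda(hp).fit(train.X, train.y))
        elif family == "GBM":
            gbm = GradientBoostingClassifier(
                n_estimators=hp["n_estimators"], learning_rate=hp["learning_rate"],
                max_depth=hp["max_depth"], random_state=seed,
            )
            model = _SklearnProbModel(gbm.fit(train.X, train.y))
        else:  # MARS
            model = MarsLogistic(max_terms=hp["max_terms"],
                                 n_knot_candidates=hp["n_knot_candidates"]).fit(train.X, train.y)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise FitError(family, replicate, str(exc)) from exc
    return FittedMember(family=family, replicate=replicate, model=model)


# ---------------------------------------------------------------------------
# ensemble


@dataclass
class SDMEnsemble:
    """AUC-weighted consensus of retained members across all replicates."""

    species: str
    members: list[FittedMember]  # retained only
    weights: np.ndarray  # aligned with members; positive, sums to 1
    all_members: list[FittedMember]
    auc_threshold: float
    eval_table: pd.DataFrame  # family-level mean/sd of test AUC
    member_table: pd.DataFrame  # family, replicate, test_auc, retained, weight
    predictor_names: tuple[str, ...] = CLIMATE_VARIABLES

    @property
    def mean_auc(self) -> float:
        return float(np.mean([m.test_auc for m in self.all_members]))

    @property
    def sd_auc(self) -> float:
        return float(np.std([m.test_auc for m in self.all_members], ddof=1))


@dataclass
class SuitabilityMap:
    """Grid of ensemble suitability scores for one species and scenario."""

    values: np.ndarray
    species: str
    scenario: str


def retain_members(aucs: np.ndarray, auc_threshold: float = 0.7
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Retention mask (test AUC strictly > threshold) and normalized weights.

    Weights are the raw AUC values of the retained members rescaled to sum
    to one; a member at or below the threshold never contributes.
    """
    aucs = np.asarray(aucs, float)
    mask = aucs > auc_threshold
    if not mask.any():
        raise EmptyEnsembleError(f"no member exceeded AUC {auc_threshold}")
    weights = aucs[mask] / aucs[mask].sum()
    return mask, weights


def weighted_consensus(aucs: np.ndarray, predictions: np.ndarray) -> np.ndarray:
    """AUC-weighted mean of member predictions (members x cells)."""
    w = np.asarray(aucs, float)
    return (w[:, None] * predictions).sum(axis=0) / w.sum()


def build_ensemble(
    occ: OccurrenceSet,
    env: EnvStack,
    strata: StrataMap,
    background_cells: np.ndarray | None = None,
    R: int = 10,
    families: tuple[str, ...] = FAMILIES,
    auc_threshold: float = 0.7,
    seed: int = 0,
    predictor_names: tuple[str, ...] = CLIMATE_VARIABLES,
    train_fraction: float = 0.7,
) -> SDMEnsemble:
    """Fit R replicates x families and combine members with AUC > threshold.

    Each replicate draws a fresh environmentally stratified absence sample
    (pseudo-absences of equal size for presence-only data; a stratified
    subsample of recorded absences for atlas data), splits it 70/30, fits
    every family on the training part and scores test AUC on the held-out
    part. Members with test AUC strictly greater than ``auc_threshold`` are
    retained with weights proportional to their AUC.
    """
    if R < 1:
        raise ParameterError("R must be >= 1")
    pres = occ.presence_cells
    if len(pres) < 10:
        raise SizeError("need at least 10 presence records")
    if background_cells is None:
        background_cells = env.region_cells(occ.region if occ.region != "all" else None)
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3 * R)]

    members: list[FittedMember] = []
    for r in range(R):
        draw_seed, split_seed, fit_seed = rep_seeds[3 * r: 3 * r + 3]
        if occ.design == "atlas" and len(occ.absence_cells) > 0:
            n_abs = min(len(pres), len(occ.absence_cells))
            absences = stratified_cell_sample(
                occ.absence_cells, strata, n_abs, seed=draw_seed)
            provenance = "true_absence"
        else:
            absences = stratified_pseudoabsences(
                occ, strata, background_cells, n=None, seed=draw_seed)
            provenance = "pseudo_absence"
        sample = build_training_sample(env, pres, absences, provenance, predictor_names)
        train, test = split_sample(sample, train_fraction, seed=split_seed)
        for family in families:
            member = fit_member(family, train, seed=fit_seed, replicate=r)
            member.test_auc = auc(test.y, member.predict(test.X))
            members.append(member)

    aucs = np.array([m.test_auc for m in members])
    try:
        retained_mask, weights = retain_members(aucs, auc_threshold)
    except EmptyEnsembleError as exc:
        raise EmptyEnsembleError(f"{occ.species}: {exc}") from exc
    retained = [m for m, keep in zip(members, retained_mask) if keep]
    logger.info("%s: retained %d/%d members (AUC > %.2f)",
                occ.species, len(retained), len(members), auc_threshold)

    member_table = pd.DataFrame({
        "family": [m.family for m in members],
        "replicate": [m.replicate for m in members],
        "test_auc": aucs,
        "retained": retained_mask,
    })
    member_table["weight"] = 0.0
    member_table.loc[retained_mask, "weight"] = weights
    eval_table = (
        member_table.groupby("family")["test_auc"].agg(["mean", "std"])
        .rename(columns={"mean": "mean_auc", "std": "sd_auc"}).reset_index()
    )
    return SDMEnsemble(
        species=occ.species, members=retained, weights=weights,
        all_members=members, auc_threshold=auc_threshold,
        eval_table=eval_table, member_table=member_table,
        predictor_names=predictor_names,
    )


def predict_suitability(ens: SDMEnsemble, env: EnvStack) -> SuitabilityMap:
    """Project the AUC-weighted consensus onto a (current or future) stack."""
    X = np.column_stack([env.variables[v].ravel() for v in ens.predictor_names
                         if v in env.variables])
    if X.shape[1] != len(ens.predictor_names):
        missing = [v for v in ens.predictor_names if v not in env.variables]
        raise SchemaError(f"environment missing predictors: {missing}")
    preds = np.vstack([m.predict(X) for m in ens.members])
    consensus = (ens.weights[:, None] * preds).sum(axis=0)
    return SuitabilityMap(values=consensus.reshape(env.grid_shape),
                          species=ens.species, scenario=env.scenario)


def evaluate_transfer(
    ens: SDMEnsemble,
    occ_b: OccurrenceSet,
    env: EnvStack,
    strata: StrataMap,
    seed: int = 0,
) -> float:
    """Transfer AUC: observed occurrences in a new region vs the projection.

    Presences of ``occ_b`` are scored against an equal-size stratified
    pseudo-absence sample from the new region's background.
    """
    pres = occ_b.presence_cells
    background = env.region_cells(occ_b.region if occ_b.region != "all" else None)
    absences = stratified_pseudoabsences(occ_b, strata, background, n=len(pres), seed=seed)
    cells = np.vstack([pres, absences])
    labels = np.concatenate([np.ones(len(pres), int), np.zeros(len(absences), int)])
    X = predictor_matrix(env, cells, ens.predictor_names)
    preds = np.vstack([m.predict(X) for m in ens.members])
    scores = (ens.weights[:, None] * preds).sum(axis=0)
    return auc(labels, scores)
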
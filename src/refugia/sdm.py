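"""Presence/pseudo-absence suitability modelling and evaluation.

Occurrences are thinned to one per grid cell, contrasted against several
sets of uniformly sampled pseudo-absences, and modelled on the two principal
component predictors with a small committee of algorithms: a surface range
envelope (SRE), a maximum-likelihood logistic regression on a degree-2
polynomial expansion, and optionally gradient-boosted trees. Each
(algorithm x pseudo-absence set x split repeat) member is evaluated on its
held-out 30% with AUC (Mann-Whitney rank form) and the true skill statistic
(TSS, maximised over all candidate thresholds); members passing a TSS
cut-off are committee-averaged into habitat suitability surfaces for all
time slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression

from ._seeds import derive_seed
from .raster import Raster, assert_same_grid
from .synthetic import SLICE_LABELS, OccurrenceSet


# ---------------------------------------------------------------------------
# Data assembly
# ---------------------------------------------------------------------------

def thin_occurrences(raw: OccurrenceSet, grid: Raster) -> OccurrenceSet:
    """One occurrence per grid cell; the first record in input order wins."""
    t = raw.table
    if len(t) == 0:
        warnings.warn("thinning an empty occurrence set")
        return OccurrenceSet(t.copy())
    rc = raw.rc
    if np.any((rc < 0) | (rc >= [grid.nrows, grid.ncols])):
        raise ValueError("occurrences fall outside the grid extent")
    return OccurrenceSet(t.drop_duplicates(subset=["row", "col"], keep="first"))


def sample_pseudo_absences(
    domain: Raster,
    presences: OccurrenceSet,
    n_sets: int = 10,
    n_each: int = 10_000,
    seed: int = 0,
) -> list[np.ndarray]:
    """Uniform without-replacement background samples, excluding presence cells.

    Returns ``n_sets`` arrays of (row, col) pairs. When the domain has fewer
    candidate cells than ``n_each`` (desk-scale grids are far smaller than a
    real study area), ``n_each`` is reduced with a warning.
    """
    candidates = domain.mask & ~presences.cell_mask(domain)
    rows, cols = np.nonzero(candidates)
    if rows.size == 0:
        raise ValueError("no candidate cells for pseudo-absences")
    if n_each > rows.size:
        warnings.warn(
            f"n_each={n_each} exceeds the {rows.size} candidate cells; reduced"
        )
        n_each = rows.size
    sets = []
    for i in range(n_sets):
        rng = np.random.default_rng(derive_seed(seed, "pseudo_absence", i))
        pick = rng.choice(rows.size, size=n_each, replace=False)
        pick.sort()
        sets.append(np.column_stack([rows[pick], cols[pick]]))
    return sets


@dataclass
class PresenceBackground:
    """Thinned presences, pseudo-absence sets, and their predictor values."""

    presence_rc: np.ndarray           # (n_pres, 2)
    pa_sets: list[np.ndarray]         # each (n_abs, 2)
    x_presence: np.ndarray            # (n_pres, 2) PC1, PC2
    x_absence: list[np.ndarray]       # per set (n_abs, 2)

    @property
    def n_sets(self) -> int:
        return len(self.pa_sets)

    def training_xy(self, set_idx: int) -> tuple[np.ndarray, np.ndarray]:
        """Stacked design (presences first) and 0/1 labels for one PA set."""
        X = np.vstack([self.x_presence, self.x_absence[set_idx]])
        y = np.concatenate([
            np.ones(len(self.x_presence)), np.zeros(len(self.x_absence[set_idx]))
        ])
        return X, y


def extract_predictors(pc: Raster, rc: np.ndarray) -> np.ndarray:
    """(n, nbands) predictor values at (row, col) cells of a multi-band raster."""
    d = pc.data if pc.data.ndim == 3 else pc.data[None]
    return d[:, rc[:, 0], rc[:, 1]].T


def build_presence_background(
    occ: OccurrenceSet, pc_current: Raster, pa_sets: Sequence[np.ndarray]
) -> PresenceBackground:
    rc = occ.rc
    if len(np.unique(rc, axis=0)) != len(rc):
        raise ValueError("occurrences must be thinned (one per cell) first")
    return PresenceBackground(
        presence_rc=rc,
        pa_sets=list(pa_sets),
        x_presence=extract_predictors(pc_current, rc),
        x_absence=[extract_predictors(pc_current, s) for s in pa_sets],
    )


def split_cv(
    n_presence: int,
    n_absence: int,
    train_frac: float = 0.7,
    repeats: int = 10,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated stratified 70/30 split-sample partitions.

    Indices run over the stacked design (presences first). Each class is
    split separately with ``floor(train_frac * n)`` cells on the training
    side. A repeat leaving fewer than 2 test presences is redrawn once with
    a warning, then accepted as drawn.
    """
    if n_presence < 10:
        raise ValueError("split-sample cross-validation needs at least 10 presences")
    out = []
    for rep in range(repeats):
        for attempt in range(2):
            rng = np.random.default_rng(derive_seed(seed, "cv", rep, attempt))
            tr_parts, te_parts = [], []
            for offset, n in ((0, n_presence), (n_presence, n_absence)):
                perm = offset + rng.permutation(n)
                k = int(np.floor(train_frac * n))
                tr_parts.append(perm[:k])
                te_parts.append(perm[k:])
            train = np.sort(np.concatenate(tr_parts))
            test = np.sort(np.concatenate(te_parts))
            if n_presence - int(np.floor(train_frac * n_presence)) >= 2 or attempt == 1:
                break
            warnings.warn(f"repeat {rep}: fewer than 2 test presences; redrawing once")
        out.append((train, test))
    return out


# ---------------------------------------------------------------------------
# Member models
# ---------------------------------------------------------------------------

@dataclass
class SREModel:
    """Surface range envelope: inside all per-predictor quantile intervals -> 1."""

    lower: np.ndarray
    upper: np.ndarray
    binary: bool = True

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        inside = (X >= self.lower) & (X <= self.upper)
        return inside.all(axis=1).astype(float)


def fit_sre(x_presence: np.ndarray, q: float = 0.025) -> SREModel:
    """Envelope between the q and 1-q empirical quantiles of presence values."""
    x_presence = np.asarray(x_presence, dtype=float)
    if len(x_presence) < 2:
        raise ValueError("SRE needs at least 2 presences")
    if not 0 <= q < 0.5:
        raise ValueError("quantile q must be in [0, 0.5)")
    lower = np.quantile(x_presence, q, axis=0)
    upper = np.quantile(x_presence, 1 - q, axis=0)
    return SREModel(lower=lower, upper=upper)


def _poly2_expand(X: np.ndarray) -> np.ndarray:
    x1, x2 = X[:, 0], X[:, 1]
    return np.column_stack([x1, x2, x1 * x1, x1 * x2, x2 * x2])


@dataclass
class LogisticPoly2Model:
    """Logistic regression on [x1, x2, x1^2, x1*x2, x2^2], predictors standardised."""

    means: np.ndarray
    sds: np.ndarray
    coef: np.ndarray      # (6,) including intercept
    penalized: bool = False

    def _design(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.means) / self.sds
        E = _poly2_expand(Z)
        return np.column_stack([np.ones(len(E)), E])

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = self._design(X) @ self.coef
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))


def fit_logistic_poly2(X: np.ndarray, y: np.ndarray) -> LogisticPoly2Model:
    """Maximum-likelihood logistic fit (IRLS); small-L2 fallback on separation."""
    X, y = np.asarray(X, dtype=float), np.asarray(y, dtype=float)
    if X.shape[1] != 2:
        raise ValueError("logistic_poly2 expects two predictors (PC1, PC2)")
    means, sds = X.mean(axis=0), X.std(axis=0)
    sds = np.where(sds > 1e-12, sds, 1.0)
    model = LogisticPoly2Model(means=means, sds=sds, coef=np.zeros(6))
    D = model._design(X)
    coef = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, D, family=sm.families.Binomial()).fit(maxiter=200, tol=1e-10)
            params = np.asarray(res.params)
            if np.all(np.isfinite(params)) and np.abs(params).max() < 1e3:
                coef = params
        except Exception:
            coef = None
    if coef is None:  # (quasi-)separation: penalised fallback, flagged
        lr = LogisticRegression(penalty="l2", C=1.0, solver="lbfgs", max_iter=1000)
        lr.fit(D[:, 1:], y)
        coef = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        model.penalized = True
    model.coef = coef
    return model


@dataclass
class BoostedTreesModel:
    """Gradient-boosted classification trees (established implementation)."""

    clf: GradientBoostingClassifier

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict_proba(np.asarray(X, dtype=float))[:, 1]


def fit_boosted_trees(X: np.ndarray, y: np.ndarray, seed: int = 0) -> BoostedTreesModel:
    clf = GradientBoostingClassifier(
        n_estimators=100, max_depth=3, learning_rate=0.1, random_state=seed
    )
    clf.fit(np.asarray(X, dtype=float), np.asarray(y))
    return BoostedTreesModel(clf=clf)


def fit_parametric(X: np.ndarray, y: np.ndarray, family: str, seed: int = 0):
    """Fit a probabilistic member: ``logistic_poly2`` or ``boosted_trees``."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if family == "logistic_poly2":
        return fit_logistic_poly2(X, y)
    if family == "boosted_trees":
        return fit_boosted_trees(X, y, seed=seed)
    raise ValueError(f"unknown model family {family!r}")


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------

def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("evaluation needs both presences and absences")
    return labels, ~labels


def evaluate_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC in the Mann-Whitney rank form; ties earn half credit."""
    pos, neg = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    ranks = rankdata(scores)
    n1, n0 = pos.sum(), neg.sum()
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def evaluate_tss(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Max over thresholds of sensitivity + specificity - 1.

    Candidate thresholds are the distinct score values; a cell is predicted
    present when its score is >= the threshold. Ties on the maximum go to
    the smallest threshold.
    """
    pos, neg = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    thr = np.unique(scores)
    sp = np.sort(scores[pos])
    sn = np.sort(scores[neg])
    # sensitivity: fraction of presences with score >= t; specificity: absences < t
    sens = (sp.size - np.searchsorted(sp, thr, side="left")) / sp.size
    spec = np.searchsorted(sn, thr, side="left") / sn.size
    tss = sens + spec - 1.0
    best = int(np.argmax(tss))  # argmax returns the first (smallest) threshold
    return float(tss[best]), float(thr[best])


@dataclass
class EvalResult:
    """Held-out performance of one ensemble member."""

    algorithm: str
    pa_set: int
    repeat: int
    auc: float
    tss: float
    tss_threshold: float


# ---------------------------------------------------------------------------
# Ensemble fitting and projection
# ---------------------------------------------------------------------------

@dataclass
class FittedMember:
    algorithm: str
    pa_set: int
    repeat: int
    model: object
    eval: EvalResult


@dataclass
class SuitabilityStack:
    """Committee-mean habitat suitability for the four time slices."""

    species: str
    scenario: str
    rasters: list[Raster]             # current + 3 future, co-registered
    slice_labels: list[str] = field(default_factory=lambda: list(SLICE_LABELS))

    def __post_init__(self) -> None:
        if len(self.rasters) != 4:
            raise ValueError("a suitability stack holds exactly 4 time slices")
        assert_same_grid(*self.rasters)
        for r in self.rasters:
            v = r.data[r.mask]
            if v.size and (v.min() < 0 or v.max() > 1):
                raise ValueError("habitat suitability must lie in [0, 1]")

    @property
    def grid(self) -> Raster:
        return self.rasters[0]

    @property
    def current(self) -> Raster:
        return self.rasters[0]

    @property
    def future(self) -> list[Raster]:
        return self.rasters[1:]


def fit_ensemble(
    pb: PresenceBackground,
    algorithms: Sequence[str] = ("sre", "logistic_poly2"),
    sre_quantile: float = 0.025,
    train_frac: float = 0.7,
    repeats: int = 10,
    seed: int = 0,
) -> list[FittedMember]:
    """Fit every (algorithm x pseudo-absence set x split repeat) member."""
    members: list[FittedMember] = []
    n_pres = len(pb.x_presence)
    for i in range(pb.n_sets):
        X, y = pb.training_xy(i)
        splits = split_cv(n_pres, len(pb.x_absence[i]), train_frac=train_frac,
                          repeats=repeats, seed=derive_seed(seed, "splits", i))
        for j, (train, test) in enumerate(splits):
            for algo in algorithms:
                if algo == "sre":
                    pres_train = train[train < n_pres]
                    model = fit_sre(X[pres_train], q=sre_quantile)
                else:
                    model = fit_parametric(X[train], y[train], family=algo,
                                           seed=derive_seed(seed, "fit", algo, i, j))
                scores = model.predict(X[test])
                auc = evaluate_auc(scores, y[test])
                tss, thr = evaluate_tss(scores, y[test])
                ev = EvalResult(algo, i, j, auc=auc, tss=tss, tss_threshold=thr)
                members.append(FittedMember(algo, i, j, model=model, eval=ev))
    return members


def evals_table(members: Sequence[FittedMember]) -> pd.DataFrame:
    return pd.DataFrame([{
        "algorithm": m.algorithm, "pa_set": m.pa_set, "repeat": m.repeat,
        "auc": m.eval.auc, "tss": m.eval.tss, "tss_threshold": m.eval.tss_threshold,
    } for m in members])


def summarize_evals(members: Sequence[FittedMember]) -> pd.DataFrame:
    """Mean and standard deviation of AUC and TSS per algorithm."""
    t = evals_table(members)
    out = t.groupby("algorithm")[["auc", "tss"]].agg(["mean", "std"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()


def ensemble_predict(
    members: Sequence[FittedMember],
    predictors: Mapping[str, Raster],
    tss_min: float = 0.4,
    species: str = "species_1",
    scenario: str = "ssp245",
) -> SuitabilityStack:
    """Committee-mean habitat suitability over members with TSS >= tss_min.

    ``predictors`` maps each of the four slice labels to its 2-band PC
    raster. Binary members (SRE) contribute 0/1; output is clipped to [0,1].
    """
    passing = [m for m in members if m.eval.tss >= tss_min]
    if not passing:
        tss_list = ", ".join(f"{m.algorithm}[{m.pa_set},{m.repeat}]={m.eval.tss:.3f}"
                             for m in members)
        raise ValueError(f"no ensemble member reaches TSS >= {tss_min}: {tss_list}")
    missing = [s for s in SLICE_LABELS if s not in predictors]
    if missing:
        raise ValueError(f"predictors missing for slices {missing}")
    rasters = []
    for s in SLICE_LABELS:
        pc = predictors[s]
        m = pc.mask
        rows, cols = np.nonzero(m)
        X = extract_predictors(pc, np.column_stack([rows, cols]))
        mean = np.zeros(len(X))
        for mem in passing:
            mean += mem.model.predict(X)
        mean = np.clip(mean / len(passing), 0.0, 1.0)
        out = np.full(pc.shape, pc.nodata)
        out[rows, cols] = mean
        rasters.append(Raster(out, pc.x_origin, pc.y_origin, pc.cell_size, pc.nodata))
    return SuitabilityStack(species=species, scenario=scenario, rasters=rasters)
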
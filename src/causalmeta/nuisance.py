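"""Nuisance-function estimation.

Four prediction functions feed the doubly robust estimators:

* the outcome model ``g_a(x)`` — conditional outcome mean under arm ``a``,
  fitted per arm on the pooled sources;
* the source model ``eta_s(x)`` — probability of each source given covariates;
* the treatment (propensity) model ``e_a(x, s)`` — probability of treatment
  given covariates and source;
* the external model ``q(x)`` — probability of belonging to the external
  population, fitted on the stacked multi-source + external rows (external
  analyses only).

Each model is fitted through :func:`super_learn`, a cross-validated stacking
("super learner") routine over a pluggable library of candidate learners:
either an optimally weighted simplex combination of the candidates
(``mode="stack"``) or the single CV-best candidate (``mode="select"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.dummy import DummyClassifier, DummyRegressor
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import (
    LassoCV,
    LinearRegression,
    LogisticRegression,
    LogisticRegressionCV,
    RidgeCV,
)
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier, MLPRegressor

from .data_model import AnalysisSpec, DesignEncoder, ExternalCovariates, MultiSourceDataset

__all__ = [
    "Learner",
    "register_learner",
    "get_learner",
    "super_learn",
    "SuperLearnerFit",
    "NuisanceFits",
    "fit_outcome_model",
    "fit_source_model",
    "fit_treatment_model",
    "fit_external_model",
    "fit_nuisances",
    "clip_probabilities",
]

_PROB_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# learner registry
# ---------------------------------------------------------------------------

@dataclass
class Learner:
    """A named candidate model for :func:`super_learn`.

    ``make_continuous`` / ``make_binary`` build unfitted sklearn-style
    estimators for the respective family; hyperparameter selection inside a
    learner (e.g. a CV-chosen penalty) is allowed and happens within the
    learner's own fit.
    """

    name: str
    make_continuous: Optional[Callable[[int], object]] = None
    make_binary: Optional[Callable[[int], object]] = None

    def build(self, family: str, seed: int):
        maker = self.make_continuous if family == "continuous" else self.make_binary
        if maker is None:
            raise ValueError(f"learner {self.name!r} does not support family {family!r}")
        return maker(seed)


_REGISTRY: dict[str, Learner] = {}


def register_learner(learner: Learner) -> None:
    """Register a learner under its name (overwrites silently)."""
    _REGISTRY[learner.name] = learner


def get_learner(name: str) -> Learner:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown learner {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None


register_learner(Learner(
    "mean",
    lambda seed: DummyRegressor(strategy="mean"),
    lambda seed: DummyClassifier(strategy="prior"),
))
register_learner(Learner(
    "glm",
    lambda seed: LinearRegression(),
    lambda seed: LogisticRegression(C=np.inf, max_iter=2000),
))
register_learner(Learner(
    "glmnet",
    lambda seed: LassoCV(cv=5, random_state=seed, n_alphas=30),
    lambda seed: LogisticRegressionCV(cv=5, Cs=10, max_iter=2000, random_state=seed,
                                      scoring="neg_log_loss"),
))
register_learner(Learner(
    "ridge",
    lambda seed: RidgeCV(alphas=np.logspace(-3, 3, 13)),
    lambda seed: LogisticRegressionCV(cv=5, Cs=10, max_iter=2000, random_state=seed,
                                      scoring="neg_log_loss"),
))
register_learner(Learner(
    "nnet",
    lambda seed: MLPRegressor(hidden_layer_sizes=(8,), max_iter=1000,
                              random_state=seed),
    lambda seed: MLPClassifier(hidden_layer_sizes=(8,), max_iter=1000,
                               random_state=seed),
))
register_learner(Learner(
    "rf",
    lambda seed: RandomForestRegressor(n_estimators=200, min_samples_leaf=5,
                                       random_state=seed),
    lambda seed: RandomForestClassifier(n_estimators=200, min_samples_leaf=5,
                                        random_state=seed),
))
register_learner(Learner(
    "gbm",
    lambda seed: GradientBoostingRegressor(random_state=seed),
    lambda seed: GradientBoostingClassifier(random_state=seed),
))


def _predict(est, Z: np.ndarray, family: str) -> np.ndarray:
    if family == "binary":
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(Z)
            classes = list(getattr(est, "classes_", [0, 1]))
            if 1 in classes:
                return proba[:, classes.index(1)]
            return np.zeros(len(Z))
        return np.clip(np.asarray(est.predict(Z), dtype=float), 0.0, 1.0)
    return np.asarray(est.predict(Z), dtype=float)


def clip_probabilities(p: np.ndarray, eps: float) -> tuple[np.ndarray, int]:
    """Clip probabilities into [eps, 1-eps]; returns (clipped, count clipped)."""
    if not (0.0 < eps < 0.5):
        raise ValueError("eps must lie in (0, 0.5)")
    p = np.asarray(p, dtype=float)
    n_clipped = int(np.sum((p < eps) | (p > 1.0 - eps)))
    return np.clip(p, eps, 1.0 - eps), n_clipped


# ---------------------------------------------------------------------------
# super learner
# ---------------------------------------------------------------------------

def _risk(pred: np.ndarray, y: np.ndarray, family: str) -> float:
    if family == "binary":
        p = np.clip(pred, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
        return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    return float(np.mean((y - pred) ** 2))


def _simplex_weights(P: np.ndarray, y: np.ndarray, family: str) -> np.ndarray:
    """Minimize CV risk of the combination P @ w over the probability simplex.

    Started at the vertex of the CV-best learner; if the optimizer fails to
    improve on that vertex the vertex is returned, so the stacked CV risk is
    never above the best single learner's.
    """
    k = P.shape[1]
    if k == 1:
        return np.ones(1)
    vertex_risks = [_risk(P[:, j], y, family) for j in range(k)]
    best = int(np.argmin(vertex_risks))
    x0 = np.zeros(k)
    x0[best] = 1.0

    def objective(w):
        return _risk(P @ w, y, family)

    res = minimize(
        objective, x0, method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: np.sum(w) - 1.0}],
        options={"maxiter": 500, "ftol": 1e-10},
    )
    w = np.clip(res.x, 0.0, None)
    w = w / w.sum() if w.sum() > 0 else x0
    if objective(w) > vertex_risks[best] + 1e-12:
        return x0
    return w


@dataclass
class SuperLearnerFit:
    """A fitted stacked (or selected) combination of learners."""

    family: str
    learner_names: list[str]
    weights: np.ndarray
    cv_risks: np.ndarray
    cv_risk_stack: float
    estimators: list
    mode: str

    def predict(self, Z: np.ndarray) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        out = np.zeros(len(Z))
        for w, est in zip(self.weights, self.estimators):
            if w > 0:
                out += w * _predict(est, Z, self.family)
        if self.family == "binary":
            out = np.clip(out, 0.0, 1.0)
        return out

    @property
    def weight_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "learner": self.learner_names,
            "weight": self.weights,
            "cv_risk": self.cv_risks,
        })


def super_learn(
    Z: np.ndarray,
    y: np.ndarray,
    family: str,
    library: Sequence,
    V: int = 10,
    mode: str = "stack",
    seed: int = 0,
) -> SuperLearnerFit:
    """Cross-validated stacking over a library of candidate learners.

    Parameters
    ----------
    Z, y
        Design matrix and labels.
    family
        "continuous" (squared-error CV loss) or "binary" (Bernoulli
        negative log-likelihood CV loss).
    library
        Learner names (registry keys) or :class:`Learner` objects.
    V
        Number of CV folds (stratified by class for binary labels).
    mode
        "stack" returns simplex weights minimizing CV risk; "select" puts
        weight 1 on the CV-best learner.

    A learner that fails to fit is dropped with a warning; only if every
    learner fails is an error raised.  With a single-learner library no CV
    is run: the weight is 1 by construction.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    learners = [l if isinstance(l, Learner) else get_learner(l) for l in library]
    if not learners:
        raise ValueError("empty learner library")
    if mode not in ("stack", "select"):
        raise ValueError(f"unknown mode {mode!r}")

    if len(learners) == 1:
        est = learners[0].build(family, seed)
        est.fit(Z, y)
        return SuperLearnerFit(
            family, [learners[0].name], np.ones(1), np.array([np.nan]),
            np.nan, [est], mode,
        )

    V = min(V, len(y))
    if family == "binary" and len(np.unique(y)) > 1:
        V = min(V, int(np.bincount(y.astype(int)).min())) or 2
        splitter = StratifiedKFold(n_splits=max(V, 2), shuffle=True, random_state=seed)
        splits = list(splitter.split(Z, y))
    else:
        splitter = KFold(n_splits=max(V, 2), shuffle=True, random_state=seed)
        splits = list(splitter.split(Z))

    cv_pred = np.full((len(y), len(learners)), np.nan)
    alive = []
    for j, learner in enumerate(learners):
        try:
            for tr, te in splits:
                est = learner.build(family, seed)
                est.fit(Z[tr], y[tr])
                cv_pred[te, j] = _predict(est, Z[te], family)
            alive.append(j)
        except Exception as exc:  # pragma: no cover - depends on learner
            warnings.warn(f"learner {learner.name!r} failed and was dropped: {exc}")
    if not alive:
        raise RuntimeError("all learners failed to fit")

    P = cv_pred[:, alive]
    risks = np.array([_risk(P[:, j], y, family) for j in range(len(alive))])
    if mode == "select":
        w = np.zeros(len(alive))
        w[int(np.argmin(risks))] = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = _simplex_weights(P, y, family)
    stack_risk = _risk(P @ w, y, family)

    full = []
    for j in alive:
        est = learners[j].build(family, seed)
        est.fit(Z, y)
        full.append(est)
    return SuperLearnerFit(
        family, [learners[j].name for j in alive], w, risks, stack_risk,
        full, mode,
    )


# ---------------------------------------------------------------------------
# the four nuisance models
# ---------------------------------------------------------------------------

@dataclass
class NuisanceFits:
    """Per-observation nuisance predictions used by the estimators.

    For internal analyses arrays run over the N multi-source rows.  For
    external analyses ``g0``/``g1`` additionally cover the n0 external rows
    (appended after the multi-source rows) and ``q`` covers all N + n0
    stacked rows.  Probabilities are clipped into ``[eps, 1-eps]``; row sums
    of ``eta`` equal 1 before clipping by construction of the fitted model.
    """

    g0: np.ndarray
    g1: np.ndarray
    eta: np.ndarray                 # N x m, columns ordered by source_levels
    source_levels: list[str]
    e1: np.ndarray                  # N
    q: Optional[np.ndarray] = None  # N + n0, Pr(external | x)
    eps: float = 0.01
    clip_counts: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)

    def eta_for(self, s: str) -> np.ndarray:
        return self.eta[:, self.source_levels.index(s)]

    def e_for(self, a: int) -> np.ndarray:
        return self.e1 if a == 1 else 1.0 - self.e1


def _source_estimator(spec: AnalysisSpec):
    if spec.source_model == "multinomial":
        return LogisticRegression(C=np.inf, max_iter=2000)
    if spec.source_model == "multinomial_penalized":
        return LogisticRegressionCV(cv=5, Cs=10, max_iter=2000,
                                    random_state=spec.seed, scoring="neg_log_loss")
    if spec.source_model == "nnet":
        return MLPClassifier(hidden_layer_sizes=(8,), max_iter=1000,
                             random_state=spec.seed)
    raise ValueError(f"unknown source model {spec.source_model!r}")


class OutcomeModel:
    """Per-arm conditional outcome mean; arms share features, pooled over sources."""

    def __init__(self, fits: dict[int, SuperLearnerFit]):
        self.fits = fits

    def predict(self, a: int, Z: np.ndarray) -> np.ndarray:
        return self.fits[a].predict(Z)


def fit_outcome_model(
    data: MultiSourceDataset,
    spec: AnalysisSpec,
    Z: np.ndarray,
    rows: Optional[np.ndarray] = None,
) -> OutcomeModel:
    """Fit g_0 and g_1 by stacking on the rows of each arm within ``rows``."""
    rows = np.arange(data.n) if rows is None else np.asarray(rows)
    A = data.A.to_numpy()[rows].astype(int)
    fits = {}
    for a in (0, 1):
        sel = rows[A == a]
        if len(sel) == 0:
            raise ValueError(f"arm {a} unobserved in training split")
        fits[a] = super_learn(
            Z[sel], data.Y.to_numpy()[sel], spec.outcome_family,
            spec.outcome_library, V=spec.cv_folds, mode=spec.sl_mode,
            seed=spec.seed,
        )
    return OutcomeModel(fits)


class SourceModel:
    def __init__(self, est, levels: list[str]):
        self.est = est
        self.levels = levels

    def predict(self, Z: np.ndarray) -> np.ndarray:
        if self.est is None:  # single source: eta == 1 by convention
            return np.ones((len(Z), 1))
        proba = self.est.predict_proba(Z)
        classes = list(self.est.classes_)
        cols = [classes.index(lv) for lv in self.levels]
        return proba[:, cols]


def fit_source_model(
    data: MultiSourceDataset,
    spec: AnalysisSpec,
    Z: np.ndarray,
    rows: Optional[np.ndarray] = None,
) -> SourceModel:
    """Multinomial model for Pr(S = s | x); eta == 1 when there is one source."""
    levels = data.source_levels
    if len(levels) == 1:
        return SourceModel(None, levels)
    rows = np.arange(data.n) if rows is None else np.asarray(rows)
    S = data.S.to_numpy()[rows]
    missing = sorted(set(levels) - set(S))
    if missing:
        raise ValueError(f"source(s) {missing} absent from training split")
    est = _source_estimator(spec)
    est.fit(Z[rows], S)
    return SourceModel(est, levels)


class TreatmentModel:
    def __init__(self, kind: str, joint_fit=None, per_source=None,
                 source_levels=None):
        self.kind = kind
        self.joint_fit = joint_fit
        self.per_source = per_source or {}
        self.source_levels = source_levels or []

    def predict(self, Z: np.ndarray, S: np.ndarray) -> np.ndarray:
        if self.kind == "joint":
            ZS = _append_source_dummies(Z, S, self.source_levels)
            return self.joint_fit.predict(ZS)
        out = np.empty(len(Z))
        for s, fit in self.per_source.items():
            mask = S == s
            if mask.any():
                out[mask] = fit.predict(Z[mask])
        return out


def _append_source_dummies(Z: np.ndarray, S: np.ndarray, levels: list[str]) -> np.ndarray:
    dummies = np.column_stack([(S == lv).astype(float) for lv in levels[1:]]) \
        if len(levels) > 1 else np.empty((len(Z), 0))
    return np.hstack([Z, dummies])


def fit_treatment_model(
    data: MultiSourceDataset,
    spec: AnalysisSpec,
    Z: np.ndarray,
    rows: Optional[np.ndarray] = None,
) -> TreatmentModel:
    """Propensity Pr(A = 1 | x, s): one joint fit with source indicators, or
    one fit per source with predictions routed by each row's own source."""
    rows = np.arange(data.n) if rows is None else np.asarray(rows)
    A = data.A.to_numpy().astype(float)
    S = data.S.to_numpy()
    levels = data.source_levels
    if spec.treatment_model_type == "joint":
        if len(np.unique(A[rows])) < 2:
            raise ValueError("both treatment arms must be present in the training split")
        ZS = _append_source_dummies(Z, S, levels)
        fit = super_learn(
            ZS[rows], A[rows], "binary", spec.treatment_library,
            V=spec.cv_folds, mode=spec.sl_mode, seed=spec.seed,
        )
        return TreatmentModel("joint", joint_fit=fit, source_levels=levels)
    per_source = {}
    for s in levels:
        sel = rows[S[rows] == s]
        if len(sel) == 0 or len(np.unique(A[sel])) < 2:
            raise ValueError(
                f"source {s!r} lacks both treatment arms in the training "
                "split; a separate treatment model cannot be fit"
            )
        per_source[s] = super_learn(
            Z[sel], A[sel], "binary", spec.treatment_library,
            V=spec.cv_folds, mode=spec.sl_mode, seed=spec.seed,
        )
    return TreatmentModel("separate", per_source=per_source, source_levels=levels)


def fit_external_model(
    Z_stacked: np.ndarray,
    is_external: np.ndarray,
    spec: AnalysisSpec,
    rows: Optional[np.ndarray] = None,
) -> SuperLearnerFit:
    """Fit q(x) = Pr(external | x) on the stacked multi-source + external rows."""
    rows = np.arange(len(Z_stacked)) if rows is None else np.asarray(rows)
    r = np.asarray(is_external, dtype=float)
    if len(np.unique(r[rows])) < 2:
        raise ValueError(
            "external model needs both multi-source and external rows in the "
            "training split"
        )
    return super_learn(
        Z_stacked[rows], r[rows], "binary", spec.external_library,
        V=spec.cv_folds, mode=spec.sl_mode, seed=spec.seed,
    )


def fit_nuisances(
    data: MultiSourceDataset,
    external: Optional[ExternalCovariates],
    spec: AnalysisSpec,
    rows_by_role: Optional[dict[str, np.ndarray]] = None,
) -> NuisanceFits:
    """Fit all required nuisances and evaluate them on every row.

    ``rows_by_role`` optionally restricts the rows each nuisance is *fitted*
    on (keys "outcome", "source", "treatment", "external"); predictions are
    always produced for all rows, which is what cross-fitting needs.  For
    external analyses the "external" role indexes the stacked N + n0 rows,
    and indices for the other roles refer to multi-source rows.
    """
    rows_by_role = rows_by_role or {}
    use_em = data.EM is not None
    enc = DesignEncoder(standardize=spec.standardize)
    enc.fit(data.X, data.EM if use_em else None)
    Z = enc.transform(data.X, data.EM if use_em else None)

    is_ext = spec.target == "external"
    if is_ext and external is None:
        raise ValueError("external analysis requires external covariates")

    outcome = fit_outcome_model(data, spec, Z, rows_by_role.get("outcome"))
    source = fit_source_model(data, spec, Z, rows_by_role.get("source"))
    treatment = fit_treatment_model(data, spec, Z, rows_by_role.get("treatment"))

    clip_counts: dict[str, int] = {}
    if is_ext:
        Z_ext = enc.transform(external.X, external.EM if use_em else None)
        Z_stacked = np.vstack([Z, Z_ext])
        r = np.concatenate([np.zeros(data.n), np.ones(external.n)])
        ext_fit = fit_external_model(Z_stacked, r, spec,
                                     rows_by_role.get("external"))
        q, clip_counts["q"] = clip_probabilities(
            ext_fit.predict(Z_stacked), spec.eps)
        g0 = outcome.predict(0, Z_stacked)
        g1 = outcome.predict(1, Z_stacked)
    else:
        ext_fit, q = None, None
        g0 = outcome.predict(0, Z)
        g1 = outcome.predict(1, Z)

    eta = source.predict(Z)
    eta_clipped, clip_counts["eta"] = clip_probabilities(eta, spec.eps)
    e1, clip_counts["e"] = clip_probabilities(
        treatment.predict(Z, data.S.to_numpy()), spec.eps)

    return NuisanceFits(
        g0=g0, g1=g1, eta=eta_clipped, source_levels=data.source_levels,
        e1=e1, q=q, eps=spec.eps, clip_counts=clip_counts,
        models={
            "outcome": outcome, "source": source, "treatment": treatment,
            "external": ext_fit, "encoder": enc,
        },
    )
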
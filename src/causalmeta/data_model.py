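"""Input containers, validation, and design-matrix encoding.

The estimators operate on individual-participant data pooled from ``m``
sources: an outcome ``Y`` (continuous or binary), a source label ``S``, a
binary treatment ``A`` coded 0/1, a covariate table ``X``, and optionally a
categorical effect modifier ``EM`` whose levels define the subgroups of a
subgroup-treatment-effect (STE) analysis.  External-target analyses
additionally require a covariate table for the target population, which has
no outcome or treatment information.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MultiSourceDataset",
    "ExternalCovariates",
    "AnalysisSpec",
    "ValidationReport",
    "ValidationError",
    "DesignEncoder",
    "validate_inputs",
    "encode_design",
]


class ValidationError(ValueError):
    """Raised when input data violate a fatal requirement."""


def _as_series(v, name: str) -> pd.Series:
    s = pd.Series(np.asarray(v)) if not isinstance(v, pd.Series) else v.reset_index(drop=True)
    s.name = name
    return s


@dataclass
class MultiSourceDataset:
    """The (Y, S, A, X, EM) table for the multi-source analysis data.

    Parameters
    ----------
    Y : array-like, length N
        Outcome, continuous or binary.
    S : array-like, length N
        Source label, categorical with m levels.
    A : array-like, length N
        Treatment, coded 0/1.
    X : DataFrame, N rows
        Baseline covariates (continuous, binary and/or categorical columns).
        Must not contain the effect modifier.
    EM : array-like, length N, optional
        Categorical effect modifier with K levels (required for STE analyses).
    """

    Y: pd.Series
    S: pd.Series
    A: pd.Series
    X: pd.DataFrame
    EM: Optional[pd.Series] = None

    def __post_init__(self):
        self.Y = _as_series(self.Y, "Y").astype(float)
        self.S = _as_series(self.S, "S").astype(str)
        self.A = _as_series(self.A, "A")
        if not isinstance(self.X, pd.DataFrame):
            self.X = pd.DataFrame(self.X)
        self.X = self.X.reset_index(drop=True)
        if self.EM is not None:
            self.EM = _as_series(self.EM, "EM").astype(str)

    @property
    def n(self) -> int:
        return len(self.Y)

    @property
    def source_levels(self) -> list[str]:
        return sorted(self.S.unique())

    @property
    def m(self) -> int:
        return len(self.source_levels)

    @property
    def em_levels(self) -> list[str]:
        if self.EM is None:
            return []
        return sorted(self.EM.unique())

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        Y: str = "Y",
        S: str = "S",
        A: str = "A",
        EM: Optional[str] = None,
        X: Optional[Sequence[str]] = None,
    ) -> "MultiSourceDataset":
        """Build a dataset from a single table by naming the column roles.

        When ``X`` is omitted, every column not used for another role becomes
        a covariate.
        """
        if X is None:
            used = {Y, S, A} | ({EM} if EM else set())
            X = [c for c in df.columns if c not in used]
        return cls(
            Y=df[Y], S=df[S], A=df[A], X=df[list(X)].copy(),
            EM=df[EM] if EM else None,
        )

    @classmethod
    def from_csv(cls, path, sep=",", **roles) -> "MultiSourceDataset":
        return cls.from_frame(pd.read_csv(path, sep=sep), **roles)


@dataclass
class ExternalCovariates:
    """Covariate (and effect-modifier) table for an external target population."""

    X: pd.DataFrame
    EM: Optional[pd.Series] = None

    def __post_init__(self):
        if not isinstance(self.X, pd.DataFrame):
            self.X = pd.DataFrame(self.X)
        self.X = self.X.reset_index(drop=True)
        if self.EM is not None:
            self.EM = _as_series(self.EM, "EM").astype(str)

    @property
    def n(self) -> int:
        return len(self.X)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, EM: Optional[str] = None,
                   X: Optional[Sequence[str]] = None) -> "ExternalCovariates":
        if X is None:
            X = [c for c in df.columns if c != EM]
        return cls(X=df[list(X)].copy(), EM=df[EM] if EM else None)

    @classmethod
    def from_csv(cls, path, sep=",", **roles) -> "ExternalCovariates":
        return cls.from_frame(pd.read_csv(path, sep=sep), **roles)


@dataclass
class AnalysisSpec:
    """Configuration of one analysis (target population, estimand, models).

    ``target`` selects an internal target population (one of the sources) or
    the external population; ``estimand`` selects overall (ATE) or subgroup
    (STE) effects.  Learner libraries name entries of the learner registry in
    :mod:`causalmeta.nuisance`; ``sl_mode`` chooses cross-validated stacking
    ("stack") or discrete selection of the CV-best learner ("select").
    """

    target: str = "internal"            # internal | external
    estimand: str = "ATE"               # ATE | STE
    outcome_family: str = "continuous"  # continuous | binary
    treatment_model_type: str = "joint"  # joint | separate
    outcome_library: tuple = ("glm",)
    treatment_library: tuple = ("glm",)
    external_library: tuple = ("glm",)
    source_model: str = "multinomial"   # multinomial | multinomial_penalized | nnet
    sl_mode: str = "stack"              # stack | select
    cv_folds: int = 10
    eps: float = 0.01                   # probability clip
    level: float = 0.95
    scb_draws: int = 10_000
    seed: int = 0
    standardize: bool = False
    augmentation: str = "pooled"        # pooled | target_only (diagnostic)

    def __post_init__(self):
        if self.target not in ("internal", "external"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.estimand not in ("ATE", "STE"):
            raise ValueError(f"unknown estimand {self.estimand!r}")
        if self.outcome_family not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome_family {self.outcome_family!r}")
        if self.treatment_model_type not in ("joint", "separate"):
            raise ValueError(f"unknown treatment_model_type {self.treatment_model_type!r}")
        if not (0.0 < self.eps < 0.5):
            raise ValueError("eps must lie in (0, 0.5)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must lie in (0, 1)")

    def replace(self, **kw) -> "AnalysisSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class ValidationReport:
    """Collected fatal errors and non-fatal warnings from input validation."""

    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_fatal(self) -> None:
        if self.errors:
            raise ValidationError(
                "input validation failed:\n- " + "\n- ".join(self.errors)
            )


def _has_missing(obj) -> bool:
    if isinstance(obj, pd.DataFrame):
        return bool(obj.isna().any().any())
    return bool(pd.isna(np.asarray(obj, dtype=object)).any())


def validate_inputs(
    data: MultiSourceDataset,
    external: Optional[ExternalCovariates] = None,
    spec: Optional[AnalysisSpec] = None,
) -> ValidationReport:
    """Check every structural requirement, collecting *all* violations.

    Fatal errors: mismatched lengths, missing values, non-0/1 treatment,
    effect modifier duplicated inside X, external target without external
    covariates, STE without an effect modifier, column/level mismatches
    between X and the external table.  Non-fatal warnings flag sparse
    (source x arm [x subgroup]) cells with fewer than 10 observations, a
    practical positivity concern the software can only flag.
    """
    spec = spec or AnalysisSpec()
    rep = ValidationReport()
    n = data.n

    for name, obj in (("Y", data.Y), ("S", data.S), ("A", data.A), ("X", data.X)):
        if len(obj) != n:
            rep.errors.append(f"{name} has {len(obj)} rows, expected {n}")
    if data.EM is not None and len(data.EM) != n:
        rep.errors.append(f"EM has {len(data.EM)} rows, expected {n}")

    for name, obj in (("Y", data.Y), ("S", data.S), ("A", data.A),
                      ("X", data.X)) + ((("EM", data.EM),) if data.EM is not None else ()):
        if _has_missing(obj):
            rep.errors.append(f"{name} contains missing values")

    a_vals = set(pd.unique(pd.Series(data.A).dropna()))
    if not a_vals <= {0, 1, 0.0, 1.0}:
        bad = sorted(v for v in a_vals if v not in (0, 1))
        rep.errors.append(f"treatment not 0/1: found values {bad}")

    if data.EM is not None:
        em_str = data.EM.astype(str)
        for col in data.X.columns:
            if data.X[col].astype(str).equals(em_str):
                rep.errors.append(
                    f"effect modifier duplicated inside X (column {col!r}); "
                    "X must not include the effect modifier"
                )

    # sparse-cell positivity warnings
    if not rep.errors:
        counts = pd.crosstab(data.S, data.A)
        for s in counts.index:
            for a in (0, 1):
                c = int(counts.loc[s, a]) if a in counts.columns else 0
                if c < 10:
                    rep.warnings.append(
                        f"source {s!r}, arm {a}: only {c} observations"
                    )
        if data.EM is not None and spec.estimand == "STE":
            counts3 = data.Y.groupby(
                [data.S, data.A, data.EM], observed=True
            ).size()
            full = pd.MultiIndex.from_product(
                [data.source_levels, [0, 1], data.em_levels]
            )
            counts3 = counts3.reindex(full, fill_value=0)
            for (s, a, em), c in counts3.items():
                if c < 10:
                    rep.warnings.append(
                        f"source {s!r}, arm {a}, subgroup {em!r}: only {c} observations"
                    )

    if spec.estimand == "STE" and data.EM is None:
        rep.errors.append("estimand STE requires an effect modifier EM")

    if spec.target == "external":
        if external is None:
            rep.errors.append(
                "target is the external population but no external covariate "
                "data were provided"
            )
        else:
            if list(external.X.columns) != list(data.X.columns):
                rep.errors.append(
                    "external covariate columns must match X in name and "
                    f"order (got {list(external.X.columns)}, expected "
                    f"{list(data.X.columns)})"
                )
            if _has_missing(external.X):
                rep.errors.append("X_external contains missing values")
            if spec.estimand == "STE":
                if external.EM is None:
                    rep.errors.append(
                        "external STE analysis requires EM for the external rows"
                    )
                elif data.EM is not None:
                    extra = set(external.EM.unique()) - set(data.EM.unique())
                    if extra:
                        rep.errors.append(
                            "external EM levels not present in the "
                            f"multi-source data: {sorted(extra)}"
                        )
    return rep


class DesignEncoder:
    """Deterministic numeric encoding of a covariate table.

    Categorical columns (object/category/bool dtype) are expanded to
    reference-level-dropped indicator columns with levels sorted
    lexicographically; numeric columns pass through (optionally standardized
    by the mean/SD learned at fit time).  The effect modifier, when supplied,
    is appended as indicator columns the same way.  The fitted encoder maps
    the external covariate table with the levels learned from X; an unseen
    level is a fatal error (never silently zeroed).
    """

    def __init__(self, standardize: bool = False):
        self.standardize = standardize
        self.fitted_ = False

    @staticmethod
    def _is_categorical(col: pd.Series) -> bool:
        return (
            col.dtype == object
            or isinstance(col.dtype, pd.CategoricalDtype)
            or col.dtype == bool
        )

    def fit(self, X: pd.DataFrame, EM: Optional[pd.Series] = None) -> "DesignEncoder":
        self.columns_in_ = list(X.columns)
        self.cat_levels_: dict[str, list] = {}
        self.num_cols_: list[str] = []
        for c in X.columns:
            if self._is_categorical(X[c]):
                self.cat_levels_[c] = sorted(X[c].astype(str).unique())
            else:
                self.num_cols_.append(c)
        self.em_levels_ = sorted(EM.astype(str).unique()) if EM is not None else None
        if self.standardize:
            self.means_ = {c: float(X[c].mean()) for c in self.num_cols_}
            self.sds_ = {
                c: (float(X[c].std(ddof=0)) or 1.0) for c in self.num_cols_
            }
        cols: list[str] = []
        for c in self.columns_in_:
            if c in self.cat_levels_:
                cols.extend(f"{c}={lv}" for lv in self.cat_levels_[c][1:])
            else:
                cols.append(str(c))
        if self.em_levels_ is not None:
            cols.extend(f"EM={lv}" for lv in self.em_levels_[1:])
        self.columns_ = cols
        self.fitted_ = True
        return self

    def transform(self, X: pd.DataFrame, EM: Optional[pd.Series] = None) -> np.ndarray:
        if not self.fitted_:
            raise RuntimeError("encoder not fitted")
        n = len(X)
        out = np.empty((n, len(self.columns_)), dtype=float)
        j = 0
        for c in self.columns_in_:
            if c in self.cat_levels_:
                vals = X[c].astype(str).to_numpy()
                levels = self.cat_levels_[c]
                unseen = sorted(set(vals) - set(levels))
                if unseen:
                    raise ValidationError(
                        f"column {c!r}: unseen categorical level(s) "
                        f"{unseen} not present when the encoder was fitted"
                    )
                for lv in levels[1:]:
                    out[:, j] = vals == lv
                    j += 1
            else:
                v = X[c].to_numpy(dtype=float)
                if self.standardize:
                    v = (v - self.means_[c]) / self.sds_[c]
                out[:, j] = v
                j += 1
        if self.em_levels_ is not None:
            if EM is None:
                raise ValidationError("encoder fitted with EM but none supplied")
            vals = EM.astype(str).to_numpy()
            unseen = sorted(set(vals) - set(self.em_levels_))
            if unseen:
                raise ValidationError(
                    f"effect modifier: unseen level(s) {unseen}"
                )
            for lv in self.em_levels_[1:]:
                out[:, j] = vals == lv
                j += 1
        return out

    def fit_transform(self, X, EM=None) -> np.ndarray:
        return self.fit(X, EM).transform(X, EM)


def encode_design(
    X: pd.DataFrame,
    EM: Optional[pd.Series] = None,
    standardize: bool = False,
) -> tuple[np.ndarray, DesignEncoder]:
    """One-shot fit+transform; returns the matrix and the fitted encoder."""
    enc = DesignEncoder(standardize=standardize)
    return enc.fit_transform(X, EM), enc
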
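"""Stratified sample splitting and cross-fitting.

Flexible (data-adaptive) nuisance learners can overfit, biasing the
estimating equation; cross-fitting removes this by never letting a row's own
influence contribution depend on nuisances fit to that row.  The data are
split into J folds stratified by source (and subgroup for STE analyses;
external rows form their own stratum), J = 4 for internal analyses and 5 for
external ones, so within each cycle one fold is the estimation fold and each
remaining fold fits exactly one nuisance.  Rotating the estimation fold
through all J positions uses every row once for estimation; repeating the
whole procedure over many independent splits ("replications", default 100)
and averaging removes sensitivity to any single split.  The aggregated
variance adds the between-replication spread of the point estimates to the
mean within-replication influence-function variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional
import warnings

import numpy as np

from .data_model import AnalysisSpec, ExternalCovariates, MultiSourceDataset
from .estimators import EffectEstimate, effect
from .inference import sup_t_critical, _corr_from_cov, wald_interval
from .nuisance import NuisanceFits, fit_nuisances

__all__ = ["CrossfitConfig", "stratified_split", "crossfit_estimate"]


@dataclass
class CrossfitConfig:
    """Cross-fitting switches: on/off, replication count, folds, master seed.

    ``folds=None`` selects the analysis-appropriate default: 4 folds for
    internal targets (estimation + outcome + source + treatment), 5 for
    external ones (plus the external-membership model).
    """

    enabled: bool = True
    replications: int = 100
    folds: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if self.folds is not None and self.folds < 2:
            raise ValueError("folds must be >= 2")


def stratified_split(strata: np.ndarray, J: int, seed) -> np.ndarray:
    """Random fold assignment, balanced within every stratum.

    Members of each stratum are permuted and dealt round-robin into J folds,
    so per-stratum fold sizes differ by at most one.  A stratum with fewer
    than J members gets a best-effort assignment and a warning (cross-fitting
    is not recommended for very small sources).
    """
    strata = np.asarray(strata)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(strata), dtype=int)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        if len(idx) < J:
            warnings.warn(
                f"stratum {s!r} has {len(idx)} rows, fewer than {J} folds; "
                "cross-fitting is not recommended for such small strata"
            )
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(perm)) % J
    return folds


def _role_names(is_external: bool) -> list[str]:
    return ["outcome", "source", "treatment"] + (
        ["external"] if is_external else []
    )


def _assemble_replication(
    data: MultiSourceDataset,
    external: Optional[ExternalCovariates],
    spec: AnalysisSpec,
    J: int,
    rep_seed,
) -> NuisanceFits:
    """One replication: split, rotate fold roles, and assemble per-row
    nuisance predictions such that every row's predictions come from models
    fitted without any row of its own (estimation) fold."""
    is_ext = spec.target == "external"
    roles = _role_names(is_ext)

    strata = data.S.to_numpy().astype(object).copy()
    if spec.estimand == "STE" and data.EM is not None:
        strata = np.array([f"{s}||{e}" for s, e in
                           zip(strata, data.EM.to_numpy())], dtype=object)
    if is_ext:
        strata = np.concatenate([
            strata, np.full(external.n, "__external__", dtype=object)])
    fold_of = stratified_split(strata, J, rep_seed)

    N = data.n
    n_total = N + (external.n if is_ext else 0)
    m = data.m
    g0 = np.empty(n_total)
    g1 = np.empty(n_total)
    eta = np.empty((N, m))
    e1 = np.empty(N)
    q = np.empty(n_total) if is_ext else None
    eps = spec.eps

    ms_fold = fold_of[:N]  # folds of multi-source rows
    for c in range(J):
        # estimation fold c; remaining folds assigned one-per-nuisance,
        # rotating so each fold plays each role once per replication
        role_fold = {
            role: (c + 1 + k) % J for k, role in enumerate(roles)
        }
        rows_by_role = {
            role: np.flatnonzero(ms_fold == f)
            for role, f in role_fold.items() if role != "external"
        }
        if is_ext:
            rows_by_role["external"] = np.flatnonzero(
                fold_of == role_fold["external"])
        fits_c = fit_nuisances(data, external, spec, rows_by_role)

        eval_all = np.flatnonzero(fold_of == c)
        eval_ms = eval_all[eval_all < N]
        g0[eval_all] = fits_c.g0[eval_all]
        g1[eval_all] = fits_c.g1[eval_all]
        eta[eval_ms] = fits_c.eta[eval_ms]
        e1[eval_ms] = fits_c.e1[eval_ms]
        if is_ext:
            q[eval_all] = fits_c.q[eval_all]

    return NuisanceFits(
        g0=g0, g1=g1, eta=eta, source_levels=data.source_levels,
        e1=e1, q=q, eps=eps,
    )


def crossfit_estimate(
    data: MultiSourceDataset,
    external: Optional[ExternalCovariates],
    spec: AnalysisSpec,
    config: CrossfitConfig,
) -> list[EffectEstimate]:
    """Cross-fitted effect estimates, aggregated over replications.

    With ``config.enabled=False`` this is a single full-data fit.  Otherwise,
    per replication r the cross-fitted influence contributions give an
    estimate ``est_r`` and IF variance ``var_r``; the aggregate point
    estimate is ``mean_r(est_r)`` and the aggregate variance is
    ``mean_r(var_r + (est_r - mean)^2)``.  The master seed deterministically
    spawns per-replication seeds, so any replication is individually
    reproducible.  Simultaneous bands for STE analyses are rebuilt from the
    aggregated covariance.
    """
    if not config.enabled:
        fits = fit_nuisances(data, external, spec)
        return effect(data, external, fits, spec)

    J = config.folds or (5 if spec.target == "external" else 4)
    R = config.replications
    rep_seeds = np.random.SeedSequence(config.seed).spawn(R)

    per_rep: list[list[EffectEstimate]] = []
    for r in range(R):
        fits_r = _assemble_replication(data, external, spec, J, rep_seeds[r])
        per_rep.append(effect(data, external, fits_r, spec, add_bands=False))

    K = len(per_rep[0])
    n_if = len(per_rep[0][0].if_diff)
    out: list[EffectEstimate] = []
    diffs = np.array([[cells[k].diff for k in range(K)] for cells in per_rep])
    mean_diff = diffs.mean(axis=0)
    # aggregated covariance of the K estimates (for SCBs): mean within-rep
    # IF covariance plus between-replication covariance of the estimates
    covs = np.zeros((K, K))
    for r in range(R):
        phi = np.column_stack([per_rep[r][k].if_diff for k in range(K)])
        covs += (phi.T @ phi) / (n_if * n_if)
        d = diffs[r] - mean_diff
        covs += np.outer(d, d)
    covs /= R

    for k in range(K):
        c0 = per_rep[0][k]
        mu0 = float(np.mean([cells[k].mu0 for cells in per_rep]))
        mu1 = float(np.mean([cells[k].mu1 for cells in per_rep]))
        d = diffs[:, k]

        def _agg_var(attr_se, attr_est, center):
            vals = np.array([getattr(cells[k], attr_se) ** 2
                             + (getattr(cells[k], attr_est) - center) ** 2
                             for cells in per_rep])
            return float(vals.mean())

        se = float(np.sqrt(covs[k, k]))
        out.append(EffectEstimate(
            target_id=c0.target_id, subgroup=c0.subgroup,
            mu0=mu0, mu1=mu1, diff=float(mean_diff[k]),
            if0=np.zeros(0), if1=np.zeros(0), if_diff=np.zeros(0),
            n_target=c0.n_target,
            se=se,
            se0=float(np.sqrt(_agg_var("se0", "mu0", mu0))),
            se1=float(np.sqrt(_agg_var("se1", "mu1", mu1))),
        ))

    for c in out:
        c.ci_low, c.ci_high = wald_interval(c.diff, c.se, spec.level)

    if spec.estimand == "STE":
        # sup-t band per target population from the aggregated covariance
        targets = sorted({c.target_id for c in out})
        for t in targets:
            idx = [k for k in range(K) if out[k].target_id == t]
            corr, _ = _corr_from_cov(covs[np.ix_(idx, idx)])
            crit = sup_t_critical(corr, spec.level, spec.scb_draws, spec.seed)
            for k in idx:
                out[k].scb_low = out[k].diff - crit * out[k].se
                out[k].scb_high = out[k].diff + crit * out[k].se
    return out
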
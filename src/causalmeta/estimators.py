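"""Doubly robust (augmented IPW) estimators of potential-outcome means and
treatment effects in internal and external target populations.

For an internal target population (the population underlying source ``s``)
the potential-outcome mean under arm ``a`` is estimated by the Hájek-
normalized augmented estimator

    mu_hat = [ sum_i T_i g_a(x_i) + sum_i W_i (y_i - g_a(x_i)) ] / sum_i T_i,

with target indicator ``T_i = I(S_i = s)`` (times ``I(EM_i = em)`` for a
subgroup) and augmentation weight
``W_i = I(A_i = a) * eta_s(x_i) / e_a(x_i, S_i)``: the residual term pools
observations from *all* sources, re-weighted to the target's covariate
distribution, which is the efficiency-bearing choice licensed by
exchangeability of the potential-outcome distribution over sources.

For an external target population the index runs over the stacked
multi-source + external rows; ``T_i`` marks external rows and
``W_i = I(multi-source, A_i = a) * [q(x_i)/(1-q(x_i))] / e_a(x_i, S_i)``
uses the external-membership odds in place of the source probability.

Both forms solve an estimating equation that sets the empirical mean of the
influence function to zero *exactly*, because the normalizer is the realized
target count; the IF second moment then yields the standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import AnalysisSpec, ExternalCovariates, MultiSourceDataset
from .inference import if_se, simultaneous_band, wald_interval
from .nuisance import NuisanceFits

__all__ = ["EffectEstimate", "po_mean_internal", "po_mean_external", "effect",
           "estimates_to_frames"]


@dataclass
class EffectEstimate:
    """One target-population x subgroup row of an analysis.

    ``if0``/``if1``/``if_diff`` are mean-zero per-observation influence
    vectors over the full index set (N rows internal, N + n0 external);
    ``n_target`` is the realized count of target rows, the estimate of the
    normalizing fraction kappa times the total row count.
    """

    target_id: str
    subgroup: str
    mu0: float
    mu1: float
    diff: float
    if0: np.ndarray
    if1: np.ndarray
    if_diff: np.ndarray
    n_target: int
    se: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    scb_low: float = np.nan
    scb_high: float = np.nan
    se0: float = np.nan
    se1: float = np.nan


def _po_mean(
    T: np.ndarray,
    W: np.ndarray,
    g: np.ndarray,
    resid_times_W: np.ndarray,
) -> tuple[float, np.ndarray]:
    n_target = T.sum()
    if n_target == 0:
        raise ValueError("empty target cell")
    total = float(np.sum(T * g) + np.sum(resid_times_W))
    mu = total / n_target
    n = len(T)
    phi = (n / n_target) * (T * (g - mu) + resid_times_W)
    return mu, phi


def po_mean_internal(
    data: MultiSourceDataset,
    fits: NuisanceFits,
    s: str,
    a: int,
    em: Optional[str] = None,
    augmentation: str = "pooled",
) -> tuple[float, np.ndarray]:
    """Potential-outcome mean under arm ``a`` in the population of source
    ``s`` (optionally within effect-modifier level ``em``).

    ``augmentation="pooled"`` (the default, efficiency-bearing form) lets
    the residual term draw on every source re-weighted by eta_s / e_a;
    ``"target_only"`` restricts it to the target source's own rows, a
    diagnostic variant.  Returns the estimate and its length-N mean-zero
    influence vector.
    """
    S = data.S.to_numpy()
    A = data.A.to_numpy().astype(int)
    Y = data.Y.to_numpy()
    T = (S == s).astype(float)
    if T.sum() == 0:
        raise ValueError(f"empty target cell: no rows with source {s!r}")
    g = fits.g1 if a == 1 else fits.g0
    g = g[: data.n]
    W = (A == a) * fits.eta_for(s) / fits.e_for(a)
    if augmentation == "target_only":
        W = W * (S == s)
    elif augmentation != "pooled":
        raise ValueError(f"unknown augmentation {augmentation!r}")
    if em is not None:
        in_em = (data.EM.to_numpy() == em).astype(float)
        T = T * in_em
        W = W * in_em
    return _po_mean(T, W, g, W * (Y - g))


def po_mean_external(
    data: MultiSourceDataset,
    external: ExternalCovariates,
    fits: NuisanceFits,
    a: int,
    em: Optional[str] = None,
) -> tuple[float, np.ndarray]:
    """Potential-outcome mean under arm ``a`` in the external target
    population (optionally within effect-modifier level ``em``).

    The influence vector has length N + n0, over the stacked rows
    (multi-source first, external after).
    """
    if fits.q is None:
        raise ValueError("external analysis requires a fitted external model")
    N, n0 = data.n, external.n
    A = data.A.to_numpy().astype(int)
    Y = np.concatenate([data.Y.to_numpy(), np.zeros(n0)])
    T = np.concatenate([np.zeros(N), np.ones(n0)])
    g = fits.g1 if a == 1 else fits.g0
    odds = fits.q[:N] / (1.0 - fits.q[:N])
    W = np.concatenate([(A == a) * odds / fits.e_for(a), np.zeros(n0)])
    if em is not None:
        if external.EM is None:
            raise ValueError("external subgroup analysis requires external EM")
        in_em = np.concatenate([
            (data.EM.to_numpy() == em).astype(float),
            (external.EM.to_numpy() == em).astype(float),
        ])
        T = T * in_em
        W = W * in_em
    return _po_mean(T, W, g, W * (Y - g))


def _one_cell(data, external, fits, spec, target_id, subgroup, em):
    if target_id == "external":
        mu0, if0 = po_mean_external(data, external, fits, 0, em)
        mu1, if1 = po_mean_external(data, external, fits, 1, em)
        n_t = int(np.sum(
            np.ones(external.n) if em is None
            else (external.EM.to_numpy() == em)
        ))
    else:
        aug = spec.augmentation
        mu0, if0 = po_mean_internal(data, fits, target_id, 0, em, augmentation=aug)
        mu1, if1 = po_mean_internal(data, fits, target_id, 1, em, augmentation=aug)
        mask = data.S.to_numpy() == target_id
        if em is not None:
            mask = mask & (data.EM.to_numpy() == em)
        n_t = int(mask.sum())
    if_diff = if1 - if0
    return EffectEstimate(
        target_id=target_id, subgroup=subgroup,
        mu0=mu0, mu1=mu1, diff=mu1 - mu0,
        if0=if0, if1=if1, if_diff=if_diff, n_target=n_t,
        se=if_se(if_diff), se0=if_se(if0), se1=if_se(if1),
    )


def effect(
    data: MultiSourceDataset,
    external: Optional[ExternalCovariates],
    fits: NuisanceFits,
    spec: AnalysisSpec,
    add_bands: bool = True,
) -> list[EffectEstimate]:
    """All effect estimates for the analysis described by ``spec``.

    ATE-internal: one estimate per source.  ATE-external: one estimate.
    STE-internal: one per (source, subgroup) pair.  STE-external: one per
    subgroup present in the external effect modifier.  Wald CIs are attached
    to every row; for STE analyses a sup-t simultaneous band over each target
    population's subgroups is attached as well.
    """
    is_ste = spec.estimand == "STE"
    if spec.target == "external":
        targets = ["external"]
    else:
        targets = data.source_levels
    results: list[EffectEstimate] = []
    for t in targets:
        if is_ste:
            if t == "external":
                levels = sorted(external.EM.unique())
            else:
                levels = data.em_levels
            cells = [_one_cell(data, external, fits, spec, t, em, em)
                     for em in levels]
            if add_bands and cells:
                band = simultaneous_band(
                    np.array([c.diff for c in cells]),
                    np.column_stack([c.if_diff for c in cells]),
                    level=spec.level, draws=spec.scb_draws, seed=spec.seed,
                )
                for c, lo, hi in zip(cells, band.lower, band.upper):
                    c.scb_low, c.scb_high = float(lo), float(hi)
            results.extend(cells)
        else:
            results.append(_one_cell(data, external, fits, spec, t, "overall", None))
    for c in results:
        c.ci_low, c.ci_high = wald_interval(c.diff, c.se, spec.level)
    return results


def estimates_to_frames(
    estimates: list[EffectEstimate], level: float = 0.95
) -> dict[str, pd.DataFrame]:
    """Serialize estimates into the three result tables: arm-0 potential
    outcome means (``df_A0``), arm-1 means (``df_A1``), and differences
    (``df_dif``)."""
    rows0, rows1, rowsd = [], [], []
    for c in estimates:
        lo0, hi0 = wald_interval(c.mu0, c.se0, level)
        lo1, hi1 = wald_interval(c.mu1, c.se1, level)
        base = {"target": c.target_id, "subgroup": c.subgroup, "n_target": c.n_target}
        rows0.append({**base, "estimate": c.mu0, "se": c.se0,
                      "ci_low": lo0, "ci_high": hi0})
        rows1.append({**base, "estimate": c.mu1, "se": c.se1,
                      "ci_low": lo1, "ci_high": hi1})
        rowsd.append({**base, "estimate": c.diff, "se": c.se,
                      "ci_low": c.ci_low, "ci_high": c.ci_high,
                      "scb_low": c.scb_low, "scb_high": c.scb_high})
    return {
        "df_A0": pd.DataFrame(rows0),
        "df_A1": pd.DataFrame(rows1),
        "df_dif": pd.DataFrame(rowsd),
    }
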
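"""Estimator tests, centered on independent oracles.

The key oracle is exhaustive enumeration on a fully discrete study (one
binary covariate, two sources): with nuisances set to exact empirical
frequencies, the augmented estimator must coincide with the standardization
(plug-in) estimator computed by summing over strata, because the
augmentation term solves the same weighted estimating equation the pooled
frequency outcome model solves.
"""

import numpy as np
import pandas as pd
import pytest

from causalmeta import (
    AnalysisSpec,
    ExternalCovariates,
    MultiSourceDataset,
    NuisanceFits,
    effect,
    fit_nuisances,
    po_mean_external,
    po_mean_internal,
)
from conftest import make_discrete_data


def frequency_nuisances(data, external=None):
    """Exact empirical-frequency nuisances for a discrete study.

    The pooled outcome model g_a(x) is the inverse-propensity-weighted cell
    mean sum_s n_{x,s} ybar(x,s,a) / n_x — the empirical solution of the
    pooled weighted least-squares estimating equation — so that the
    augmentation term vanishes identically.
    """
    x = data.X["x"].to_numpy().astype(int)
    s = data.S.to_numpy()
    a = data.A.to_numpy().astype(int)
    y = data.Y.to_numpy()
    levels = data.source_levels
    xs = np.unique(x)

    g = {0: np.zeros(2), 1: np.zeros(2)}
    for xv in xs:
        n_x = (x == xv).sum()
        for av in (0, 1):
            tot = 0.0
            for sv in levels:
                cell = (x == xv) & (s == sv)
                treated = cell & (a == av)
                ybar = y[treated].mean()
                tot += cell.sum() * ybar
            g[av][xv] = tot / n_x

    n = data.n
    eta = np.zeros((n, len(levels)))
    e1 = np.zeros(n)
    for xv in xs:
        mask = x == xv
        for j, sv in enumerate(levels):
            eta[mask, j] = ((x == xv) & (s == sv)).sum() / mask.sum()
        for sv in levels:
            cell = (x == xv) & (s == sv)
            e1[cell] = (cell & (a == 1)).sum() / cell.sum()

    q = None
    g0_full, g1_full = g[0][x], g[1][x]
    if external is not None:
        xe = external.X["x"].to_numpy().astype(int)
        x_all = np.concatenate([x, xe])
        q = np.zeros(len(x_all))
        for xv in xs:
            n_ms = (x == xv).sum()
            n_ex = (xe == xv).sum()
            q[x_all == xv] = n_ex / (n_ms + n_ex)
        g0_full = g[0][x_all]
        g1_full = g[1][x_all]

    return NuisanceFits(
        g0=g0_full, g1=g1_full, eta=eta, source_levels=levels, e1=e1, q=q,
        eps=1e-12,
    ), g


def plugin_standardized_mean(data, g, s, a):
    """Exhaustive-enumeration plug-in: sum_x Phat(x | target) g_a(x)."""
    x = data.X["x"].to_numpy().astype(int)
    mask = data.S.to_numpy() == s
    out = 0.0
    for xv in np.unique(x):
        out += ((x == xv) & mask).sum() / mask.sum() * g[a][xv]
    return out


class TestDiscreteOracle:
    @pytest.mark.parametrize("s", ["s1", "s2"])
    @pytest.mark.parametrize("a", [0, 1])
    def test_internal_equals_plugin_enumeration(self, s, a):
        data, _ = make_discrete_data(seed=21)
        fits, g = frequency_nuisances(data)
        mu, phi = po_mean_internal(data, fits, s, a)
        assert mu == pytest.approx(plugin_standardized_mean(data, g, s, a),
                                   abs=1e-12)
        assert abs(phi.mean()) < 1e-10

    @pytest.mark.parametrize("a", [0, 1])
    def test_external_equals_plugin_enumeration(self, a):
        data, external = make_discrete_data(seed=22)
        fits, g = frequency_nuisances(data, external)
        mu, phi = po_mean_external(data, external, fits, a)
        xe = external.X["x"].to_numpy().astype(int)
        plug = sum((xe == xv).mean() * g[a][xv] for xv in np.unique(xe))
        assert mu == pytest.approx(plug, abs=1e-12)
        assert abs(phi.mean()) < 1e-10

    @pytest.mark.parametrize("a", [0, 1])
    def test_tiny_handbuilt_example_matches_enumeration(self, a):
        """10 rows, every stratum visited, checked against the same
        enumeration done by hand-maintained loops."""
        data = MultiSourceDataset(
            Y=np.array([1., 3., 2., 4., 0., 2., 5., 1., 3., 2.]),
            S=np.array(["s1"] * 6 + ["s2"] * 4),
            A=np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1]),
            X=pd.DataFrame({"x": [0., 0., 1., 1., 0., 1., 0., 0., 1., 1.]}),
        )
        fits, g = frequency_nuisances(data)
        mu, _ = po_mean_internal(data, fits, "s1", a)
        assert mu == pytest.approx(plugin_standardized_mean(data, g, "s1", a),
                                   abs=1e-12)


class TestAlgebraicReductions:
    def test_zero_residuals_reduce_to_outcome_model_average(self):
        """If Y equals g_a(X) on arm a, the augmentation vanishes and the
        estimate is the plain average of g over the target rows."""
        data, _ = make_discrete_data(seed=30)
        fits, g = frequency_nuisances(data)
        x = data.X["x"].to_numpy().astype(int)
        data_exact = MultiSourceDataset(
            Y=np.where(data.A.to_numpy() == 1, fits.g1, fits.g0),
            S=data.S, A=data.A, X=data.X)
        mu, _ = po_mean_internal(data_exact, fits, "s1", 1)
        target = data.S.to_numpy() == "s1"
        assert mu == pytest.approx(fits.g1[target].mean(), abs=1e-12)

    def test_single_source_reduces_to_hajek_ipw(self):
        """m=1, g == 0: the estimate is the Horvitz-Thompson mean
        (1/N) sum A_i Y_i / e_i (the Hajek normalizer is N itself)."""
        rng = np.random.default_rng(31)
        n = 200
        y = rng.normal(size=n)
        a = rng.integers(0, 2, size=n)
        e1 = np.clip(rng.uniform(0.2, 0.8, size=n), None, None)
        data = MultiSourceDataset(Y=y, S=np.repeat("s", n), A=a,
                                  X=pd.DataFrame({"x": rng.normal(size=n)}))
        fits = NuisanceFits(
            g0=np.zeros(n), g1=np.zeros(n), eta=np.ones((n, 1)),
            source_levels=["s"], e1=e1)
        mu, _ = po_mean_internal(data, fits, "s", 1)
        assert mu == pytest.approx(np.mean(a * y / e1), rel=1e-12)

    def test_empty_target_cell_is_an_error(self):
        data, _ = make_discrete_data(seed=32)
        fits, _ = frequency_nuisances(data)
        with pytest.raises(ValueError, match="empty target"):
            po_mean_internal(data, fits, "s_not_there", 1)


class TestEffect:
    def test_null_effect_detected(self):
        """Y independent of A: the estimated difference is within 3 SEs of 0."""
        rng = np.random.default_rng(33)
        n = 1500
        x = rng.normal(size=n)
        data = MultiSourceDataset(
            Y=1.0 + x + rng.normal(size=n),
            S=np.repeat(["s1", "s2"], n // 2),
            A=rng.integers(0, 2, size=n),
            X=pd.DataFrame({"x": x}))
        spec = AnalysisSpec()
        fits = fit_nuisances(data, None, spec)
        for est in effect(data, None, fits, spec):
            assert abs(est.diff) < 3 * est.se

    def test_ste_internal_has_sources_times_subgroups_rows(self, small_study):
        data, _, _ = small_study
        spec = AnalysisSpec(estimand="STE")
        fits = fit_nuisances(data, None, spec)
        ests = effect(data, None, fits, spec)
        assert len(ests) == data.m * len(data.em_levels)
        assert all(np.isfinite(e.scb_low) for e in ests)

    def test_diff_is_exactly_mu1_minus_mu0(self, small_study):
        data, _, _ = small_study
        spec = AnalysisSpec()
        fits = fit_nuisances(data, None, spec)
        for est in effect(data, None, fits, spec):
            assert est.diff == est.mu1 - est.mu0
            np.testing.assert_array_equal(est.if_diff, est.if1 - est.if0)

    def test_row_permutation_leaves_estimates_unchanged(self):
        data, _ = make_discrete_data(seed=34)
        spec = AnalysisSpec()
        fits = fit_nuisances(data, None, spec)
        base = {(e.target_id): e.diff for e in effect(data, None, fits, spec)}

        rng = np.random.default_rng(0)
        perm = rng.permutation(data.n)
        pdata = MultiSourceDataset(
            Y=data.Y.to_numpy()[perm], S=data.S.to_numpy()[perm],
            A=data.A.to_numpy()[perm], X=data.X.iloc[perm])
        pfits = fit_nuisances(pdata, None, spec)
        for e in effect(pdata, None, pfits, spec):
            assert e.diff == pytest.approx(base[e.target_id], rel=1e-6)

    def test_source_relabeling_only_renames_targets(self):
        data, _ = make_discrete_data(seed=35)
        spec = AnalysisSpec()
        fits = fit_nuisances(data, None, spec)
        base = {e.target_id: e.diff for e in effect(data, None, fits, spec)}

        rename = {"s1": "zebra", "s2": "ant"}
        rdata = MultiSourceDataset(
            Y=data.Y, S=np.array([rename[s] for s in data.S]),
            A=data.A, X=data.X)
        rfits = fit_nuisances(rdata, None, spec)
        for e in effect(rdata, None, rfits, spec):
            orig = {v: k for k, v in rename.items()}[e.target_id]
            assert e.diff == pytest.approx(base[orig], rel=1e-6)

    def test_target_only_augmentation_differs_but_agrees_statistically(self):
        """The diagnostic variant restricting the residual term to the
        target source is a different (less efficient) estimator but must
        agree with the pooled one within sampling error."""
        data, _ = make_discrete_data(seed=36, n=2000)
        pooled_spec = AnalysisSpec()
        fits = fit_nuisances(data, None, pooled_spec)
        pooled = effect(data, None, fits, pooled_spec)
        diag = effect(data, None, fits,
                      pooled_spec.replace(augmentation="target_only"))
        for p, d in zip(pooled, diag):
            assert d.diff != p.diff  # genuinely different estimator
            assert abs(d.diff - p.diff) < 4 * p.se
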
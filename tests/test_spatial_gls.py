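"""Neighborhood averaging and spatial GLS regression."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from tailsync import (
    gls_exponential,
    great_circle_distance_matrix,
    neighborhood_mean_pairwise,
    neighborhood_mean_sitewise,
    pairwise_synchrony,
    driver_tail_profile,
    regression_suite,
)
from tailsync.spatial_gls import _objective

from conftest import line_sites, make_panel


@pytest.fixture
def dist10():
    return great_circle_distance_matrix(line_sites(10, spacing_km=5.0))


class TestNeighborhoodMeans:
    def test_two_sites_share_their_pair_value(self):
        dist = great_circle_distance_matrix(line_sites(2, spacing_km=10.0))
        D = np.array([[0.0, 0.4], [0.4, 0.0]])
        out = neighborhood_mean_pairwise(D, dist, 25.0)
        assert np.allclose(out, 0.4)

    def test_radius_below_spacing_gives_all_missing(self, dist10):
        D = np.ones((10, 10))
        out = neighborhood_mean_pairwise(D, dist10, 1.0)
        assert np.isnan(out).all()

    def test_pairwise_matches_brute_force(self, dist10, rng):
        D = rng.normal(size=(10, 10))
        D = (D + D.T) / 2
        radius = 12.0
        out = neighborhood_mean_pairwise(D, dist10, radius)
        for i in range(10):
            vals = [
                D[i, j]
                for j in range(10)
                if j != i and dist10.d[i, j] <= radius
            ]
            if vals:
                assert np.isclose(out[i], np.mean(vals))
            else:
                assert np.isnan(out[i])

    def test_sitewise_includes_focal_site(self, dist10, rng):
        v = rng.normal(size=10)
        out = neighborhood_mean_sitewise(v, dist10, 1.0)
        assert np.allclose(out, v)  # isolated discs keep their own value

    def test_sitewise_matches_brute_force(self, dist10, rng):
        v = rng.normal(size=10)
        radius = 11.0
        out = neighborhood_mean_sitewise(v, dist10, radius)
        for i in range(10):
            vals = [v[j] for j in range(10) if dist10.d[i, j] <= radius]
            assert np.isclose(out[i], np.mean(vals))

    def test_neighbor_sets_nested_in_radius(self, dist10):
        small = dist10.d <= 10.0
        large = dist10.d <= 30.0
        assert np.all(large[small])


class TestGls:
    def test_identity_correlation_reproduces_ols(self, rng):
        n = 60
        dist = great_circle_distance_matrix(line_sites(n, spacing_km=2.0))
        x = rng.normal(size=n)
        y = 1.0 + 0.5 * x + 0.2 * rng.normal(size=n)
        fit = gls_exponential(y, x, dist, range_km=1e-9)
        X = np.column_stack([np.ones(n), x])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta, beta_ols, atol=1e-8)

    def test_exact_relationship(self, rng):
        n = 40
        dist = great_circle_distance_matrix(line_sites(n, spacing_km=2.0))
        x = rng.normal(size=n)
        fit = gls_exponential(x.copy(), x, dist, range_km=5.0)
        assert np.allclose(fit.beta, [0.0, 1.0], atol=1e-8)
        assert fit.p[1] < 1e-12 or fit.se[1] == 0.0

    def test_all_zero_response(self, rng):
        n = 40
        dist = great_circle_distance_matrix(line_sites(n, spacing_km=2.0))
        fit = gls_exponential(np.zeros(n), rng.normal(size=n), dist)
        assert np.allclose(fit.beta, 0.0, atol=1e-12)
        assert np.allclose(fit.p, 1.0)

    def test_profile_optimum_beats_grid(self, rng):
        n = 80
        dist = great_circle_distance_matrix(line_sites(n, spacing_km=2.0))
        L = np.linalg.cholesky(np.exp(-dist.d / 15.0))
        x = rng.normal(size=n)
        y = 0.3 * x + 0.2 * (L @ rng.standard_normal(n))
        fit = gls_exponential(y, x, dist)
        X = np.column_stack([np.ones(n), x])
        for r in np.geomspace(0.5, 500.0, 12):
            assert fit.loglik >= _objective(dist.d, y, X, r, 0.0, "reml") - 1e-6

    def test_singular_design_rejected(self, rng):
        n = 40
        dist = great_circle_distance_matrix(line_sites(n, spacing_km=2.0))
        x = np.ones(n)  # collinear with the intercept
        with pytest.raises(ValueError, match="singular"):
            gls_exponential(rng.normal(size=n), x, dist)

    def test_too_few_complete_cases_rejected(self, rng):
        n = 25
        dist = great_circle_distance_matrix(line_sites(n, spacing_km=2.0))
        X = rng.normal(size=(n, 2))
        with pytest.raises(ValueError, match="complete sites"):
            gls_exponential(rng.normal(size=n), X, dist)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_nlme_gls_oracle(self, tmp_path, rng):
        # Independent oracle: nlme::gls with corExp, REML, on one dataset.
        n = 60
        sites = line_sites(n, spacing_km=3.0)
        dist = great_circle_distance_matrix(sites)
        L = np.linalg.cholesky(np.exp(-dist.d / 20.0))
        x = L @ rng.standard_normal(n)
        y = 0.2 + 0.4 * x + 0.15 * (L @ rng.standard_normal(n))
        km = np.cumsum(np.r_[0.0, np.full(n - 1, 3.0)])
        pd.DataFrame({"y": y, "x": x, "km": km}).to_csv(tmp_path / "d.csv", index=False)
        script = textwrap.dedent(
            """
            library(nlme)
            d <- read.csv(commandArgs(TRUE)[1])
            fit <- gls(y ~ x, data = d,
                       correlation = corExp(form = ~km, nugget = FALSE),
                       method = "REML")
            cat(coef(fit), sqrt(diag(vcov(fit))),
                coef(fit$modelStruct$corStruct, unconstrained = FALSE), sep = "\\n")
            """
        )
        (tmp_path / "fit.R").write_text(script)
        out = subprocess.run(
            ["Rscript", str(tmp_path / "fit.R"), str(tmp_path / "d.csv")],
            capture_output=True, text=True, check=True,
        )
        vals = [float(v) for v in out.stdout.split()]
        r_beta, r_se, r_range = vals[0:2], vals[2:4], vals[4]
        fit = gls_exponential(y, x, dist)
        assert np.allclose(fit.beta, r_beta, rtol=1e-3, atol=1e-5)
        assert np.allclose(fit.se, r_se, rtol=1e-2, atol=1e-5)
        assert np.isclose(fit.range_km, r_range, rtol=0.05)


class TestRegressionSuite:
    def _inputs(self, rng, n=40):
        sites = line_sites(n, spacing_km=3.0)
        dist = great_circle_distance_matrix(sites)
        panel = make_panel(rng.normal(size=(n, 25)))
        panel.site_ids = dist.site_ids
        sync = pairwise_synchrony(panel)
        drv = make_panel(rng.normal(size=(n, 25)), name="wave_calmness")
        drv.site_ids = dist.site_ids
        profiles = {"wave_calmness": driver_tail_profile(panel, drv)}
        return sync, profiles, dist, drv

    def test_table_shape_and_terms(self, rng):
        sync, profiles, dist, drv = self._inputs(rng)
        tab = regression_suite(
            sync, profiles, dist, radii=(15.0,), mean_calmness=drv.values.mean(axis=1)
        )
        assert set(tab["model"]) == {
            "synchrony_tail_dep ~ driver_tail_dep",
            "calmness_tail_dep ~ mean_calmness",
        }
        assert list(tab[tab["radius_km"] == 15.0]["term"]) == ["intercept", "wave_calmness"]

    def test_invariant_to_site_permutation(self, rng):
        sync, profiles, dist, _ = self._inputs(rng)
        perm = rng.permutation(len(sync.site_ids))
        from tailsync import SynchronySet
        from tailsync.io_panels import DistanceMatrix

        ids_p = [sync.site_ids[i] for i in perm]
        sync_p = SynchronySet(
            site_ids=ids_p,
            m_upper=sync.m_upper[np.ix_(perm, perm)],
            m_lower=sync.m_lower[np.ix_(perm, perm)],
            d=sync.d[np.ix_(perm, perm)],
        )
        prof_p = {
            k: v.iloc[perm].reset_index(drop=True) for k, v in profiles.items()
        }
        dist_p = DistanceMatrix(ids_p, dist.d[np.ix_(perm, perm)])
        t1 = regression_suite(sync, profiles, dist, radii=(15.0,))
        t2 = regression_suite(sync_p, prof_p, dist_p, radii=(15.0,))
        assert np.allclose(t1["beta"], t2["beta"], atol=1e-8)
        assert np.allclose(t1["p"], t2["p"], atol=1e-8)
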
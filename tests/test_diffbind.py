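"""NB GLM framework: dispersion, fitting, contrasts, FDR and calling."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from endosig.diffbind import (
    RegionCounts,
    SampleDesign,
    adjust_fdr,
    call_dbrs,
    differential_binding,
    estimate_dispersion,
    fit_nb_glm,
    test_contrast,
)
from endosig.simulate import simulate_chip_counts

DESIGN = ["a", "a", "a", "b", "b", "b"]
LIBS = [1_000_000] * 6


def make_rc(counts, design=DESIGN, libs=LIBS):
    counts = np.atleast_2d(np.asarray(counts))
    rc, _ = simulate_chip_counts(
        counts.shape[0], design, 0.0, 0.0, 0.0, libs, seed=0
    )
    return RegionCounts(regions=rc.regions, counts=counts, design=rc.design)


class TestDispersion:
    def test_constant_counts_have_zero_moment(self):
        rc = make_rc(np.full((3, 6), 50))
        est = estimate_dispersion(rc)
        np.testing.assert_array_equal(est.moment, 0.0)
        # shrunk toward common
        np.testing.assert_allclose(
            est.tagwise, est.prior_df * est.common / (est.residual_df + est.prior_df)
        )

    def test_simulation_recovery(self):
        rc, _ = simulate_chip_counts(5000, DESIGN, 0.0, 0.0, 0.2, LIBS, seed=13)
        est = estimate_dispersion(rc)
        assert 0.15 <= est.tagwise.mean() <= 0.25
        assert 0.15 <= est.common <= 0.25

    def test_all_zero_region_takes_common_and_is_flagged(self):
        counts = np.vstack([np.zeros(6, dtype=int), np.full(6, 40)])
        rng = np.random.default_rng(0)
        noisy = rng.poisson(100, size=(50, 6))
        rc = make_rc(np.vstack([counts, noisy]))
        est = estimate_dispersion(rc)
        assert est.all_zero[0]
        assert est.tagwise[0] == est.common


class TestGLMFit:
    def test_identical_counts_give_zero_group_coefficient(self):
        rc = make_rc(np.full((4, 6), 77))
        X = rc.design.design_matrix("cell_type")[0]
        fit = fit_nb_glm(rc.counts, X, 0.1, np.log(rc.design.lib_sizes))
        np.testing.assert_allclose(fit.beta[:, 1], 0.0, atol=1e-6)

    def test_poisson_limit_matches_statsmodels_glm(self, rng):
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        offsets = np.log(np.array(LIBS, dtype=float))
        counts = rng.poisson(80, size=(25, 6))
        fit = fit_nb_glm(counts, X, 0.0, offsets)
        for g in range(counts.shape[0]):
            ref = sm.GLM(
                counts[g], X, family=sm.families.Poisson(), offset=offsets
            ).fit()
            np.testing.assert_allclose(fit.beta[g], ref.params, atol=1e-6)

    def test_single_region_matches_grid_search_mle(self):
        # one region, two groups: grid-search the NB likelihood directly
        from scipy.special import gammaln

        y = np.array([95, 110, 102, 310, 290, 305], dtype=float)
        phi = 0.05
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        offsets = np.zeros(6)
        fit = fit_nb_glm(y[None, :], X, phi, offsets)

        def ll(b0, b1):
            mu = np.exp(b0 + b1 * X[:, 1])
            r = 1 / phi
            return (
                gammaln(y + r)
                - gammaln(r)
                - gammaln(y + 1)
                + y * np.log(phi * mu / (1 + phi * mu))
                - r * np.log1p(phi * mu)
            ).sum()

        b0_grid = np.linspace(4.0, 5.2, 400)
        b1_grid = np.linspace(0.5, 1.8, 400)
        grid = np.array([[ll(b0, b1) for b1 in b1_grid] for b0 in b0_grid])
        i, j = np.unravel_index(grid.argmax(), grid.shape)
        assert abs(fit.beta[0, 0] - b0_grid[i]) < 1e-2
        assert abs(fit.beta[0, 1] - b1_grid[j]) < 1e-2
        # and the fitted likelihood is at least the best grid value
        assert fit.loglik[0] >= grid.max() - 1e-6

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_nb_glm(np.full((2, 6), 10), X, 0.1, np.zeros(6))


class TestContrast:
    def test_zero_contrast_rejected(self):
        rc = make_rc(np.full((2, 6), 10))
        X = rc.design.design_matrix("cell_type")[0]
        fit = fit_nb_glm(rc.counts, X, 0.1, np.log(rc.design.lib_sizes))
        with pytest.raises(ValueError):
            test_contrast(fit, np.zeros(2))

    def test_known_fold_change_recovered(self, rng):
        mu = np.where(np.array([0, 0, 0, 1, 1, 1]) == 1, 400.0, 100.0)
        counts = rng.poisson(np.broadcast_to(mu, (300, 6)))
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        fit = fit_nb_glm(counts, X, 0.0, np.zeros(6))
        res = test_contrast(fit, np.array([0.0, 1.0]), lib_sizes=np.ones(6))
        assert abs(res["logFC"].mean() - 2.0) < 0.15

    def test_logcpm_definition(self):
        counts = np.array([[100, 100, 100, 100, 100, 100]])
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        fit = fit_nb_glm(counts, X, 0.1, np.log(np.array(LIBS, float)))
        res = test_contrast(fit, np.array([0.0, 1.0]), lib_sizes=np.array(LIBS, float))
        assert res["logCPM"][0] == pytest.approx(np.log2(100 + 0.5), abs=1e-9)


class TestFDR:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            adjust_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_trivial_cases(self):
        np.testing.assert_array_equal(adjust_fdr([1.0, 1.0, 1.0]), 1.0)
        np.testing.assert_array_equal(adjust_fdr([0.2]), [0.2])

    def test_matches_hand_step_up_on_random_vectors(self, rng):
        def bh(p):
            p = np.asarray(p)
            n = len(p)
            order = np.argsort(p, kind="mergesort")
            adj = p[order] * n / np.arange(1, n + 1)
            adj = np.minimum.accumulate(adj[::-1])[::-1]
            out = np.empty(n)
            out[order] = np.minimum(adj, 1.0)
            return out

        for _ in range(200):
            p = rng.random(rng.integers(1, 60))
            np.testing.assert_allclose(adjust_fdr(p), bh(p), atol=1e-15)

    def test_order_invariance(self, rng):
        p = rng.random(100)
        perm = rng.permutation(100)
        np.testing.assert_allclose(adjust_fdr(p)[perm], adjust_fdr(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.2])

    def test_monotone_in_p_ranking(self, rng):
        p = rng.random(500)
        fdr = adjust_fdr(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-15).all()


class TestCallDBRs:
    def _frame(self, logfc, fdr, logcpm):
        return pd.DataFrame(
            {"logFC": [logfc], "logCPM": [logcpm], "p": [fdr], "fdr": [fdr]}
        )

    @pytest.mark.parametrize(
        "logfc,fdr,logcpm,expected",
        [
            (1.6, 0.005, 0.0, "up"),
            (1.6, 0.005, -4.0, "ns"),  # fails the abundance filter
            (-1.6, 0.005, 0.0, "down"),
            (0.0, 0.0001, 0.0, "ns"),
            (1.5, 0.005, 0.0, "ns"),  # strict inequality at the threshold
            (1.6, 0.01, 0.0, "ns"),  # strict FDR inequality
        ],
    )
    def test_threshold_conjunction(self, logfc, fdr, logcpm, expected):
        out = call_dbrs(self._frame(logfc, fdr, logcpm))
        assert out["call"][0] == expected

    def test_sorted_by_abs_logfc_then_fdr(self):
        df = pd.DataFrame(
            {
                "logFC": [1.0, -3.0, 3.0, 2.0],
                "logCPM": [0.0] * 4,
                "p": [0.5, 0.001, 0.001, 0.001],
                "fdr": [0.5, 0.002, 0.001, 0.001],
            }
        )
        out = call_dbrs(df)
        assert list(np.abs(out["logFC"])) == [3.0, 3.0, 2.0, 1.0]
        assert list(out["fdr"][:2]) == [0.001, 0.002]


def test_offset_invariance_under_library_doubling():
    rc, _ = simulate_chip_counts(300, DESIGN, 0.1, 2.0, 0.1, LIBS, seed=31)
    res1 = differential_binding(rc)
    counts2 = rc.counts.copy()
    counts2[:, 0] *= 2
    frame2 = rc.design.frame.copy()
    frame2.loc[0, "lib_size"] *= 2
    rc2 = RegionCounts(
        regions=rc.regions, counts=counts2, design=SampleDesign(frame2)
    )
    res2 = differential_binding(rc2)
    key = ["chrom", "start", "end"]
    m = res1.set_index(key).join(res2.set_index(key), rsuffix="_2")
    assert np.max(np.abs(m["logFC"] - m["logFC_2"])) < 1e-6
    assert np.max(np.abs(m["p"] - m["p_2"])) < 1e-6
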
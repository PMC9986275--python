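"""Unit tests for the cross-population composite-likelihood sweep scan."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln, ndtr, xlog1py, xlogy

from sweepscan import xpclr_scan as xs
from sweepscan.synthetic_data import draw_population_freqs

from conftest import make_table, two_pop_assignment


def trapezoid_neutral_loglik(k, n, p_ref, omega, npts=1_000_000):
    """Dense log-domain trapezoid oracle for the neutral site likelihood.

    More accurate than adaptive quadrature in the deep tails (the integrand
    is log-concave with a single narrow peak).
    """
    sigma = math.sqrt(omega * p_ref * (1 - p_ref))
    p = np.linspace(1e-12, 1 - 1e-12, npts)
    logC = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    logf = (
        logC + xlogy(k, p) + xlog1py(n - k, -p)
        - 0.5 * ((p - p_ref) / sigma) ** 2
        - math.log(sigma) - 0.5 * math.log(2 * math.pi)
    )
    m = logf.max()
    terms = [math.log(np.trapezoid(np.exp(logf - m), p)) + m]
    m0 = float(ndtr(-p_ref / sigma))
    m1 = float(ndtr((p_ref - 1) / sigma))
    if k == 0 and m0 > 0:
        terms.append(math.log(m0))
    if k == n and m1 > 0:
        terms.append(math.log(m1))
    mm = max(terms)
    return mm + math.log(sum(math.exp(t - mm) for t in terms))


class TestSiteLikelihoods:
    CASES = [
        (3, 10, 0.5, 0.1),
        (0, 40, 0.9, 0.05),
        (40, 40, 0.1, 0.02),
        (90, 100, 0.15, 0.01),
        (1, 200, 0.8, 0.2),
    ]

    @pytest.mark.parametrize("k,n,p_ref,omega", CASES)
    def test_neutral_matches_trapezoid_oracle(self, k, n, p_ref, omega):
        got = xs.neutral_site_loglik(k, n, p_ref, omega)
        want = trapezoid_neutral_loglik(k, n, p_ref, omega)
        assert got == pytest.approx(want, abs=5e-9)

    def test_neutral_normalises(self):
        for n, p_ref, omega in [(12, 0.3, 0.1), (40, 0.85, 0.3)]:
            total = sum(
                math.exp(xs.neutral_site_loglik(k, n, p_ref, omega))
                for k in range(n + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_sweep_normalises(self):
        for c in (0.0, 0.3, 0.9):
            total = sum(
                math.exp(xs.sweep_site_loglik(k, 20, 0.4, 0.15, c))
                for k in range(21)
            )
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_c_one_reduces_to_neutral_exactly(self):
        for k, n, p_ref, omega in self.CASES:
            assert xs.sweep_site_loglik(k, n, p_ref, omega, 1.0) == (
                xs.neutral_site_loglik(k, n, p_ref, omega)
            )

    def test_omega_zero_recovers_binomial(self):
        for k, n, p_ref in [(3, 10, 0.4), (0, 8, 0.7), (8, 8, 0.2)]:
            got = xs.neutral_site_loglik(k, n, p_ref, 0.0)
            want = xs._log_binom(k, n, p_ref)
            assert got == want

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            xs.neutral_site_loglik(5, 4, 0.5, 0.1)
        with pytest.raises(ValueError):
            xs.neutral_site_loglik(1, 4, 0.0, 0.1)
        with pytest.raises(ValueError):
            xs.sweep_site_loglik(1, 4, 0.5, 0.1, 1.5)


class TestDriftGrids:
    def test_matches_exact_scalar_path(self):
        # the vectorised +-8 sigma grid agrees with the exact mode-centered
        # integrator wherever the site log-likelihood is non-negligible
        rng = np.random.default_rng(19)
        checked = 0
        for _ in range(150):
            n = int(rng.integers(4, 200))
            k = int(rng.integers(0, n + 1))
            p_ref = float(rng.uniform(0.05, 0.95))
            omega = float(rng.uniform(0.01, 0.5))
            c = float(rng.uniform(0.0, 1.0))
            exact_n = xs.neutral_site_loglik(k, n, p_ref, omega)
            exact_s = xs.sweep_site_loglik(k, n, p_ref, omega, c)
            g = xs._DriftGrids(
                np.array([k]), np.array([n]), np.array([p_ref]), omega, 64
            )
            neut = g.neutral_lik()
            sw = g.sweep_lik(np.array([[c]]), neut)
            # compare where the likelihood is non-negligible: the shared
            # +-8 sigma grid is a deliberate approximation whose error grows
            # in the deep tails the scalar integrator handles exactly
            if exact_n > -15:
                checked += 1
                assert math.log(neut[0]) == pytest.approx(exact_n, abs=1e-8)
            if exact_s > -15:
                assert math.log(sw[0, 0]) == pytest.approx(exact_s, abs=1e-8)
        assert checked > 90

    def test_degenerate_sigma_uses_point_mass(self):
        g = xs._DriftGrids(np.array([2]), np.array([10]), np.array([0.3]), 0.0, 32)
        lik = g.neutral_lik()
        assert math.log(lik[0]) == pytest.approx(xs._log_binom(2, 10, 0.3))


class TestOmegaEstimation:
    def test_recovers_drift_scale(self):
        # object frequencies drift from the reference by Balding-Nichols
        # with F = 0.2 -> omega should recover 0.2
        rng = np.random.default_rng(23)
        s = 4000
        p_ref = rng.uniform(0.2, 0.8, size=s)
        p_obj = draw_population_freqs(p_ref, 0.2, rng)
        n1 = n2 = 100
        gt = np.zeros((s, n1 + n2, 2), dtype=np.int8)
        dos_o = rng.binomial(2, p_obj[:, None], size=(s, n1))
        dos_r = rng.binomial(2, p_ref[:, None], size=(s, n2))
        dos = np.concatenate([dos_o, dos_r], axis=1)
        gt[:, :, 0] = (dos >= 1)
        gt[:, :, 1] = (dos == 2)
        t = make_table(np.arange(1, s + 1) * 10, gt)
        pops = two_pop_assignment(t.samples, n1)
        omega = xs.estimate_omega(t, pops)
        assert omega == pytest.approx(0.2, rel=0.15)

    def test_too_few_sites_raises_with_advice(self):
        gt = np.zeros((10, 6, 2), dtype=np.int8)
        gt[:, 0] = [0, 1]
        gt[:, 3] = [0, 1]
        t = make_table(np.arange(1, 11) * 10, gt)
        pops = two_pop_assignment(t.samples, 3)
        with pytest.raises(ValueError, match="fixed omega"):
            xs.estimate_omega(t, pops)

    def test_floor(self):
        rng = np.random.default_rng(29)
        s = 1000
        p = rng.uniform(0.3, 0.7, size=s)
        gt = np.zeros((s, 40, 2), dtype=np.int8)
        dos = rng.binomial(2, p[:, None], size=(s, 40))
        gt[:, :, 0] = (dos >= 1)
        gt[:, :, 1] = (dos == 2)
        t = make_table(np.arange(1, s + 1) * 10, gt)
        pops = two_pop_assignment(t.samples, 20)
        # identical populations: only sampling noise, estimate near the floor
        assert xs.estimate_omega(t, pops, min_sites=100) >= 1e-6


class TestLdWeights:
    def test_duplicate_snps_split_weight(self):
        row = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
        d = np.vstack([row, row, row + 0.0])  # three identical rows
        w = xs.ld_weights(d, 0.95)
        assert np.allclose(w, 1 / 3)

    def test_independent_snps_full_weight(self):
        rng = np.random.default_rng(31)
        d = rng.integers(0, 3, size=(4, 200)).astype(float)
        w = xs.ld_weights(d, 0.95)
        assert np.allclose(w, 1.0)

    def test_zero_variance_row(self):
        d = np.vstack([np.full(10, 1.0), np.arange(10, dtype=float)])
        w = xs.ld_weights(d, 0.95)
        assert w[0] == 1.0 and w[1] == 1.0

    def test_missing_mean_imputed(self):
        row = np.array([0.0, 1.0, 2.0, np.nan, 0.0, 2.0])
        w = xs.ld_weights(np.vstack([row, row]), 0.95)
        assert np.allclose(w, 0.5)

    def test_bad_shape(self):
        with pytest.raises(ValueError):
            xs.ld_weights(np.zeros(5), 0.95)


class TestWindows:
    def test_contig_window_count(self):
        assert xs.contig_window_count(100_000, 200_000, 20_000) == 0
        assert xs.contig_window_count(200_000, 200_000, 20_000) == 1
        assert xs.contig_window_count(600_000, 200_000, 20_000) == 21
        assert xs.contig_window_count(10_000_000, 200_000, 20_000) == 491

    def test_params_validation(self):
        with pytest.raises(ValueError):
            xs.XpclrParams(step=300_000)
        with pytest.raises(ValueError):
            xs.XpclrParams(ld_r2_max=0.0)

    def test_default_kappa_grid(self):
        g = xs.default_kappa_grid()
        assert len(g) == 12
        assert g[0] == pytest.approx(1e-7) and g[-1] == pytest.approx(1e-3)
        assert np.all(np.diff(np.log(g)) > 0)


class TestTopPercentBlocks:
    @staticmethod
    def blocks_frame(n, direction, rng):
        return pd.DataFrame(
            {
                "contig": ["chr1"] * n,
                "start": np.arange(1, n + 1) * 100,
                "end": np.arange(1, n + 1) * 100 + 99,
                "clr": rng.uniform(0.1, 50.0, size=n),
                "direction": [direction] * n,
            }
        )

    def test_paper_scale_counts(self):
        # ceil(0.01 * 5680) = 57 and ceil(0.01 * 1046) = 11
        rng = np.random.default_rng(37)
        blocks = pd.concat(
            [self.blocks_frame(5680, "CSS", rng), self.blocks_frame(1046, "CSA", rng)],
            ignore_index=True,
        )
        top = xs.top_percent_blocks(blocks, 0.01)
        counts = top.groupby("direction").size()
        assert counts["CSS"] == 57
        assert counts["CSA"] == 11

    def test_positive_only_and_tiebreak(self):
        blocks = pd.DataFrame(
            {
                "contig": ["chr1"] * 4,
                "start": [400, 100, 200, 300],
                "end": [499, 199, 299, 399],
                "clr": [5.0, 5.0, 0.0, 0.0],
                "direction": ["d"] * 4,
            }
        )
        top = xs.top_percent_blocks(blocks, 0.5)
        assert len(top) == 1  # ceil(0.5 * 2 positive)
        assert top["start"].iloc[0] == 100  # tie broken by position

    def test_all_nonpositive_empty(self):
        blocks = pd.DataFrame(
            {"contig": ["c"], "start": [1], "end": [2], "clr": [0.0],
             "direction": ["d"]}
        )
        assert xs.top_percent_blocks(blocks, 0.01).empty

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            xs.top_percent_blocks(pd.DataFrame(), 0.0)


@pytest.fixture(scope="module")
def tiny_scan():
    from sweepscan.synthetic_data import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        n_obj=20, n_ref=10, n_sites=600, contig_length=300_000, seed=41
    )
    table, _, pops, _ = simulate_cohort(cfg)
    params = xs.XpclrParams(
        window_size=100_000, step=50_000, omega=0.1, max_snps=100
    )
    return table, pops, params


class TestScan:
    def test_columns_and_directions(self, tiny_scan):
        table, pops, params = tiny_scan
        blocks = xs.xpclr_scan(table, pops, params)
        assert list(blocks.columns) == [
            "contig", "start", "end", "focal", "n_snps", "clr", "kappa_hat",
            "direction",
        ]
        assert set(blocks["direction"]) == {"CSS", "CSA"}
        assert blocks["start"].min() == 1
        assert (blocks["end"] - blocks["start"] + 1 == 100_000).all()
        assert (blocks["clr"] >= 0).all()
        assert (blocks["n_snps"] <= 100).all()

    def test_single_direction(self, tiny_scan):
        table, pops, params = tiny_scan
        obj_only = xs.xpclr_scan(table, pops, params, directions="obj")
        assert set(obj_only["direction"]) == {"CSS"}
        ref_only = xs.xpclr_scan(table, pops, params, directions="ref")
        assert set(ref_only["direction"]) == {"CSA"}

    def test_deterministic(self, tiny_scan):
        table, pops, params = tiny_scan
        b1 = xs.xpclr_scan(table, pops, params)
        b2 = xs.xpclr_scan(table, pops, params)
        pd.testing.assert_frame_equal(b1, b2)
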
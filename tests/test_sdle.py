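"""SDLE core: shells, pair search, error growth, scaling fit, doubling time.

The heavy artillery is an independent naive O(N^2 * t) reimplementation of
the shell -> pairs -> growth -> SDLE chain, against which the vectorized
code must agree to 1e-9.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from sdleeg import (EmbeddingParams, ErrorGrowthCurve, SDLEConfig, SDLECurve,
                    ShellSpec, average_sdle, build_shells, channel_sdle,
                    epoch_sdle, error_doubling_time, error_growth,
                    extract_features, find_shell_pairs, fit_scaling,
                    reconstruct, sdle_from_growth)
from sdleeg.sdle import DegenerateSeriesError, LN2

# ---------------------------------------------------------------- oracle


def naive_chain(x, m, L, shell, theiler, t_max):
    """Brute-force shells->pairs->growth->SDLE, loops only."""
    n_vec = len(x) - (m - 1) * L
    vectors = [np.array([x[i + k * L] for k in range(m)])
               for i in range(n_vec)]
    pairs = []
    for i in range(n_vec):
        for j in range(i + 1, n_vec):
            if j - i <= theiler:
                continue
            d = math.dist(vectors[i], vectors[j])
            if shell.eps <= d <= shell.eps + shell.d_eps:
                pairs.append((i, j))
    ln_eps_t, counts, ts = [], [], []
    for t in range(t_max + 1):
        logs = [math.log(math.dist(vectors[i + t], vectors[j + t]))
                for i, j in pairs if j + t < n_vec]
        if not logs:
            break
        ln_eps_t.append(sum(logs) / len(logs))
        counts.append(len(logs))
        ts.append(t)
    lam = [(ln_eps_t[k + 1] - ln_eps_t[k]) for k in range(len(ts) - 1)]
    abscissa = ln_eps_t[:-1]
    order = sorted(range(len(abscissa)), key=lambda k: abscissa[k])
    return pairs, ts, ln_eps_t, counts, \
        [abscissa[k] for k in order], [lam[k] for k in order]


# ---------------------------------------------------------------- shells


class TestBuildShells:
    def test_recipe_sizes(self):
        x = np.random.default_rng(0).standard_normal(4096) * 10
        x = x / x.std() * 10  # SD exactly 10
        shells = build_shells(x)
        np.testing.assert_allclose([s.d_eps for s in shells],
                                   [1.0, 0.5, 0.25, 0.125])
        np.testing.assert_allclose([s.eps for s in shells],
                                   [1.0, 0.5, 0.25, 0.125])

    def test_single_shell(self):
        x = np.random.default_rng(1).standard_normal(512)
        shells = build_shells(x, n_shells=1)
        assert len(shells) == 1
        assert shells[0].d_eps == pytest.approx(0.1 * x.std())

    def test_homogeneity(self):
        x = np.random.default_rng(2).standard_normal(512)
        s1 = build_shells(x)
        s3 = build_shells(3 * x)
        for a, b in zip(s1, s3):
            assert b.eps == pytest.approx(3 * a.eps)
            assert b.d_eps == pytest.approx(3 * a.d_eps)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            build_shells(np.full(100, 2.0))


class TestFindShellPairs:
    def test_hand_checked_triplet(self):
        pts = reconstruct(np.array([0.0, 0.0, 1.0, 0.05, 1.0]),
                          EmbeddingParams(2, 1))
        # vectors: (0,0),(0,1),(1,.05),(.05,1); d((0,0),?) etc. checked by
        # the brute-force scan below; thin shell around d=0.05
        shell = ShellSpec(eps=0.0, d_eps=0.1)
        pairs = find_shell_pairs(pts, shell, theiler=0)
        d = np.linalg.norm(pts.vectors[:, None] - pts.vectors[None, :],
                           axis=-1)
        expected = [(i, j) for i in range(4) for j in range(i + 1, 4)
                    if d[i, j] <= 0.1]
        assert [tuple(p) for p in pairs] == expected

    def test_shell_above_diameter_empty(self):
        pts = reconstruct(np.random.default_rng(3).standard_normal(100),
                          EmbeddingParams(2, 1))
        shell = ShellSpec(eps=1e6, d_eps=1.0)
        assert len(find_shell_pairs(pts, shell, theiler=0)) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_scan(self, seed):
        x = np.random.default_rng(seed).standard_normal(200)
        pts = reconstruct(x, EmbeddingParams(2, 1))
        shell = build_shells(x)[1]
        pairs = find_shell_pairs(pts, shell, theiler=2)
        naive_pairs, *_ = naive_chain(x, 2, 1, shell, 2, 1)
        assert [tuple(p) for p in pairs] == naive_pairs


# ---------------------------------------------------------------- growth


class TestErrorGrowth:
    def test_mean_of_logs(self):
        # two pairs with separations e^1 and e^3 at t=0
        vectors = np.array([[0.0, 0.0], [np.e, 0.0],
                            [100.0, 0.0], [100.0 + np.e ** 3, 0.0]])
        pts = reconstruct(np.zeros(10), EmbeddingParams(2, 1))
        pts.vectors = vectors
        curve = error_growth(pts, np.array([[0, 1], [2, 3]]), t_max=0)
        assert curve.ln_eps_t[0] == pytest.approx(2.0)

    def test_doubling_pairs_slope_ln2(self):
        # separations double each step: x interleaves 0 and 2^t
        n = 20
        x = np.zeros(2 * n)
        x[1::2] = 2.0 ** np.arange(n)
        pts = reconstruct(x, EmbeddingParams(2, 2))
        curve = error_growth(pts, np.array([[0, 1]]), t_max=16, dt=2)
        slopes = np.diff(curve.ln_eps_t) / np.diff(curve.t)
        np.testing.assert_allclose(slopes, LN2 / 2, rtol=1e-12)

    def test_no_pairs_rejected(self):
        pts = reconstruct(np.arange(10.0), EmbeddingParams(2, 1))
        with pytest.raises(ValueError):
            error_growth(pts, np.empty((0, 2), dtype=int))


class TestSdleFromGrowth:
    def _curve(self, t, ln_eps):
        return ErrorGrowthCurve(t=np.asarray(t, float),
                                ln_eps_t=np.asarray(ln_eps, float),
                                pair_count=np.full(len(t), 50),
                                shell=ShellSpec(0.1, 0.1))

    def test_exact_exponential_gives_constant_lambda(self):
        t = np.arange(30.0)
        curve = self._curve(t, -3 + 0.1 * t)
        sdle = sdle_from_growth(curve)
        np.testing.assert_allclose(sdle.lam, 0.1, rtol=1e-12)

    def test_constant_separation_gives_zero(self):
        curve = self._curve(np.arange(10.0), np.full(10, -2.0))
        sdle = sdle_from_growth(curve)
        np.testing.assert_allclose(sdle.lam, 0.0, atol=1e-15)

    def test_logarithmic_growth_matches_closed_form(self):
        t = np.arange(50.0)
        a = 0.7
        curve = self._curve(t, -4 + a * np.log1p(t))
        sdle = sdle_from_growth(curve)
        expected = a * np.diff(np.log1p(t))
        np.testing.assert_allclose(np.sort(sdle.lam)[::-1],
                                   np.sort(expected)[::-1], rtol=1e-12)
        assert sdle.lam[0] > sdle.lam[-1]  # declines as scale grows


class TestAverageSdle:
    def test_identical_curves_unchanged(self):
        c = SDLECurve(ln_eps=np.linspace(-4, -1, 20),
                      lam=np.linspace(2, 0.5, 20))
        out = average_sdle([c, c, c, c])
        np.testing.assert_allclose(
            np.interp(c.ln_eps, out.ln_eps, out.lam), c.lam, rtol=1e-9)

    def test_constant_offset_halves(self):
        grid = np.linspace(-4, -1, 20)
        c1 = SDLECurve(ln_eps=grid, lam=np.linspace(2, 0.5, 20))
        c2 = SDLECurve(ln_eps=grid, lam=c1.lam + 0.6)
        out = average_sdle([c1, c2])
        np.testing.assert_allclose(out.lam, c1.lam + 0.3, rtol=1e-12)

    def test_shell_quartet_matches_interpolation_oracle(self, gen_cfg):
        from sdleeg import gen_background
        x = gen_background(gen_cfg, seed=5).data[0]
        _, growths = channel_sdle(x, SDLEConfig(max_pairs=None))
        curves = [sdle_from_growth(g) for g in growths]
        out = average_sdle(curves)
        lo = max(c.ln_eps[0] for c in curves)
        hi = min(c.ln_eps[-1] for c in curves)
        grid = np.unique(np.concatenate(
            [c.ln_eps[(c.ln_eps >= lo) & (c.ln_eps <= hi)] for c in curves]))
        expected = np.mean([np.interp(grid, c.ln_eps, c.lam)
                            for c in curves], axis=0)
        np.testing.assert_allclose(out.ln_eps, grid, atol=1e-12)
        np.testing.assert_allclose(out.lam, expected, atol=1e-9)


# ---------------------------------------------------------------- fitting


class TestFitScaling:
    def test_exact_line_recovered(self):
        grid = np.linspace(-4, -1, 40)
        curve = SDLECurve(ln_eps=grid, lam=-0.5 * grid + 0.2)
        fit = fit_scaling(curve)
        assert fit.gamma == pytest.approx(0.5, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.region == (pytest.approx(-4.0), pytest.approx(-1.0))
        assert not fit.degraded

    def test_flat_curve_gamma_zero(self):
        grid = np.linspace(-4, -1, 30)
        fit = fit_scaling(SDLECurve(ln_eps=grid, lam=np.full(30, 0.3)))
        assert fit.gamma == pytest.approx(0.0, abs=1e-12)

    def test_noisy_line_gamma_recovered_5pct(self):
        gammas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            grid = np.linspace(-5, -1, 30)
            lam = -0.8 * grid + 0.1
            lam = lam + 0.01 * np.abs(lam).max() * rng.standard_normal(30)
            gammas.append(fit_scaling(SDLECurve(ln_eps=grid, lam=lam)).gamma)
        assert np.all(np.abs(np.array(gammas) - 0.8) / 0.8 < 0.05)

    def test_piecewise_curve_finds_linear_window(self):
        # linear on [-5,-2], saturating flat tail above
        grid = np.linspace(-5, 0, 50)
        lam = np.where(grid < -2, -grid - 2, 0.0)
        fit = fit_scaling(SDLECurve(ln_eps=grid, lam=lam), r2_min=0.999)
        assert fit.region[1] <= -1.8
        # the longest qualifying window may include the breakpoint sample
        assert fit.gamma == pytest.approx(1.0, rel=0.02)


class TestExtractFeatures:
    def test_line_evaluation_at_region_scales(self):
        grid = np.linspace(-4, -1, 40)
        curve = SDLECurve(ln_eps=grid, lam=-0.5 * grid)
        fit = fit_scaling(curve)
        feats = extract_features(curve, fit)
        assert feats.lam1 == pytest.approx(2.0, rel=1e-9)
        assert feats.lam2 == pytest.approx(1.25, rel=1e-9)
        assert feats.lam3 == pytest.approx(0.5, rel=1e-9)
        assert feats.lam_bar == pytest.approx(1.25, rel=1e-9)
        assert feats.eps1 == pytest.approx(np.exp(-4))
        assert feats.eps3 == pytest.approx(np.exp(-1))

    def test_lam_bar_is_mean(self, feature_table_small):
        t = feature_table_small
        np.testing.assert_allclose(
            t["lam_bar"], t[["lam1", "lam2", "lam3"]].mean(axis=1),
            rtol=1e-9)

    def test_epileptiform_smaller_lam1(self, feature_table_small):
        by_label = feature_table_small.groupby("label")["lam1"].mean()
        assert by_label["epileptiform"] < by_label["normal"]


class TestErrorDoublingTime:
    def _curve(self, t, ln_eps):
        return ErrorGrowthCurve(t=np.asarray(t, float),
                                ln_eps_t=np.asarray(ln_eps, float),
                                pair_count=np.full(len(t), 50),
                                shell=ShellSpec(0.1, 0.1))

    def test_constant_rate_closed_form(self):
        t = np.arange(200.0)
        curve = self._curve(t, -3 + 0.1 * t)
        assert error_doubling_time(curve) == pytest.approx(LN2 / 0.1,
                                                           rel=1e-9)

    def test_never_doubles_returns_none(self):
        curve = self._curve(np.arange(10.0), np.full(10, -3.0))
        assert error_doubling_time(curve) is None

    def test_integral_of_lambda_over_tdb_is_ln2(self, gen_cfg):
        from sdleeg import gen_background
        x = gen_background(gen_cfg, seed=9).data[0]
        _, growths = channel_sdle(x, SDLEConfig())
        small = max(growths, key=lambda g: g.shell.index)
        tdb = error_doubling_time(small)
        assert tdb is not None
        # telescoping: integral of the finite-difference lambda up to T_db
        lam = np.diff(small.ln_eps_t) / np.diff(small.t)
        full, frac = int(np.floor(tdb)), tdb - np.floor(tdb)
        integral = lam[:full].sum() + (frac * lam[full] if frac else 0.0)
        assert integral == pytest.approx(LN2, abs=0.01)


# ------------------------------------------------------- chain properties


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_full_chain_matches_naive(self, seed):
        x = np.random.default_rng(100 + seed).standard_normal(250)
        shell = build_shells(x)[0]
        pts = reconstruct(x, EmbeddingParams(2, 1))
        pairs = find_shell_pairs(pts, shell, theiler=2)
        curve = error_growth(pts, pairs, t_max=32, shell=shell)
        sdle = sdle_from_growth(curve)
        (n_pairs, n_t, n_ln, n_counts,
         n_abscissa, n_lam) = naive_chain(x, 2, 1, shell, 2, 32)
        assert [tuple(p) for p in pairs] == n_pairs
        np.testing.assert_allclose(curve.ln_eps_t, n_ln, atol=1e-9)
        np.testing.assert_array_equal(curve.pair_count, n_counts)
        np.testing.assert_allclose(sdle.ln_eps, n_abscissa, atol=1e-9)
        np.testing.assert_allclose(sdle.lam, n_lam, atol=1e-9)


class TestAmplitudeEquivariance:
    def test_scaling_shifts_abscissa_only(self, gen_cfg):
        from sdleeg import gen_background
        x = gen_background(gen_cfg, seed=21).data[0]
        k = 7.5
        c1, _ = channel_sdle(x, SDLEConfig())
        c2, _ = channel_sdle(k * x, SDLEConfig())
        np.testing.assert_allclose(c2.ln_eps, c1.ln_eps + np.log(k),
                                   atol=1e-9)
        np.testing.assert_allclose(c2.lam, c1.lam, atol=1e-9)


class TestTimeReversalSymmetry:
    def test_white_noise_lambda_bar_statistically_symmetric(self):
        fwd, rev = [], []
        cfg = SDLEConfig()
        for seed in range(8):
            x = np.random.default_rng(300 + seed).standard_normal(1024) * 30
            for data, acc in ((x, fwd), (x[::-1].copy(), rev)):
                feats, _, _ = epoch_sdle(data[None, :], cfg)
                acc.append(feats.lam_bar)
        fwd, rev = np.array(fwd), np.array(rev)
        assert abs(fwd.mean() - rev.mean()) < fwd.std(ddof=1)


class TestCumulativeConsistency:
    def test_lambda_telescopes_back_to_growth(self, gen_cfg):
        from sdleeg import gen_background
        x = gen_background(gen_cfg, seed=33).data[0]
        _, growths = channel_sdle(x, SDLEConfig())
        for g in growths:
            lam = np.diff(g.ln_eps_t) / np.diff(g.t)
            recon = g.ln_eps_t[0] + np.concatenate(
                ([0.0], np.cumsum(lam * np.diff(g.t))))
            np.testing.assert_allclose(recon, g.ln_eps_t, atol=1e-12)
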
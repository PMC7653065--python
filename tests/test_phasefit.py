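import numpy as np
import pytest

from circascreen import (
    CosineFitConfig,
    DegenerateFitError,
    ExpressionSeries,
    bootstrap_ci,
    circular_diff_hours,
    coefficient_of_determination,
    fit_shared_phase,
    inner_linear_solve,
    peak_time_from_theta,
    standardize_series,
)
from circascreen.phasefit import _profile_cost

from conftest import OMEGA, cosine_series, two_gene_pair


def dense_grid_oracle(series_list, cfg, anchor="Per3", ngrid=100_000):
    """Brute-force θ scan with closed-form inner least squares per θ."""
    thetas = 2 * np.pi * np.arange(ngrid) / ngrid
    by = {s.gene: s for s in series_list}
    t = by[anchor].times_h
    total, _, _ = _profile_cost(thetas, t, by[anchor].values, OMEGA)
    for g in by:
        if g == anchor:
            continue
        costs = np.stack([
            _profile_cost(thetas + 2 * np.pi * dt / 24.0, t, by[g].values, OMEGA)[0]
            for dt in cfg.delta_tau_grid()
        ])
        total = total + costs.min(axis=0)
    i = int(np.argmin(total))
    th = thetas[i]
    _, a, _ = _profile_cost(np.array([th]), t, by[anchor].values, OMEGA)
    if a[0] < 0:
        th = (th + np.pi) % (2 * np.pi)
    return th, float(total[i])


class TestNoiselessRecovery:
    def test_exact_model_recovered(self, argmax_cfg):
        series = two_gene_pair(peak_h=5.0, offset_h=2.0)
        fit = fit_shared_phase(series, argmax_cfg)
        assert abs(circular_diff_hours(fit.p3pt_h, 5.0)) < 0.01
        assert fit.delta_tau_h["Nr1d2"] == pytest.approx(2.0)
        assert fit.cost < 1e-12
        assert fit.cd == pytest.approx(1.0)
        assert not fit.antiphase

    def test_offset_recovered_within_grid_step(self, argmax_cfg):
        series = two_gene_pair(peak_h=7.0, offset_h=2.4)
        fit = fit_shared_phase(series, argmax_cfg)
        assert abs(fit.delta_tau_h["Nr1d2"] - 2.4) <= argmax_cfg.delta_tau_step_h

    def test_three_gene_fit(self, argmax_cfg):
        times = np.array([1.0, 9.0, 17.0])
        series = [
            standardize_series(cosine_series("Per3", 6.4, times)),
            standardize_series(cosine_series("Nr1d2", 4.4, times)),
            standardize_series(cosine_series("Nr1d1", 4.6, times)),
        ]
        fit = fit_shared_phase(series, argmax_cfg)
        assert abs(circular_diff_hours(fit.p3pt_h, 6.4)) < 0.01
        assert fit.cd > 0.999


class TestOracleAgreement:
    def test_matches_dense_grid_on_noisy_data(self, argmax_cfg, rng):
        for _ in range(20):
            series = two_gene_pair(
                peak_h=rng.uniform(0, 24),
                offset_h=rng.uniform(1.5, 2.5),
                times=np.array([0.0, 8.0, 16.0]) + rng.uniform(0, 24),
                noise_sd=0.3,
                rng=rng,
            )
            fit = fit_shared_phase(series, argmax_cfg)
            th_o, cost_o = dense_grid_oracle(series, argmax_cfg)
            peak_o = peak_time_from_theta(th_o, "curve-argmax")
            assert abs(circular_diff_hours(fit.p3pt_h, peak_o)) < 0.01
            assert fit.cost <= cost_o + 1e-8

    def test_cg_backend_agrees_with_grid(self, argmax_cfg, rng):
        series = two_gene_pair(peak_h=9.3, offset_h=2.1, noise_sd=0.2, rng=rng)
        grid = fit_shared_phase(series, argmax_cfg, backend="grid")
        cg = fit_shared_phase(series, argmax_cfg, backend="cg")
        assert abs(circular_diff_hours(grid.p3pt_h, cg.p3pt_h)) < 0.02
        assert cg.cost == pytest.approx(grid.cost, abs=1e-6)


class TestInnerLinearSolve:
    def test_zero_cost_at_truth(self):
        series = two_gene_pair(peak_h=3.0)
        by = {s.gene: s for s in series}
        theta = -2 * np.pi * 3.0 / 24.0
        dtheta = {"Per3": 0.0, "Nr1d2": 2 * np.pi * 2.0 / 24.0}
        _, cost, _ = inner_linear_solve(theta, by, dtheta)
        assert cost < 1e-12

    def test_never_worse_than_constant_model(self, rng):
        series = two_gene_pair(peak_h=3.0, noise_sd=0.5, rng=rng)
        by = {s.gene: s for s in series}
        const_cost = sum(float(np.sum((s.values - s.values.mean()) ** 2))
                         for s in series)
        for theta in rng.uniform(0, 2 * np.pi, size=20):
            _, cost, _ = inner_linear_solve(theta, by, {"Nr1d2": 0.5})
            assert cost <= const_cost + 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(30):
            t = np.sort(rng.uniform(0, 24, size=4))
            o = rng.normal(size=4)
            s = ExpressionSeries("s", "Per3", t, o)
            theta = rng.uniform(0, 2 * np.pi)
            coeffs, cost, _ = inner_linear_solve(theta, {"Per3": s}, {})
            X = np.column_stack([np.cos(OMEGA * t + theta), np.ones(4)])
            beta, *_ = np.linalg.lstsq(X, o, rcond=None)
            assert coeffs["Per3"][0] == pytest.approx(beta[0], abs=1e-10)
            assert coeffs["Per3"][1] == pytest.approx(beta[1], abs=1e-10)
            assert cost == pytest.approx(float(np.sum((o - X @ beta) ** 2)), abs=1e-10)


class TestPeakTimeConventions:
    @pytest.mark.parametrize(
        "theta,convention,expected",
        [
            (np.pi / 2, "paper-formula", 0.0),
            (0.0, "paper-formula", 6.0),
            (0.0, "curve-argmax", 0.0),
        ],
    )
    def test_examples(self, theta, convention, expected):
        assert peak_time_from_theta(theta, convention) == pytest.approx(expected)

    def test_conventions_differ_by_six_hours(self, rng):
        for theta in rng.uniform(-10, 10, size=20):
            d = (peak_time_from_theta(theta, "paper-formula")
                 - peak_time_from_theta(theta, "curve-argmax")) % 24
            assert d == pytest.approx(6.0)

    def test_unknown_convention_errors(self):
        with pytest.raises(ValueError, match="convention"):
            peak_time_from_theta(0.0, "sideways")


class TestGoodnessOfFit:
    def test_cd_equals_direct_recomputation(self, argmax_cfg, rng):
        series = two_gene_pair(peak_h=11.0, noise_sd=0.4, rng=rng)
        fit = fit_shared_phase(series, argmax_cfg)
        assert coefficient_of_determination(fit, series) == pytest.approx(
            fit.cd, abs=1e-12
        )
        assert 0.0 <= fit.cd <= 1.0

    def test_cd_in_unit_interval_under_heavy_noise(self, argmax_cfg, rng):
        for _ in range(20):
            series = two_gene_pair(peak_h=rng.uniform(0, 24), noise_sd=2.0, rng=rng)
            fit = fit_shared_phase(series, argmax_cfg)
            assert 0.0 <= fit.cd <= 1.0


class TestProperties:
    def test_time_shift_equivariance(self, argmax_cfg):
        base_times = np.array([0.0, 8.0, 16.0])
        ref = fit_shared_phase(two_gene_pair(4.0, times=base_times), argmax_cfg)
        for shift in (1.0, 5.5, 13.0):
            # same data relative to the curve, clock shifted by `shift`
            series = two_gene_pair(4.0 + shift, times=base_times + shift)
            fit = fit_shared_phase(series, argmax_cfg)
            assert abs(
                circular_diff_hours(fit.p3pt_h, (ref.p3pt_h + shift) % 24)
            ) < 0.01
            assert fit.cd == pytest.approx(ref.cd, abs=1e-9)

    def test_scale_invariance_of_raw_series(self, argmax_cfg, rng):
        times = np.array([0.0, 8.0, 16.0])
        v1 = np.cos(OMEGA * (times - 7.0)) + rng.normal(0, 0.2, 3)
        v2 = np.cos(OMEGA * (times - 5.0)) + rng.normal(0, 0.2, 3)
        def fit_with_scale(k):
            series = [
                standardize_series(ExpressionSeries("s", "Per3", times, v1 * k)),
                standardize_series(ExpressionSeries("s", "Nr1d2", times, v2)),
            ]
            return fit_shared_phase(series, argmax_cfg)
        a, b = fit_with_scale(1.0), fit_with_scale(37.5)
        assert a.p3pt_h == pytest.approx(b.p3pt_h, abs=1e-9)
        assert a.delta_tau_h == b.delta_tau_h
        assert a.cd == pytest.approx(b.cd, abs=1e-9)

    def test_finer_delta_tau_grid_never_increases_cost(self, argmax_cfg, rng):
        series = two_gene_pair(peak_h=8.2, offset_h=2.33, noise_sd=0.2, rng=rng)
        costs = []
        for step in (0.5, 0.25, 0.1, 0.05):
            cfg = CosineFitConfig(delta_tau_step_h=step, convention="curve-argmax")
            costs.append(fit_shared_phase(series, cfg).cost)
        assert all(b <= a + 1e-10 for a, b in zip(costs, costs[1:]))

    def test_determinism(self, argmax_cfg, rng):
        series = two_gene_pair(peak_h=15.0, noise_sd=0.3, rng=rng)
        a = fit_shared_phase(series, argmax_cfg)
        b = fit_shared_phase(series, argmax_cfg)
        assert a == b


class TestDegenerateAndErrors:
    def test_all_constant_raises(self):
        times = np.array([0.0, 8.0, 16.0])
        series = [
            standardize_series(ExpressionSeries("s", g, times, np.full(3, 2.0)))
            for g in ("Per3", "Nr1d2")
        ]
        with pytest.raises(DegenerateFitError):
            fit_shared_phase(series)

    def test_mismatched_times_rejected(self):
        a = standardize_series(cosine_series("Per3", 5.0, np.array([0.0, 8.0, 16.0])))
        b = standardize_series(cosine_series("Nr1d2", 3.0, np.array([0.0, 7.0, 16.0])))
        with pytest.raises(ValueError, match="sampling times"):
            fit_shared_phase([a, b])

    def test_single_gene_rejected(self):
        a = standardize_series(cosine_series("Per3", 5.0, np.array([0.0, 8.0, 16.0])))
        with pytest.raises(ValueError, match="two genes"):
            fit_shared_phase([a])

    def test_antiphase_flagged(self, argmax_cfg):
        times = np.array([0.0, 8.0, 16.0])
        series = [
            standardize_series(cosine_series("Per3", 5.0, times)),
            # peaks 12 h away from the constrained offset window -> antiphase
            standardize_series(cosine_series("Nr1d2", 15.0, times)),
        ]
        fit = fit_shared_phase(series, argmax_cfg)
        assert fit.antiphase
        assert fit.amplitudes["Per3"] >= 0


class TestBootstrapCi:
    def test_noiseless_ci_is_tight(self, argmax_cfg):
        series = two_gene_pair(peak_h=6.0)
        (lo, hi), width = bootstrap_ci(series, argmax_cfg, n_boot=200, seed=1)
        assert width < 0.05

    def test_fixed_seed_reproducible(self, argmax_cfg, rng):
        series = two_gene_pair(peak_h=6.0, noise_sd=0.3, rng=rng)
        a = bootstrap_ci(series, argmax_cfg, n_boot=100, seed=42)
        b = bootstrap_ci(series, argmax_cfg, n_boot=100, seed=42)
        assert a == b

    def test_ci_contains_point_estimate(self, argmax_cfg, rng):
        series = two_gene_pair(peak_h=2.0, noise_sd=0.3, rng=rng)
        fit = fit_shared_phase(series, argmax_cfg)
        (lo, hi), _ = bootstrap_ci(series, argmax_cfg, n_boot=200, seed=3, fit=fit)
        span = (hi - lo) % 24
        assert (fit.p3pt_h - lo) % 24 <= span + 1e-9

    def test_gaussian_noise_sd_path(self, argmax_cfg, rng):
        series = two_gene_pair(peak_h=6.0, noise_sd=0.3, rng=rng)
        (lo, hi), width = bootstrap_ci(
            series, argmax_cfg, n_boot=200, seed=5, method="gaussian", noise_sd=0.3
        )
        assert 0.1 < width < 24.0
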
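"""Shared-phase constrained cosine fitting of sparse clock-gene expression.

The model
---------
Each gene's standardized expression is fitted to a fixed-period (24 h)
cosine sharing a single phase θ across genes, with a configurable peak-time
offset Δτ between the anchor gene (Per3) and every other gene:

    obs_g(t) ≈ A_g cos(ω t + θ + Δθ_g) + C_g,   ω = 2π/24,
    Δθ_anchor = 0,  Δθ_g = 2π Δτ_g / 24.

For fixed θ and Δθ_g the amplitudes/offsets have an exact per-gene linear
least-squares solution, so the residual cost E(θ) can be profiled over θ
alone. E is multimodal in θ for three-point data, so the global minimum is
located by a dense deterministic θ grid (default 1440 points = 1-minute
resolution) followed by local golden-section refinement; Δτ_g is selected
on its own grid ([1.5, 2.5] h, step 0.1 h by default) to minimize the cost.
A nonlinear conjugate-gradient backend over the full parameter vector is
available as a cross-check (``backend="cg"``).

Peak-time conventions
---------------------
Two conventions for converting θ to the anchor peak time are exposed:
``"paper-formula"`` evaluates 24(0.5π − θ)/(2π) mod 24 (the peak of
sin(ωt + θ)), and ``"curve-argmax"`` evaluates (−24θ/2π) mod 24, the argmax
of the fitted cosine itself. The two differ by exactly 6 h. Interval
parameters referenced to a control band are unaffected by the choice, since
the constant offset cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .circular import PERIOD_H, circular_diff_hours, wrap_hours
from .datamodel import ExpressionSeries, standardize_series

__all__ = [
    "CosineFitConfig",
    "PhaseFitResult",
    "DegenerateFitError",
    "fit_shared_phase",
    "inner_linear_solve",
    "peak_time_from_theta",
    "coefficient_of_determination",
    "bootstrap_ci",
    "estimate_noise_sd",
]

_EPS = 1e-12

CONVENTIONS = ("paper-formula", "curve-argmax")


class DegenerateFitError(RuntimeError):
    """Raised when the data carry no rhythm to fit (all series constant)."""


@dataclass(frozen=True)
class CosineFitConfig:
    """Tuning knobs of the shared-phase cosine fit.

    delta_tau_range_h applies to every non-anchor gene (each optimized
    independently on the same grid); the period is fixed at 24 h.
    """

    period_h: float = PERIOD_H
    delta_tau_range_h: tuple[float, float] = (1.5, 2.5)
    delta_tau_step_h: float = 0.1
    theta_grid_points: int = 1440
    refine_tolerance: float = 1e-10
    convention: str = "paper-formula"

    def __post_init__(self) -> None:
        if self.period_h <= 0:
            raise ValueError("period_h must be positive")
        lo, hi = self.delta_tau_range_h
        if lo > hi:
            raise ValueError("delta_tau_range_h lower bound exceeds upper")
        if self.delta_tau_step_h <= 0:
            raise ValueError("delta_tau_step_h must be positive")
        if self.convention not in CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi / self.period_h

    def delta_tau_grid(self) -> np.ndarray:
        lo, hi = self.delta_tau_range_h
        n = int(round((hi - lo) / self.delta_tau_step_h)) + 1
        return lo + self.delta_tau_step_h * np.arange(n)


@dataclass
class PhaseFitResult:
    """Outcome of one shared-phase fit."""

    subject_id: str
    anchor: str
    genes: tuple[str, ...]
    theta_rad: float
    amplitudes: dict[str, float]
    offsets: dict[str, float]
    delta_tau_h: dict[str, float]
    cost: float
    cd: float
    p3pt_h: float
    convention: str
    ci95_h: tuple[float, float] | None = None
    ci95_width_h: float | None = None
    antiphase: bool = False
    singular: bool = False
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Inner linear solve
# ---------------------------------------------------------------------------

def _profile_cost(phis: np.ndarray, t: np.ndarray, o: np.ndarray, omega: float):
    """Exact conditional least squares for obs = A cos(ωt+φ) + C at each φ.

    Returns (cost, A, C) arrays over the φ grid. A singular design (all
    cosine regressors equal) falls back to A=0, C=mean.
    """
    phis = np.atleast_1d(np.asarray(phis, dtype=float))
    c = np.cos(omega * t[None, :] + phis[:, None])
    cbar = c.mean(axis=1)
    cc = c - cbar[:, None]
    sxx = np.einsum("ij,ij->i", cc, cc)
    obar = o.mean()
    od = o - obar
    soo = float(od @ od)
    sxy = cc @ od
    ok = sxx > _EPS
    a = np.where(ok, sxy / np.where(ok, sxx, 1.0), 0.0)
    cost = soo - np.where(ok, sxy * sxy / np.where(ok, sxx, 1.0), 0.0)
    const = obar - a * cbar
    return np.maximum(cost, 0.0), a, const


def inner_linear_solve(
    theta: float,
    series: Mapping[str, ExpressionSeries],
    delta_theta: Mapping[str, float],
    period_h: float = PERIOD_H,
):
    """Exact (A_g, C_g) minimizing the cost at fixed θ and gene offsets.

    ``delta_theta`` maps gene -> phase offset in radians (0 for the anchor).
    Returns (coeffs, cost, singular) where coeffs maps gene -> (A, C).
    """
    omega = 2.0 * np.pi / period_h
    coeffs: dict[str, tuple[float, float]] = {}
    total = 0.0
    singular = False
    for g, s in series.items():
        phi = theta + delta_theta.get(g, 0.0)
        cost, a, const = _profile_cost(np.array([phi]), s.times_h, s.values, omega)
        c = np.cos(omega * s.times_h + phi)
        if np.ptp(c) <= _EPS:
            singular = True
        coeffs[g] = (float(a[0]), float(const[0]))
        total += float(cost[0])
    return coeffs, total, singular


# ---------------------------------------------------------------------------
# Peak-time conversion
# ---------------------------------------------------------------------------

def peak_time_from_theta(
    theta: float, convention: str = "paper-formula", period_h: float = PERIOD_H
) -> float:
    """Convert the shared phase θ (radians) to a peak clock time in [0, 24).

    "paper-formula": period·(0.5π − θ)/(2π) mod period (sine-peak reading);
    "curve-argmax": (−period·θ/2π) mod period, the cosine-curve argmax.
    """
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    if convention == "paper-formula":
        return float((period_h * (0.5 * np.pi - theta) / (2.0 * np.pi)) % period_h)
    if convention == "curve-argmax":
        return float((-period_h * theta / (2.0 * np.pi)) % period_h)
    raise ValueError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# The fit
# ---------------------------------------------------------------------------

def _prepare(series: Sequence[ExpressionSeries], anchor: str):
    by_gene = {s.gene: (s if s.standardized else standardize_series(s)) for s in series}
    if anchor not in by_gene:
        raise ValueError(f"anchor gene {anchor!r} not among series")
    if len(by_gene) < 2:
        raise ValueError("need at least two genes for a shared-phase fit")
    genes = [anchor] + sorted(g for g in by_gene if g != anchor)
    t0 = by_gene[anchor].times_h
    if t0.size < 3:
        raise ValueError("need at least three time points")
    for g in genes:
        if not np.allclose(by_gene[g].times_h, t0):
            raise ValueError("all genes in one fit must share sampling times")
    if all(by_gene[g].degenerate for g in genes):
        raise DegenerateFitError(
            "all gene series are constant: no circadian rhythm to fit "
            f"(subject {by_gene[anchor].subject_id!r})"
        )
    return by_gene, genes, t0


def fit_shared_phase(
    series: Sequence[ExpressionSeries],
    cfg: CosineFitConfig | None = None,
    anchor: str = "Per3",
    backend: str = "grid",
) -> PhaseFitResult:
    """Globally minimize the shared-phase cosine cost.

    ``series`` holds one (standardized or raw) series per gene on identical
    sampling times; raw series are standardized internally. The grid backend
    is deterministic: θ on a dense grid with exact inner least squares and
    golden-section refinement, Δτ per non-anchor gene selected on its grid;
    ties in cost resolve to the smaller θ. ``backend="cg"`` instead runs
    nonlinear conjugate-gradient minimization over {θ, A, C} per Δτ
    combination.
    """
    cfg = cfg or CosineFitConfig()
    by_gene, genes, t = _prepare(series, anchor)
    omega = cfg.omega
    if backend == "cg":
        return _fit_cg(by_gene, genes, t, cfg, anchor)
    if backend != "grid":
        raise ValueError(f"unknown backend {backend!r}")

    n_grid = cfg.theta_grid_points
    thetas = 2.0 * np.pi * np.arange(n_grid) / n_grid
    dtaus = cfg.delta_tau_grid()

    anchor_cost, _, _ = _profile_cost(thetas, t, by_gene[anchor].values, omega)
    total = anchor_cost.copy()
    best_dtau_idx: dict[str, np.ndarray] = {}
    for g in genes[1:]:
        o = by_gene[g].values
        costs = np.empty((dtaus.size, n_grid))
        for k, dt in enumerate(dtaus):
            costs[k], _, _ = _profile_cost(
                thetas + 2.0 * np.pi * dt / cfg.period_h, t, o, omega
            )
        idx = np.argmin(costs, axis=0)
        best_dtau_idx[g] = idx
        total += costs[idx, np.arange(n_grid)]

    i_best = int(np.argmin(total))  # first minimum -> smallest θ on ties
    theta0 = float(thetas[i_best])
    dtau_sel = {g: float(dtaus[best_dtau_idx[g][i_best]]) for g in genes[1:]}
    dtheta = {g: 2.0 * np.pi * dtau_sel[g] / cfg.period_h for g in genes[1:]}
    dtheta[anchor] = 0.0

    def cost_at(th: float) -> float:
        return _total_cost(th, by_gene, genes, dtheta, omega)

    step = 2.0 * np.pi / n_grid
    res = optimize.minimize_scalar(
        cost_at, bounds=(theta0 - step, theta0 + step), method="bounded",
        options={"xatol": 1e-9},
    )
    theta = float(res.x) if res.fun <= total[i_best] + cfg.refine_tolerance else theta0
    theta %= 2.0 * np.pi

    return _finalize(by_gene, genes, theta, dtheta, dtau_sel, cfg, anchor)


def _total_cost(theta, by_gene, genes, dtheta, omega) -> float:
    tot = 0.0
    for g in genes:
        s = by_gene[g]
        cost, _, _ = _profile_cost(
            np.array([theta + dtheta[g]]), s.times_h, s.values, omega
        )
        tot += float(cost[0])
    return tot


def _finalize(by_gene, genes, theta, dtheta, dtau_sel, cfg, anchor) -> PhaseFitResult:
    coeffs, cost, singular = inner_linear_solve(theta, by_gene, dtheta, cfg.period_h)
    # canonicalize: anchor amplitude non-negative via joint θ -> θ+π flip
    if coeffs[anchor][0] < 0:
        theta = (theta + np.pi) % (2.0 * np.pi)
        coeffs, cost, singular = inner_linear_solve(theta, by_gene, dtheta, cfg.period_h)
    antiphase = any(coeffs[g][0] < 0 for g in genes if g != anchor)

    sst = sum(
        float(np.sum((by_gene[g].values - by_gene[g].values.mean()) ** 2))
        for g in genes
    )
    degenerate = sst <= _EPS
    cd = 0.0 if degenerate else float(np.clip(1.0 - cost / sst, 0.0, 1.0))

    return PhaseFitResult(
        subject_id=by_gene[anchor].subject_id,
        anchor=anchor,
        genes=tuple(genes),
        theta_rad=float(theta),
        amplitudes={g: coeffs[g][0] for g in genes},
        offsets={g: coeffs[g][1] for g in genes},
        delta_tau_h=dict(dtau_sel),
        cost=float(cost),
        cd=cd,
        p3pt_h=peak_time_from_theta(theta, cfg.convention, cfg.period_h),
        convention=cfg.convention,
        antiphase=antiphase,
        singular=singular,
        degenerate=degenerate,
    )


def _fit_cg(by_gene, genes, t, cfg: CosineFitConfig, anchor) -> PhaseFitResult:
    """Conjugate-gradient minimization over {θ, A_g, C_g} per Δτ combination."""
    from itertools import product

    omega = cfg.omega
    dtaus = cfg.delta_tau_grid()
    non_anchor = genes[1:]
    best = None
    coarse = 2.0 * np.pi * np.arange(48) / 48

    def pack_cost(params, dtheta):
        th = params[0]
        tot = 0.0
        for j, g in enumerate(genes):
            a, c0 = params[1 + 2 * j], params[2 + 2 * j]
            pred = a * np.cos(omega * t + th + dtheta[g]) + c0
            tot += float(np.sum((by_gene[g].values - pred) ** 2))
        return tot

    for combo in product(dtaus, repeat=len(non_anchor)):
        dtheta = {anchor: 0.0}
        for g, dt in zip(non_anchor, combo):
            dtheta[g] = 2.0 * np.pi * dt / cfg.period_h
        # coarse profile over θ to seed CG near the basin of the global min
        c_costs = [_total_cost(th, by_gene, genes, dtheta, omega) for th in coarse]
        th0 = float(coarse[int(np.argmin(c_costs))])
        coeffs0, _, _ = inner_linear_solve(th0, by_gene, dtheta, cfg.period_h)
        x0 = [th0]
        for g in genes:
            x0.extend(coeffs0[g])
        res = optimize.minimize(pack_cost, np.array(x0), args=(dtheta,),
                                method="CG", options={"gtol": 1e-10})
        if best is None or res.fun < best[0]:
            best = (float(res.fun), float(res.x[0]) % (2.0 * np.pi),
                    dict(zip(non_anchor, map(float, combo))), dtheta)

    _, theta, dtau_sel, dtheta = best
    return _finalize(by_gene, genes, theta, dtheta, dtau_sel, cfg, anchor)


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

def coefficient_of_determination(
    fit: PhaseFitResult, series: Sequence[ExpressionSeries]
) -> float:
    """Pooled 1 − SSE/SST across fitted genes (SST about per-gene means).

    Always in [0, 1] because the constant model is nested in the cosine
    model; constant data (SST = 0) is defined as 0.
    """
    by_gene = {s.gene: (s if s.standardized else standardize_series(s)) for s in series}
    omega = 2.0 * np.pi / PERIOD_H
    sse = 0.0
    sst = 0.0
    for g in fit.genes:
        s = by_gene[g]
        dth = 0.0 if g == fit.anchor else 2.0 * np.pi * fit.delta_tau_h[g] / PERIOD_H
        pred = fit.amplitudes[g] * np.cos(omega * s.times_h + fit.theta_rad + dth) \
            + fit.offsets[g]
        sse += float(np.sum((s.values - pred) ** 2))
        sst += float(np.sum((s.values - s.values.mean()) ** 2))
    if sst <= _EPS:
        return 0.0
    return float(np.clip(1.0 - sse / sst, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Bootstrap confidence interval
# ---------------------------------------------------------------------------

def _fit_peaks_many(
    t: np.ndarray,
    obs: dict[str, np.ndarray],
    cfg: CosineFitConfig,
    anchor: str,
    genes: Sequence[str],
    n_grid: int = 720,
) -> np.ndarray:
    """Vectorized grid fits of B datasets sharing sampling times.

    ``obs[gene]`` is (B, n). Returns peak times (hours) per dataset at grid
    resolution (no golden-section refinement; 720 points = 2 min, far below
    bootstrap spread).
    """
    omega = cfg.omega
    thetas = 2.0 * np.pi * np.arange(n_grid) / n_grid
    dtaus = cfg.delta_tau_grid()
    B = obs[anchor].shape[0]

    def gene_cost_matrix(o: np.ndarray, shift: float):
        c = np.cos(omega * t[None, :] + (thetas + shift)[:, None])  # (N, n)
        cbar = c.mean(axis=1)
        cc = c - cbar[:, None]
        sxx = np.einsum("ij,ij->i", cc, cc)
        od = o - o.mean(axis=1, keepdims=True)  # (B, n)
        soo = np.einsum("bj,bj->b", od, od)
        sxy = od @ cc.T  # (B, N)
        ok = sxx > _EPS
        gain = np.where(ok, 1.0 / np.where(ok, sxx, 1.0), 0.0)
        cost = soo[:, None] - sxy * sxy * gain[None, :]
        return cost, sxy * gain[None, :]  # cost and amplitude A

    total, a_anchor = gene_cost_matrix(obs[anchor], 0.0)
    for g in genes:
        if g == anchor:
            continue
        per_dtau = np.empty((dtaus.size, B, n_grid))
        for k, dt in enumerate(dtaus):
            per_dtau[k], _ = gene_cost_matrix(obs[g], 2.0 * np.pi * dt / cfg.period_h)
        total = total + per_dtau.min(axis=0)

    i_best = np.argmin(total, axis=1)
    theta = thetas[i_best]
    a0 = a_anchor[np.arange(B), i_best]
    theta = np.where(a0 < 0, (theta + np.pi) % (2 * np.pi), theta)
    if cfg.convention == "paper-formula":
        peaks = (cfg.period_h * (0.5 * np.pi - theta) / (2 * np.pi)) % cfg.period_h
    else:
        peaks = (-cfg.period_h * theta / (2 * np.pi)) % cfg.period_h
    return peaks


def estimate_noise_sd(
    measurements,
    subject_id: str,
    gene: str,
    scale: float = 1.0,
) -> float | None:
    """Pure-error SD of a collapsed (replicate-mean) time point.

    Pools the within-time replicate variance of reference-normalized values
    and returns the standard error of the per-time mean, divided by
    ``scale`` (the gene's standardization scale) so it lives on the
    standardized data scale the fit consumes. Returns None when no time
    point carries replication.
    """
    from .datamodel import normalize_to_reference

    by_time: dict[float, list[float]] = {}
    for m in measurements:
        if m.subject_id == subject_id and m.gene == gene:
            by_time.setdefault(m.time_h, []).append(normalize_to_reference(m))
    var_means = [
        np.var(v, ddof=1) / len(v) for v in by_time.values() if len(v) >= 2
    ]
    if not var_means:
        return None
    return float(np.sqrt(np.mean(var_means)) / scale)


def bootstrap_ci(
    series: Sequence[ExpressionSeries],
    cfg: CosineFitConfig | None = None,
    anchor: str = "Per3",
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    method: str = "resample",
    noise_sd: float | Mapping[str, float] | None = None,
    fit: PhaseFitResult | None = None,
) -> tuple[tuple[float, float], float]:
    """Parametric bootstrap 95% CI of the anchor peak time.

    Each bootstrap dataset is the fitted curve plus synthetic noise, refitted
    on a θ grid; circular 2.5/97.5 percentiles of the bootstrap peaks around
    the point estimate form the interval. Deterministic for a fixed seed.

    Noise models:

    * ``method="gaussian"`` with ``noise_sd`` (scalar or per-gene mapping, on
      the standardized scale) — the recommended path when the noise level is
      estimable, e.g. from replicate scatter via :func:`estimate_noise_sd`.
    * ``method="gaussian"`` without ``noise_sd`` — Gaussian with the
      dof-corrected residual SD.
    * ``method="resample"`` — residual resampling with replacement, residuals
      inflated by sqrt(n_obs/dof). With the minimal two-gene three-point
      design the model has nearly as many parameters as observations, so
      residual-based noise estimates are anti-conservative there; prefer the
      replicate-based Gaussian path for that design.

    Returns ((lower_h, upper_h), width_h); a degenerate fit yields the full
    circle (0, 24) with width 24.
    """
    cfg = cfg or CosineFitConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    by_gene, genes, t = _prepare(series, anchor)
    if fit is None:
        fit = fit_shared_phase([by_gene[g] for g in genes], cfg, anchor=anchor)
    if fit.degenerate:
        return (0.0, PERIOD_H), PERIOD_H
    if method not in ("resample", "gaussian"):
        raise ValueError(f"unknown bootstrap method {method!r}")

    omega = cfg.omega
    preds: dict[str, np.ndarray] = {}
    resid_all = []
    for g in genes:
        dth = 0.0 if g == anchor else 2.0 * np.pi * fit.delta_tau_h[g] / cfg.period_h
        preds[g] = (
            fit.amplitudes[g] * np.cos(omega * t + fit.theta_rad + dth) + fit.offsets[g]
        )
        resid_all.append(by_gene[g].values - preds[g])
    resid = np.concatenate(resid_all)
    # θ, (A, C) per gene, Δτ per non-anchor gene
    n_par = 1 + 2 * len(genes) + (len(genes) - 1)
    dof = max(resid.size - n_par, 1)
    inflation = np.sqrt(resid.size / dof)

    obs_boot: dict[str, np.ndarray] = {}
    for g in genes:
        if method == "gaussian":
            if noise_sd is None:
                sd = float(np.sqrt(resid @ resid / dof))
            elif isinstance(noise_sd, Mapping):
                sd = float(noise_sd[g])
            else:
                sd = float(noise_sd)
            draws = rng.normal(0.0, sd, size=(n_boot, t.size))
        else:
            draws = rng.choice(resid * inflation, size=(n_boot, t.size), replace=True)
        obs_boot[g] = preds[g][None, :] + draws

    peaks = _fit_peaks_many(t, obs_boot, cfg, anchor, genes)
    dev = circular_diff_hours(peaks, fit.p3pt_h)
    lo, hi = np.percentile(dev, [2.5, 97.5])
    width = float(hi - lo)
    ci = (float(wrap_hours(fit.p3pt_h + lo)), float(wrap_hours(fit.p3pt_h + hi)))
    return ci, width
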
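"""Mixed-effects monotone progression model with latent time shifts.

Short-term longitudinal z-score series from many subjects are stitched onto a
common latent "disease time" axis. Each subject j contributes visits at ages
t, mapped to disease time via a per-subject shift d_j (tau = t - d_j); each
region v follows a population-level monotone trajectory f_v plus a
per-subject scalar offset and Gaussian noise:

    z_vjk = f_v(t_jk - d_j) + b_jv + eps,   eps ~ N(0, noise_sd_v^2).

The fixed effect is a Gaussian-process regression in weight space: the
trajectory derivative is a non-negative combination of radial-basis bumps,

    f_v'(tau) = sum_m w_vm phi_m(tau),  w_vm >= 0,

so f_v (the integral, plus a free intercept) is monotone non-decreasing by
construction -- the identifiability device of progression models in the
atrophy orientation. Fitting alternates (a) per-region bound-constrained
ridge least squares for the trajectory weights with (b) per-subject 1-D
search for the shifts, softly bounded by twice the kernel length-scale and
anchored to mean zero. Posterior uncertainty on f' comes from a Laplace
approximation on the active weights, propagated by sampling.

Downstream quantities: the cohort maximal rate per region Y_v = max_tau
f_v'(tau), and individual rates Y_v^j = f_v'(tau_j), the derivative at the
subject's anchored mean age.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear
from scipy.special import ndtr

from .cohort import ZScoreCohort
from .errors import DataError

log = logging.getLogger(__name__)

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass
class ProgressionConfig:
    """Tunable settings for :func:`fit_progression`.

    length_scale
        RBF kernel length-scale l (disease-time years). Shifts are bounded to
        [-2l, 2l]. ``None`` -> span of centered ages / 4.
    n_basis
        Number of derivative basis bumps across the grid span.
    basis_width_factor
        Bump width as a multiple of the basis spacing.
    grid_size
        Points in the disease-time grid.
    ridge
        L2 penalty on derivative weights (not the intercept).
    max_outer / tol
        Alternating-optimization iteration cap and relative tolerance on the
        penalized residual sum of squares.
    n_draws
        Posterior samples of f' used for all downstream uncertainty.
    offset_shrinkage
        Pseudo-visits added to the denominator of the per-subject offset
        estimate; larger values shrink random intercepts toward zero.
    shift_grid
        Grid resolution of the per-subject shift search.
    """

    length_scale: float | None = None
    n_basis: int = 25
    basis_width_factor: float = 2.0
    grid_size: int = 200
    ridge: float = 1e-4
    max_outer: int = 40
    tol: float = 1e-4
    n_draws: int = 100
    offset_shrinkage: float = 4.0
    shift_grid: int = 81
    monotone_tol: float = 1e-6


@dataclass
class ProgressionModel:
    """Fitted trajectories, shifts, and posterior derivative samples."""

    tau_grid: np.ndarray
    f_mean: np.ndarray          # (V, G)
    f_sd: np.ndarray            # (V, G)
    fprime_mean: np.ndarray     # (V, G)
    fprime_sd: np.ndarray       # (V, G)
    fprime_draws: np.ndarray = field(repr=False)   # (S, V, G)
    kernel: dict = field(default_factory=dict)
    noise_sd: np.ndarray = field(default_factory=lambda: np.array([]))
    shifts: pd.Series = field(default_factory=pd.Series)
    subject_anchor: pd.Series = field(default_factory=pd.Series)
    offsets: pd.DataFrame = field(default_factory=pd.DataFrame)
    random_effect_sd: float = 0.0
    regions: list = field(default_factory=list)
    age_center: float = 0.0
    converged: bool = True
    objective_history: list = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return self.f_mean.shape[0]

    def fprime_at(self, tau, draws: bool = False):
        """Interpolate the derivative posterior mean (or all draws) at tau.

        Values outside the grid evaluate at the nearest grid end.
        """
        tau = np.atleast_1d(np.asarray(tau, float))
        lo, hi = self.tau_grid[0], self.tau_grid[-1]
        if (tau < lo).any() or (tau > hi).any():
            log.warning("anchor(s) outside the disease-time grid; clamped to ends")
            tau = np.clip(tau, lo, hi)
        source = self.fprime_draws if draws else self.fprime_mean[None]
        out = np.empty(source.shape[:-1] + (len(tau),))
        for s in range(source.shape[0]):
            for v in range(source.shape[1]):
                out[s, v] = np.interp(tau, self.tau_grid, source[s, v])
        return out if draws else out[0]

    def save(self, prefix) -> None:
        """JSON header + NPZ arrays; round-trips exactly."""
        prefix = str(prefix)
        header = {
            "kernel": self.kernel,
            "regions": list(self.regions),
            "subjects": list(self.shifts.index),
            "shifts": [float(x) for x in self.shifts],
            "subject_anchor": [float(x) for x in self.subject_anchor],
            "random_effect_sd": float(self.random_effect_sd),
            "age_center": float(self.age_center),
            "converged": bool(self.converged),
            "objective_history": [float(x) for x in self.objective_history],
        }
        with open(prefix + ".json", "w") as fh:
            json.dump(header, fh, indent=1)
        np.savez(
            prefix + ".npz",
            tau_grid=self.tau_grid,
            f_mean=self.f_mean,
            f_sd=self.f_sd,
            fprime_mean=self.fprime_mean,
            fprime_sd=self.fprime_sd,
            fprime_draws=self.fprime_draws,
            noise_sd=self.noise_sd,
            offsets=self.offsets.to_numpy(),
        )

    @classmethod
    def load(cls, prefix) -> "ProgressionModel":
        prefix = str(prefix)
        with open(prefix + ".json") as fh:
            header = json.load(fh)
        arrays = np.load(prefix + ".npz")
        subjects = header["subjects"]
        return cls(
            tau_grid=arrays["tau_grid"],
            f_mean=arrays["f_mean"],
            f_sd=arrays["f_sd"],
            fprime_mean=arrays["fprime_mean"],
            fprime_sd=arrays["fprime_sd"],
            fprime_draws=arrays["fprime_draws"],
            kernel=header["kernel"],
            noise_sd=arrays["noise_sd"],
            shifts=pd.Series(header["shifts"], index=subjects),
            subject_anchor=pd.Series(header["subject_anchor"], index=subjects),
            offsets=pd.DataFrame(arrays["offsets"], index=subjects, columns=header["regions"]),
            random_effect_sd=header["random_effect_sd"],
            regions=header["regions"],
            age_center=header["age_center"],
            converged=header["converged"],
            objective_history=header["objective_history"],
        )


@dataclass
class RateVector:
    """Cohort maximal rates (Y) and/or individual rates (Yj), z-units per year."""

    Y: pd.Series | None = None
    Y_sd: pd.Series | None = None
    Y_draws: np.ndarray | None = None      # (S, V)
    Yj: pd.DataFrame | None = None         # subjects x regions


def _basis(tau, centers, width):
    """Gaussian derivative bumps phi_m(tau), shape (len(tau), M)."""
    t = np.asarray(tau, float)[:, None]
    return np.exp(-0.5 * ((t - centers[None, :]) / width) ** 2)


def _basis_integral(tau, centers, width):
    """Antiderivatives B_m(tau) = integral of phi_m, via the normal CDF."""
    t = np.asarray(tau, float)[:, None]
    return width * _SQRT2PI * ndtr((t - centers[None, :]) / width)


def _fit_region(tau_pts, y, centers, width, ridge):
    """Bound-constrained ridge LS: y ~ c + B(tau) w, w >= 0. Returns (c, w, rss)."""
    B = _basis_integral(tau_pts, centers, width)
    n, m = B.shape
    A = np.hstack([np.ones((n, 1)), B])
    A_aug = np.vstack([A, np.hstack([np.zeros((m, 1)), np.sqrt(ridge) * np.eye(m)])])
    y_aug = np.concatenate([y, np.zeros(m)])
    lb = np.concatenate([[-np.inf], np.zeros(m)])
    ub = np.full(m + 1, np.inf)
    res = lsq_linear(A_aug, y_aug, bounds=(lb, ub), tol=1e-12, lsmr_tol="auto")
    theta = res.x
    resid = y - A @ theta
    return theta[0], theta[1:], float(resid @ resid)


def fit_progression(
    z: ZScoreCohort, config: ProgressionConfig | None = None, seed: int = 0
) -> ProgressionModel:
    """Fit the monotone mixed-effects progression model.

    Alternates trajectory fits (given shifts) with shift updates (given
    trajectories), trajectories first, until the penalized RSS stabilizes.
    Deterministic for a given seed; the seed only drives the posterior draws.
    """
    cfg = config or ProgressionConfig()
    subjects = z.subjects
    if len(subjects) < 2:
        raise DataError("need at least 2 subjects to fit a progression model")
    regions = z.regions
    V = len(regions)

    Zmat = z.volumes.to_numpy(float)            # (N, V)
    ages = z.volumes.index.get_level_values(1).to_numpy(float)
    subj_of_row = z.volumes.index.get_level_values(0).to_numpy()
    if np.isnan(Zmat).any():
        raise DataError("NaN z-scores not supported by the progression fit")
    sub_index = {s: np.where(subj_of_row == s)[0] for s in subjects}
    n_visits = {s: len(ix) for s, ix in sub_index.items()}
    if max(n_visits.values()) == 1:
        log.warning("all subjects have a single visit; shifts identified only "
                    "cross-sectionally")

    age_center = float(ages.mean())
    t = ages - age_center
    span = float(t.max() - t.min())
    l = cfg.length_scale if cfg.length_scale is not None else max(span / 4.0, 1e-3)
    lo, hi = t.min() - 2 * l, t.max() + 2 * l
    tau_grid = np.linspace(lo, hi, cfg.grid_size)

    def _centers_for(tau_pts):
        # basis bumps only where data live: bumps far outside the observed
        # span are collinear with the intercept and produce spurious slopes
        c_lo, c_hi = float(tau_pts.min()), float(tau_pts.max())
        if c_hi - c_lo <= 0:
            c_lo, c_hi = c_lo - 1.0, c_hi + 1.0
        centers = np.linspace(c_lo, c_hi, cfg.n_basis)
        width = cfg.basis_width_factor * (centers[1] - centers[0])
        return centers, width

    d = pd.Series(0.0, index=subjects)          # shifts
    offsets = np.zeros((len(subjects), V))
    subj_pos = {s: i for i, s in enumerate(subjects)}
    row_subj_idx = np.array([subj_pos[s] for s in subj_of_row])

    shift_bound = 2.0 * l
    shift_candidates = np.linspace(-shift_bound, shift_bound, cfg.shift_grid)

    intercepts = np.zeros(V)
    weights = np.zeros((V, cfg.n_basis))
    history, converged = [], False
    for outer in range(cfg.max_outer):
        tau_pts = t - d.loc[subj_of_row].to_numpy()
        centers, width = _centers_for(tau_pts)
        target = Zmat - offsets[row_subj_idx]
        rss_total = 0.0
        for v in range(V):
            c, w, rss = _fit_region(tau_pts, target[:, v], centers, width, cfg.ridge)
            intercepts[v], weights[v] = c, w
            rss_total += rss

        # random intercepts: shrunken per-subject mean residual per region
        f_grid = intercepts[:, None] + weights @ _basis_integral(tau_grid, centers, width).T
        fitted = np.empty_like(Zmat)
        for v in range(V):
            fitted[:, v] = np.interp(tau_pts, tau_grid, f_grid[v])
        resid = Zmat - fitted
        for s in subjects:
            ix = sub_index[s]
            k = len(ix)
            offsets[subj_pos[s]] = resid[ix].sum(axis=0) / (k + cfg.offset_shrinkage)

        # shift update: per-subject 1-D grid search + parabolic refinement;
        # each candidate is scored with its own optimal shrunken offsets so
        # the random intercepts cannot anchor the shift at its previous value
        kappa = cfg.offset_shrinkage
        for s in subjects:
            ix = sub_index[s]
            k = len(ix)
            cand_tau = t[ix][None, :] - shift_candidates[:, None]   # (C, K)
            sse = np.zeros(len(shift_candidates))
            for v in range(V):
                pred = np.interp(cand_tau, tau_grid, f_grid[v])
                r = Zmat[ix, v][None, :] - pred                      # (C, K)
                b = r.sum(axis=1) / (k + kappa)
                sse += ((r - b[:, None]) ** 2).sum(axis=1) + kappa * b ** 2
            best = int(np.argmin(sse))
            d_best = shift_candidates[best]
            if 0 < best < len(shift_candidates) - 1:
                y0, y1, y2 = sse[best - 1], sse[best], sse[best + 1]
                denom = y0 - 2 * y1 + y2
                if denom > 0:
                    step = shift_candidates[1] - shift_candidates[0]
                    d_best += 0.5 * step * (y0 - y2) / denom
            d.loc[s] = float(np.clip(d_best, -shift_bound, shift_bound))
        d -= d.mean()   # identifiability anchor
        d = d.clip(-shift_bound, shift_bound)

        # refresh offsets at the accepted shifts
        tau_new = t - d.loc[subj_of_row].to_numpy()
        for v in range(V):
            fitted[:, v] = np.interp(tau_new, tau_grid, f_grid[v])
        resid = Zmat - fitted
        for s in subjects:
            ix = sub_index[s]
            offsets[subj_pos[s]] = resid[ix].sum(axis=0) / (len(ix) + kappa)

        penalty = cfg.ridge * float((weights ** 2).sum())
        objective = rss_total + penalty
        history.append(objective)
        if outer > 0 and abs(history[-2] - objective) <= cfg.tol * max(history[-2], 1e-12):
            converged = True
            break
    if not converged:
        log.warning("progression fit did not converge in %d outer iterations", cfg.max_outer)

    # final refit with converged shifts
    tau_pts = t - d.loc[subj_of_row].to_numpy()
    centers, width = _centers_for(tau_pts)
    target = Zmat - offsets[row_subj_idx]
    noise_sd = np.zeros(V)
    n_rows = Zmat.shape[0]
    for v in range(V):
        c, w, rss = _fit_region(tau_pts, target[:, v], centers, width, cfg.ridge)
        intercepts[v], weights[v] = c, w
        noise_sd[v] = np.sqrt(rss / max(n_rows - 1, 1))

    # posterior draws: Laplace on the active weight set, clipped to >= 0
    rng = np.random.default_rng(seed)
    B_grid = _basis_integral(tau_grid, centers, width)
    P_grid = _basis(tau_grid, centers, width)
    B_pts = _basis_integral(tau_pts, centers, width)
    S = cfg.n_draws
    G = cfg.grid_size
    f_draws = np.empty((S, V, G))
    fprime_draws = np.empty((S, V, G))
    for v in range(V):
        active = np.where(weights[v] > 1e-12)[0]
        A = np.hstack([np.ones((n_rows, 1)), B_pts[:, active]])
        prec = A.T @ A + cfg.ridge * np.eye(A.shape[1])
        cov = noise_sd[v] ** 2 * np.linalg.inv(prec)
        mean_theta = np.concatenate([[intercepts[v]], weights[v][active]])
        # svd handles the exactly singular (noise-free) covariance case
        draws = rng.multivariate_normal(mean_theta, cov, size=S, method="svd")
        w_draws = np.clip(draws[:, 1:], 0.0, None)
        f_draws[:, v, :] = draws[:, :1] + w_draws @ B_grid[:, active].T
        fprime_draws[:, v, :] = w_draws @ P_grid[:, active].T

    f_mean = intercepts[:, None] + weights @ B_grid.T
    fprime_mean = weights @ P_grid.T
    anchor = pd.Series(
        {s: float(t[sub_index[s]].mean() - d.loc[s]) for s in subjects}
    )
    return ProgressionModel(
        tau_grid=tau_grid,
        f_mean=f_mean,
        f_sd=f_draws.std(axis=0),
        fprime_mean=fprime_mean,
        fprime_sd=fprime_draws.std(axis=0),
        fprime_draws=fprime_draws,
        kernel={"length_scale": float(l), "variance": float(np.var(Zmat)),
                "n_basis": cfg.n_basis, "basis_width": float(width)},
        noise_sd=noise_sd,
        shifts=d,
        subject_anchor=anchor,
        offsets=pd.DataFrame(offsets, index=subjects, columns=regions),
        random_effect_sd=float(offsets.std()),
        regions=list(regions),
        age_center=age_center,
        converged=converged,
        objective_history=history,
    )


def max_rates(model: ProgressionModel) -> RateVector:
    """Cohort maximal rates: Y_v = max over the grid of the derivative mean.

    Uncertainty is the sd of the per-draw maxima across the posterior samples.
    """
    Y = model.fprime_mean.max(axis=1)
    Y_draws = model.fprime_draws.max(axis=2)           # (S, V)
    return RateVector(
        Y=pd.Series(Y, index=model.regions),
        Y_sd=pd.Series(Y_draws.std(axis=0), index=model.regions),
        Y_draws=Y_draws,
    )


def individual_rates(model: ProgressionModel, z: ZScoreCohort | None = None) -> RateVector:
    """Individual rates: the derivative evaluated at each subject's anchored
    mean age (tau_j = mean visit age - d_j), clipped at zero from below."""
    subjects = list(model.shifts.index)
    if z is not None:
        missing = [s for s in z.subjects if s not in set(subjects)]
        if missing:
            log.warning("%d subject(s) absent from the fitted model; skipped", len(missing))
        subjects = [s for s in subjects if s in set(z.subjects)]
    taus = model.subject_anchor.loc[subjects].to_numpy(float)
    vals = model.fprime_at(taus)                       # (V, n_subjects)
    Yj = pd.DataFrame(np.clip(vals.T, 0.0, None), index=subjects, columns=model.regions)
    return RateVector(Yj=Yj)
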
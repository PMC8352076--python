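"""Global multiexponential refinement and IRF parameter estimation.

The sparse pipeline ends with a plain (unpenalized) global multiexponential
fit initialized from the discretized solution: penalized estimates shrink
large amplitudes by construction, and the refinement removes that bias.  The
fit uses variable projection — the per-wavelength amplitudes are eliminated
by linear least squares at every trial set of time constants, so the outer
optimizer only sees the log time constants.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.optimize import least_squares

from .dataset import KineticDataset
from .design import IRFModel, TauGrid, _exp_conv_gauss, _step_conv_gauss, build_designs
from .discretize import Feature, FeatureSet
from .model_selection import SelectionResult, bayes_opt
from .solver import ADMMSettings, genp_objective, solve_genp

__all__ = ["ExpFitResult", "global_exp_fit", "estimate_irf"]


@dataclass
class ExpFitResult:
    """Refined components, final mean squared error, convergence flag."""

    features: FeatureSet
    mse: float
    converged: bool
    initial_mse: float = np.nan
    n_evaluations: int = 0


def _exp_design(times, taus, has_const, irf: IRFModel | None, wavelength):
    """m x K design of exponential (or IRF-convolved) columns at the given
    taus, plus a trailing constant column when requested."""
    cols = []
    for tau in taus:
        if irf is None:
            cols.append(np.exp(-times / tau))
        else:
            cols.append(_exp_conv_gauss(times, tau, float(irf.t0(wavelength)), irf.sigma))
    if has_const:
        if irf is None:
            cols.append(np.ones_like(times))
        else:
            cols.append(_step_conv_gauss(times, float(irf.t0(wavelength)), irf.sigma))
    return np.column_stack(cols)


def _project_amplitudes(dataset: KineticDataset, taus, has_const, irf):
    """Variable projection: per wavelength, amplitudes by least squares.

    Returns (amps of shape (K(+1), p), residual matrix, sse)."""
    if irf is None:
        A = _exp_design(dataset.times, taus, has_const, None, None)
        amps, *_ = np.linalg.lstsq(A, dataset.signal, rcond=None)
        resid = dataset.signal - A @ amps
        return amps, resid, float(np.sum(resid**2))
    amps = []
    resid = np.empty_like(dataset.signal)
    for k, w in enumerate(dataset.wavelengths):
        A = _exp_design(dataset.times, taus, has_const, irf, w)
        a, *_ = np.linalg.lstsq(A, dataset.signal[:, k], rcond=None)
        amps.append(a)
        resid[:, k] = dataset.signal[:, k] - A @ a
    return np.column_stack(amps), resid, float(np.sum(resid**2))


def global_exp_fit(
    dataset: KineticDataset,
    init: FeatureSet,
    irf: IRFModel | None = None,
    max_nfev: int = 400,
    xtol: float = 1e-12,
    collapse_decades: float = 1e-3,
) -> ExpFitResult:
    """Refine discretized components by a global multiexponential fit.

    Minimizes the total squared residual over the log time constants, with
    per-wavelength amplitudes eliminated by linear least squares (variable
    projection).  A feature at tau = inf is carried as a constant column and
    refined in amplitude only.  Time constants that collapse onto each other
    (closer than ``collapse_decades`` decades) are merged and the fit
    restarted once.  The returned fit is never worse than the
    initialization.
    """
    finite = [f for f in init if np.isfinite(f.tau)]
    has_const = any(np.isinf(f.tau) for f in init)
    if not finite and not has_const:
        raise ValueError("init must contain at least one feature")
    taus0 = np.array(sorted(f.tau for f in finite))
    if np.any(np.diff(np.log10(taus0)) <= 0):
        raise ValueError("initial taus must be distinct")
    _, _, sse0 = _project_amplitudes(dataset, taus0, has_const, irf)
    cells = dataset.signal.size

    def run(taus_init):
        if taus_init.size == 0:
            # nothing nonlinear left: amplitude-only fit
            return taus_init, 1, True

        def residual(theta):
            _, resid, _ = _project_amplitudes(dataset, 10.0**theta, has_const, irf)
            return resid.ravel()

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = least_squares(
                residual,
                np.log10(taus_init),
                method="trf",
                max_nfev=max_nfev,
                xtol=xtol,
                ftol=1e-14,
                gtol=1e-14,
            )
        return np.sort(10.0**out.x), out.nfev, out.status > 0

    taus, nfev, ok = run(taus0)
    # merge collapsed time constants and restart once
    if taus.size > 1 and np.any(np.diff(np.log10(taus)) < collapse_decades):
        warnings.warn("time constants collapsed during refinement; merging",
                      RuntimeWarning)
        keep = np.concatenate(
            [[True], np.diff(np.log10(taus)) >= collapse_decades]
        )
        taus, nfev2, ok = run(taus[keep])
        nfev += nfev2
    amps, _, sse = _project_amplitudes(dataset, taus, has_const, irf)
    converged = bool(ok)
    # refinement must never worsen the fit (beyond round-off: merging a
    # redundant collapsed pair may shift a numerically-zero SSE)
    if sse > sse0 * (1 + 1e-9) + 1e-12 * float(np.mean(dataset.signal**2)):
        taus = taus0
        amps, _, sse = _project_amplitudes(dataset, taus, has_const, irf)
        converged = False
    feats = [
        Feature(tau=float(tau), dads=amps[i].copy()) for i, tau in enumerate(taus)
    ]
    if has_const:
        feats.append(Feature(tau=np.inf, dads=amps[-1].copy(), flags=("constant",)))
    return ExpFitResult(
        features=FeatureSet(feats),
        mse=sse / cells,
        converged=converged,
        initial_mse=sse0 / cells,
        n_evaluations=nfev,
    )


def estimate_irf(
    dataset: KineticDataset,
    taugrid: TauGrid,
    lam_fixed: float | None = None,
    sigma_bounds: tuple[float, float] = (1e-3, 1.0),
    t0_bounds: tuple[float, float] = (-1.0, 1.0),
    knot_wavelengths: np.ndarray | None = None,
    budget: int = 60,
    seed: int | None = 0,
    settings: ADMMSettings | None = None,
) -> tuple[IRFModel, SelectionResult]:
    """Estimate the Gaussian IRF width and the t0(w) spline knots.

    The objective is the group elastic net objective value at a fixed,
    moderate lambda and omega = 0 with IRF-convolved designs, minimized by
    Bayesian optimization over (t0 knot offsets, sigma).  The returned model
    is meant to be frozen for the main pipeline.  ``lam_fixed`` defaults to
    lambda_max / 1000 — strong enough to keep the fit stable, weak enough
    that the penalty's amplitude shrinkage does not bias the width estimate
    noticeably.
    """
    from .solver import lambda_max as _lmax

    settings = settings or ADMMSettings()
    if knot_wavelengths is None:
        w = dataset.wavelengths
        knot_wavelengths = (
            np.array([w[0], w[(w.size - 1) // 2], w[-1]]) if w.size >= 3
            else np.array([w[0]])
        )
    knot_wavelengths = np.asarray(knot_wavelengths, dtype=float)
    n_knots = knot_wavelengths.size
    if lam_fixed is None:
        base = build_designs(dataset.times, taugrid)
        lam_fixed = _lmax(base, dataset.signal, omega=0.0) / 1000.0

    def objective(*params):
        *knots, log_sigma = params
        irf = IRFModel(
            sigma=10.0**log_sigma,
            knot_wavelengths=knot_wavelengths,
            knot_t0=np.asarray(knots),
        )
        designs = build_designs(dataset.times, taugrid, dataset.wavelengths, irf)
        sol = solve_genp(
            [d.values for d in designs], dataset.signal, lam_fixed, 0.0, settings
        )
        return genp_objective(
            [d.values for d in designs], dataset.signal, sol.X, lam_fixed, 0.0
        )

    bounds = [t0_bounds] * n_knots + [
        (np.log10(sigma_bounds[0]), np.log10(sigma_bounds[1]))
    ]
    res = bayes_opt(objective, bounds, budget, seed=seed, log_objective=True)
    *knots, log_sigma = res.best_point
    vals = np.array([v for _, v in res.samples])
    if vals.size > 1 and vals.std() < 1e-12 * max(1.0, abs(vals.mean())):
        warnings.warn("objective insensitive to IRF parameters", RuntimeWarning)
    lo_s, hi_s = np.log10(sigma_bounds)
    if min(log_sigma - lo_s, hi_s - log_sigma) < 0.01 * (hi_s - lo_s):
        warnings.warn(
            "IRF width estimate sits at the search boundary; widen sigma_bounds",
            RuntimeWarning,
        )
    best = IRFModel(
        sigma=10.0**log_sigma,
        knot_wavelengths=knot_wavelengths,
        knot_t0=np.asarray(knots),
    )
    return best, res
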
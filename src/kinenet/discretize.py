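"""Discretization of sparse amplitude distributions into kinetic components.

A sparse group elastic net solution consists of contiguous runs of nonzero
rows on the time-constant grid.  Each run is condensed into one feature: per
wavelength the (signed) amplitudes are summed and the time constant is the
|amplitude|-weighted mean of the grid taus in the run; a single shared tau
per feature is then the |amplitude|-weighted mean across wavelengths.  The
resulting per-feature amplitude vectors are the decay-associated (difference)
spectra, DADS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import TauGrid
from .solver import GenpSolution

__all__ = ["Feature", "FeatureSet", "find_support", "discretize", "amplitude_threshold"]


@dataclass
class Feature:
    """One kinetic component: a shared time constant (inf for the constant
    term) and its per-wavelength amplitudes (the DADS)."""

    tau: float
    dads: np.ndarray
    per_wavelength_tau: np.ndarray | None = None
    flags: tuple[str, ...] = ()

    @property
    def max_amp(self) -> float:
        return float(np.abs(self.dads).max())


@dataclass
class FeatureSet:
    """Discretized components, ordered by increasing time constant."""

    features: list[Feature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, i) -> Feature:
        return self.features[i]

    @property
    def taus(self) -> np.ndarray:
        return np.array([f.tau for f in self.features])

    @property
    def finite(self) -> "FeatureSet":
        return FeatureSet([f for f in self.features if np.isfinite(f.tau)])

    def max_amp(self) -> float:
        if not self.features:
            return 0.0
        return max(f.max_amp for f in self.features)


def find_support(sol: GenpSolution | np.ndarray, zero_tol: float = 1e-9) -> np.ndarray:
    """Indices of rows with nonzero joint amplitude.

    The ADMM Z block is exactly sparse, so ``zero_tol`` (relative to the
    largest row norm) only guards against round-off.
    """
    X = sol.X if isinstance(sol, GenpSolution) else np.asarray(sol, dtype=float)
    X = np.atleast_2d(X.T).T
    norms = np.linalg.norm(X, axis=1)
    top = norms.max()
    if top == 0:
        return np.array([], dtype=int)
    return np.flatnonzero(norms > zero_tol * top)


def _run_feature(X: np.ndarray, taus: np.ndarray, rows: np.ndarray) -> Feature:
    sub = X[rows]  # (r, p)
    tau_run = taus[rows]
    amp = sub.sum(axis=0)  # per-wavelength signed amplitude
    absw = np.abs(sub)
    wsum = absw.sum(axis=0)
    per_tau = np.full(amp.size, np.nan)
    ok = wsum > 0
    per_tau[ok] = (absw[:, ok] * tau_run[:, None]).sum(axis=0) / wsum[ok]
    flags: list[str] = []
    aw = np.abs(amp)
    if aw.sum() > 0:
        shared = float(np.nansum(aw * per_tau) / aw.sum())
    else:
        # net amplitude cancels at every wavelength: keep the feature but
        # flag it; fall back to the unweighted mean of the per-wavelength
        # taus (or of the run's grid taus if those are undefined too)
        flags.append("zero_net_amplitude")
        shared = float(np.nanmean(per_tau)) if np.any(ok) else float(tau_run.mean())
    return Feature(tau=shared, dads=amp, per_wavelength_tau=per_tau, flags=tuple(flags))


def discretize(
    sol: GenpSolution | np.ndarray,
    taugrid: TauGrid,
    zero_tol: float = 1e-9,
) -> FeatureSet:
    """Convert a sparse solution into discrete components.

    Every contiguous run of support rows over the finite taus becomes one
    feature; the constant (tau = inf) column, if in the support, is its own
    feature.  An empty support yields an empty feature set.
    """
    X = sol.X if isinstance(sol, GenpSolution) else np.asarray(sol, dtype=float)
    X = np.atleast_2d(X.T).T
    if X.shape[0] != taugrid.n:
        raise ValueError("solution rows do not match the tau grid")
    support = find_support(X, zero_tol)
    features: list[Feature] = []
    finite_support = support[support < taugrid.n_finite]
    if finite_support.size:
        splits = np.flatnonzero(np.diff(finite_support) > 1)
        for rows in np.split(finite_support, splits + 1):
            features.append(_run_feature(X, taugrid.taus, rows))
    if taugrid.include_inf and (taugrid.n_finite in support):
        amp = X[taugrid.n_finite]
        features.append(
            Feature(tau=np.inf, dads=amp.copy(), per_wavelength_tau=None,
                    flags=("constant",))
        )
    features.sort(key=lambda f: f.tau)
    return FeatureSet(features)


def amplitude_threshold(fs: FeatureSet, frac: float = 0.05) -> FeatureSet:
    """Drop features whose maximum |DADS| amplitude is below ``frac`` times
    the largest recovered one.  Idempotent; a lone feature is always kept."""
    if not (0 <= frac < 1):
        raise ValueError("frac must lie in [0, 1)")
    if not fs.features:
        return FeatureSet([])
    ref = fs.max_amp()
    return FeatureSet([f for f in fs.features if f.max_amp >= frac * ref])
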
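"""Time-constant grids and design matrices.

The analysis expands each kinetic trace on a quasi-continuous, log-spaced
grid of time constants: column j of the design matrix is exp(-t_i/tau_j)
(optionally convolved with a Gaussian instrument response function), and an
optional tau = infinity column carries a constant (non-decaying) offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import erfc, erfcx

__all__ = [
    "TauGrid",
    "build_tau_grid",
    "default_tau_grid",
    "IRFModel",
    "DesignMatrix",
    "design_exponential",
    "design_irf_convolved",
    "build_designs",
]


@dataclass
class TauGrid:
    """Log-spaced finite time constants, plus an optional tau = inf marker.

    The infinite time constant, when present, is represented as an extra
    constant column appended after the finite ones.
    """

    taus: np.ndarray
    include_inf: bool = False

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, dtype=float).ravel()
        if taus.size < 1 or np.any(taus <= 0) or not np.all(np.isfinite(taus)):
            raise ValueError("taus must be positive and finite")
        if taus.size > 1 and not np.all(np.diff(taus) > 0):
            raise ValueError("taus must be strictly increasing")
        self.taus = taus

    @property
    def n_finite(self) -> int:
        return self.taus.size

    @property
    def n(self) -> int:
        """Total number of design columns (finite taus + constant column)."""
        return self.taus.size + int(self.include_inf)

    def full_taus(self) -> np.ndarray:
        """Finite taus with +inf appended when the constant column is on."""
        if self.include_inf:
            return np.concatenate([self.taus, [np.inf]])
        return self.taus


def build_tau_grid(
    tau_min: float,
    tau_max: float,
    points_per_decade: int = 50,
    include_inf: bool = False,
) -> TauGrid:
    """Log-equidistant tau grid (default 50 points per decade)."""
    if not (0 < tau_min < tau_max):
        raise ValueError("need 0 < tau_min < tau_max")
    if points_per_decade < 1:
        raise ValueError("points_per_decade must be >= 1")
    n_dec = np.log10(tau_max / tau_min)
    imax = int(np.floor(points_per_decade * n_dec * (1 + 1e-12) + 1e-9))
    taus = tau_min * 10.0 ** (np.arange(imax + 1) / points_per_decade)
    return TauGrid(taus=taus, include_inf=include_inf)


def default_tau_grid(
    times: np.ndarray,
    points_per_decade: int = 50,
    include_inf: bool = True,
    pad_decades: float = 1.0,
) -> TauGrid:
    """Default grid spanning one decade beyond the sampled time range."""
    times = np.asarray(times, dtype=float)
    t_pos = times[times > 0]
    if t_pos.size == 0:
        raise ValueError("need at least one positive time point")
    return build_tau_grid(
        t_pos.min() * 10.0 ** (-pad_decades),
        t_pos.max() * 10.0 ** (pad_decades),
        points_per_decade,
        include_inf,
    )


@dataclass
class IRFModel:
    """Gaussian instrument response with wavelength-dependent time zero.

    ``sigma`` is the (wavelength-independent) Gaussian width; t0(w) is a
    natural cubic spline through three knots at fixed wavelengths with free
    time offsets.
    """

    sigma: float
    knot_wavelengths: np.ndarray
    knot_t0: np.ndarray

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        kw = np.asarray(self.knot_wavelengths, dtype=float).ravel()
        kt = np.asarray(self.knot_t0, dtype=float).ravel()
        if kw.size != kt.size:
            raise ValueError("knot arrays must have equal length")
        if kw.size > 1 and not np.all(np.diff(kw) > 0):
            raise ValueError("knot wavelengths must be strictly increasing")
        self.knot_wavelengths = kw
        self.knot_t0 = kt

    def t0(self, wavelength: float | np.ndarray) -> float | np.ndarray:
        if self.knot_wavelengths.size == 1:
            w = np.asarray(wavelength, dtype=float)
            out = np.full_like(w, self.knot_t0[0])
            return float(out) if out.ndim == 0 else out
        spline = CubicSpline(self.knot_wavelengths, self.knot_t0, bc_type="natural")
        val = spline(wavelength)
        return float(val) if np.ndim(val) == 0 else val

    @classmethod
    def default_knots(
        cls, sigma: float, wavelengths: np.ndarray, t0: float = 0.0
    ) -> "IRFModel":
        """Knots at min/mid/max wavelength, all offsets equal to ``t0``."""
        w = np.asarray(wavelengths, dtype=float)
        if w.size >= 3:
            kw = np.array([w[0], w[(w.size - 1) // 2], w[-1]])
        else:
            kw = np.array([w[0]])
        return cls(sigma=sigma, knot_wavelengths=kw, knot_t0=np.full(kw.size, t0))


@dataclass
class DesignMatrix:
    """An m x n design matrix with a record of how its columns were built."""

    values: np.ndarray
    column_kind: str  # "exponential" | "irf_convolved"
    taugrid: TauGrid

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("design matrix must be finite")
        self.values = values

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def design_exponential(times: np.ndarray, taugrid: TauGrid) -> DesignMatrix:
    """Plain exponential design: A[i, j] = exp(-t_i / tau_j); the optional
    tau = inf column is identically 1."""
    t = np.asarray(times, dtype=float)[:, None]
    A = np.exp(-t / taugrid.taus[None, :])
    if taugrid.include_inf:
        A = np.hstack([A, np.ones((t.size, 1))])
    return DesignMatrix(values=A, column_kind="exponential", taugrid=taugrid)


def _exp_conv_gauss(t: np.ndarray, tau: float, t0: float, sigma: float) -> np.ndarray:
    """Gaussian-convolved exponential decay,

        1/2 exp(sigma^2/(2 tau^2) - (t-t0)/tau) erfc((sigma/tau - (t-t0)/sigma)/sqrt2),

    evaluated stably: for nonnegative erfc argument z the product is
    erfcx(z) exp(-(t-t0)^2/(2 sigma^2))/2, which never overflows; for z < 0
    the plain form is already safe because the exponent is negative there.
    """
    dt = t - t0
    z = (sigma / tau - dt / sigma) / np.sqrt(2.0)
    out = np.empty_like(dt)
    pos = z >= 0
    out[pos] = 0.5 * erfcx(z[pos]) * np.exp(-(dt[pos] ** 2) / (2.0 * sigma**2))
    c = sigma**2 / (2.0 * tau**2) - dt[~pos] / tau
    out[~pos] = 0.5 * np.exp(c) * erfc(z[~pos])
    return out


def _step_conv_gauss(t: np.ndarray, t0: float, sigma: float) -> np.ndarray:
    """Gaussian-convolved unit step (the tau = inf column)."""
    return 0.5 * erfc(-(t - t0) / (sigma * np.sqrt(2.0)))


def design_irf_convolved(
    times: np.ndarray,
    taugrid: TauGrid,
    irf: IRFModel,
    wavelength: float,
) -> DesignMatrix:
    """Design matrix with every column convolved with the Gaussian IRF
    centered at t0(wavelength)."""
    if irf.sigma <= 0:
        raise ValueError("sigma must be positive")
    t = np.asarray(times, dtype=float)
    t0 = float(irf.t0(wavelength))
    cols = [_exp_conv_gauss(t, tau, t0, irf.sigma) for tau in taugrid.taus]
    if taugrid.include_inf:
        cols.append(_step_conv_gauss(t, t0, irf.sigma))
    A = np.column_stack(cols)
    return DesignMatrix(values=A, column_kind="irf_convolved", taugrid=taugrid)


def build_designs(
    times: np.ndarray,
    taugrid: TauGrid,
    wavelengths: np.ndarray | None = None,
    irf: IRFModel | None = None,
):
    """Design matrices for a whole dataset.

    Without an IRF a single shared exponential design is returned; with an
    IRF a list of per-wavelength convolved designs is returned (t0 varies
    with wavelength).
    """
    if irf is None:
        return design_exponential(times, taugrid)
    if wavelengths is None:
        raise ValueError("wavelengths required for IRF-convolved designs")
    return [design_irf_convolved(times, taugrid, irf, w) for w in np.asarray(wavelengths)]
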
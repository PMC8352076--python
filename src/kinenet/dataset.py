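"""Container for spectrotemporal kinetic data.

A dataset is a rectangular matrix of signal values (absorbance change,
fluorescence counts, ...) sampled on a strictly increasing time grid and
observed at one or more wavelengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KineticDataset"]


def _validate_grid(x: np.ndarray, name: str, min_len: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_len:
        raise ValueError(f"{name} must have at least {min_len} entries")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")
    if x.size > 1 and not np.all(np.diff(x) > 0):
        raise ValueError(f"{name} must be strictly increasing")
    return x


@dataclass
class KineticDataset:
    """Time grid, wavelength grid and the observed signal matrix.

    Parameters
    ----------
    times : array of shape (m,)
        Strictly increasing sample times (consistent units throughout).
    wavelengths : array of shape (p,)
        Strictly increasing wavelengths (nm or arbitrary index).
    signal : array of shape (m, p)
        Observed signal; column ``k`` is the kinetic trace at
        ``wavelengths[k]``.
    """

    times: np.ndarray
    wavelengths: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = _validate_grid(self.times, "times", min_len=2)
        self.wavelengths = _validate_grid(self.wavelengths, "wavelengths")
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim == 1:
            sig = sig[:, None]
        if sig.shape != (self.times.size, self.wavelengths.size):
            raise ValueError(
                f"signal shape {sig.shape} does not match "
                f"({self.times.size}, {self.wavelengths.size})"
            )
        if not np.all(np.isfinite(sig)):
            raise ValueError("signal must be finite")
        self.signal = sig

    @property
    def m(self) -> int:
        """Number of time points."""
        return self.times.size

    @property
    def p(self) -> int:
        """Number of wavelengths."""
        return self.wavelengths.size

    def trace(self, k: int) -> np.ndarray:
        """Kinetic trace at wavelength index ``k``."""
        return self.signal[:, k]
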
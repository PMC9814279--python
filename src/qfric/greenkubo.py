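"""Green-Kubo estimation of the solid-liquid friction coefficient.

The friction coefficient lambda follows from the equilibrium
autocorrelation of the total tangential force F(t) the liquid exerts on a
surface of area A at temperature T:

    lambda = 1 / (A k_B T) * integral_0^tc dt <F(t) F(0)>

Forces are in kJ mol^-1 nm^-1, times in ps and areas in nm^2; lambda is
converted to SI N s/m^3.  The integral is truncated at ``t_cutoff``
(default 1 ps), where the running integral of a liquid-like force ACF has
plateaued; the running integral is returned so convergence can be
inspected.  The sign convention of the force (on the solid from the water
or the reverse) is irrelevant: lambda is quadratic in F.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import irfft, next_fast_len, rfft
from scipy.integrate import cumulative_trapezoid

from . import constants as const

__all__ = [
    "ForceSeries",
    "Acf",
    "FrictionResult",
    "autocorrelation",
    "friction_coefficient",
    "relative_friction",
]


@dataclass
class ForceSeries:
    """Uniformly sampled tangential surface force with its physical context.

    ``values`` may hold one column (x component) or two (x and y).
    """

    dt: float                 # ps
    values: np.ndarray        # (n,) or (n, k<=2), kJ mol^-1 nm^-1
    area: float               # nm^2
    temperature: float        # K
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.area <= 0:
            raise ValueError("area must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.values.ndim > 2 or (self.values.ndim == 2
                                    and self.values.shape[1] > 2):
            raise ValueError("values must be (n,) or (n, k) with k <= 2")
        if self.values.shape[0] < 2:
            raise ValueError("series must hold at least 2 samples")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]

    @property
    def duration(self) -> float:
        """Total sampled time span, ps."""
        return (self.n - 1) * self.dt

    @classmethod
    def from_csv(cls, path, area: float, temperature: float) -> "ForceSeries":
        """Load a (time_ps, Fx[, Fy]) CSV; the time column must be uniform."""
        df = pd.read_csv(path, comment="#")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: need at least time and one force column")
        t = df.iloc[:, 0].to_numpy(dtype=float)
        steps = np.diff(t)
        if steps.size == 0 or np.ptp(steps) > 1e-6 * max(steps.mean(), 1e-12):
            raise ValueError(f"{path}: time column is not uniformly sampled")
        vals = df.iloc[:, 1:3].to_numpy(dtype=float)
        if vals.shape[1] == 1:
            vals = vals[:, 0]
        return cls(float(steps.mean()), vals, area, temperature,
                   {"source": str(path)})

    def to_csv(self, path) -> None:
        t = np.arange(self.n) * self.dt
        vals = self.values if self.values.ndim == 2 else self.values[:, None]
        cols = {"time_ps": t}
        for k in range(vals.shape[1]):
            cols[f"F{'xy'[k]}"] = vals[:, k]
        pd.DataFrame(cols).to_csv(path, index=False)


@dataclass
class Acf:
    """A stationary force autocorrelation function."""

    lags: np.ndarray     # ps
    values: np.ndarray   # (L+1,) or (L+1, k), (kJ mol^-1 nm^-1)^2
    estimator: str = "fft/biased"

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        first = self.values[0] if self.values.ndim == 1 else self.values[0, :]
        if np.any(np.asarray(first) < -1e-12):
            raise ValueError("ACF at lag 0 must be non-negative")


def autocorrelation(series: ForceSeries, max_lag: float | None = None,
                    method: str = "fft", bias: str = "biased") -> Acf:
    """Autocorrelation of the mean-subtracted force series.

    ``bias="biased"`` normalizes every lag by the full sample count N
    (integrable, the default); ``"unbiased"`` divides lag k by N - k.
    ``method="direct"`` evaluates the O(N L) sum explicitly and must agree
    with the spectral estimate to rounding error.
    """
    n = series.n
    if max_lag is None:
        max_lag = series.duration / 2.0
    if max_lag >= series.duration:
        raise ValueError(
            f"max_lag = {max_lag} ps must be below the series duration "
            f"{series.duration} ps")
    nlag = int(round(max_lag / series.dt))
    x = series.values.reshape(n, -1)
    x = x - x.mean(axis=0, keepdims=True)

    if method == "fft":
        nfft = next_fast_len(2 * n)
        f = rfft(x, n=nfft, axis=0)
        full = irfft((f * f.conj()).real, n=nfft, axis=0)[:nlag + 1]
    elif method == "direct":
        full = np.empty((nlag + 1, x.shape[1]))
        for k in range(nlag + 1):
            full[k] = np.einsum("ij,ij->j", x[: n - k], x[k:])
    else:
        raise ValueError(f"unknown ACF method {method!r}")

    if bias == "biased":
        full = full / n
    elif bias == "unbiased":
        full = full / (n - np.arange(nlag + 1))[:, None]
    else:
        raise ValueError(f"unknown bias convention {bias!r}")

    if series.values.ndim == 1:
        full = full[:, 0]
    lags = np.arange(nlag + 1) * series.dt
    return Acf(lags, full, f"{method}/{bias}")


@dataclass
class FrictionResult:
    """lambda with its running integral and truncation diagnostics."""

    lam: float                  # N s/m^3 (component average)
    lambdas: np.ndarray         # per-component lambdas, N s/m^3
    t_cutoff: float             # ps
    running_lags: np.ndarray    # ps
    running_lambda: np.ndarray  # (L+1, k) running integral in N s/m^3
    converged: bool
    note: str = ""


def friction_coefficient(acf: Acf, area: float, temperature: float,
                         t_cutoff: float = 1.0) -> FrictionResult:
    """Integrate the force ACF up to ``t_cutoff`` and convert to N s/m^3.

    With two force components the reported lambda is their average.  The
    ``converged`` flag checks that the running integral varies by < 5%
    over the last half of the integration window.
    """
    if area <= 0 or temperature <= 0:
        raise ValueError("area and temperature must be positive")
    if acf.lags[-1] < t_cutoff - 1e-12:
        raise ValueError(
            f"t_cutoff = {t_cutoff} ps exceeds the ACF range {acf.lags[-1]} ps")
    vals = acf.values.reshape(len(acf.lags), -1)
    running = cumulative_trapezoid(vals, x=acf.lags, axis=0, initial=0.0)
    conv = const.ACF_INTEGRAL_TO_SI / (area * const.NM2_TO_M2
                                       * const.KB_SI * temperature)
    running_si = running * conv
    idx = int(np.searchsorted(acf.lags, t_cutoff + 1e-12) - 1)
    lambdas = running_si[idx]
    lam = float(lambdas.mean())

    half = int(np.searchsorted(acf.lags, t_cutoff / 2.0))
    window = running_si[half:idx + 1].mean(axis=1)
    scale = max(abs(lam), 1e-300)
    converged = bool(np.ptp(window) <= 0.05 * scale) if len(window) > 1 else False
    if not np.isfinite(lam):
        raise ValueError("friction integral did not evaluate to a finite number")
    return FrictionResult(lam, lambdas, float(acf.lags[idx]),
                          acf.lags[:idx + 1], running_si[:idx + 1], converged)


def relative_friction(lambda_q: float, lambda_0: float) -> float:
    """Ratio lambda_q / lambda_0 of two friction coefficients."""
    if lambda_0 <= 0:
        raise ValueError("reference friction lambda_0 must be > 0")
    return lambda_q / lambda_0
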
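"""Synthetic solubility surfaces with the structure of the real data.

The generator produces strictly positive, right-skewed solubility responses
that grow exponentially with temperature and linearly with pressure — the
qualitative structure of drug solubility in supercritical CO2 on the studied
(T, P) box.  The surface is multiplicatively separable,

    y(T, P) = base * (1 + pressure_slope * (P - P0)) * exp(temp_rate * (T - T0)),

optionally times lognormal noise, which preserves positivity and skew.  The
defaults reproduce the magnitude and trends of the bundled ketoprofen table
(they come from a one-time log-scale least-squares fit to that grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .datasets import SolubilityDataset

__all__ = [
    "SurfaceParams",
    "NoiseSpec",
    "surface_value",
    "default_grid",
    "generate_dataset",
    "recover_params",
]

#: temperature and pressure levels of the study grid (4 x 7 lattice)
STUDY_TEMPERATURES = (308.15, 318.15, 328.15, 338.15)
STUDY_PRESSURES = (160.0, 200.0, 240.0, 280.0, 320.0, 360.0, 400.0)


@dataclass(frozen=True)
class SurfaceParams:
    """Parameters of the separable linear-in-P x exponential-in-T surface.

    Attributes
    ----------
    base:
        Mole-fraction solubility at the reference point (T0, P0); > 0.
    temp_rate:
        Exponential growth coefficient per kelvin; >= 0.
    pressure_slope:
        Relative linear slope per bar; the factor 1 + slope*(P-P0) must stay
        positive over the validity box.
    T0, P0:
        Reference temperature [K] and pressure [bar]; default the grid
        minimum (308.15 K, 160 bar).
    interaction:
        Optional T-P interaction added on the log scale as
        interaction*(T-T0)*(P-P0); zero by default (separable surface).
    """

    base: float = 1.6e-5
    temp_rate: float = 0.082
    pressure_slope: float = 0.0112
    T0: float = 308.15
    P0: float = 160.0
    interaction: float = 0.0

    def __post_init__(self) -> None:
        if self.base <= 0:
            raise ValueError("base must be > 0")
        if self.temp_rate < 0:
            raise ValueError("temp_rate must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative lognormal noise: y -> y * exp(N(0, sigma))."""

    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def surface_value(params: SurfaceParams, T, P) -> np.ndarray:
    """Noiseless surface value at temperature(s) T [K] and pressure(s) P [bar].

    Strictly positive, and nondecreasing in both T and P for nonnegative
    coefficients.  Raises if the pressure factor is not positive anywhere
    among the requested points.
    """
    T = np.asarray(T, float)
    P = np.asarray(P, float)
    pressure_factor = 1.0 + params.pressure_slope * (P - params.P0)
    if np.any(pressure_factor <= 0):
        raise ValueError(
            "pressure factor 1 + pressure_slope*(P - P0) is non-positive at some "
            "requested pressures; the surface would not be a valid solubility"
        )
    log_y = (
        np.log(params.base)
        + np.log(pressure_factor)
        + params.temp_rate * (T - params.T0)
        + params.interaction * (T - params.T0) * (P - params.P0)
    )
    return np.exp(log_y)


def default_grid() -> tuple[np.ndarray, np.ndarray]:
    """The study's 4 x 7 (T, P) lattice, flattened to paired vectors."""
    TT, PP = np.meshgrid(STUDY_TEMPERATURES, STUDY_PRESSURES, indexing="ij")
    return TT.ravel(), PP.ravel()


def generate_dataset(
    params: SurfaceParams = SurfaceParams(),
    grid: tuple[np.ndarray, np.ndarray] | None = None,
    noise: NoiseSpec = NoiseSpec(),
    name: str = "synthetic",
) -> SolubilityDataset:
    """Sample a solubility dataset from the surface with lognormal noise.

    ``grid`` is a pair of equal-length (T, P) vectors; by default the study's
    4 x 7 lattice (28 records).  sigma = 0 returns the noiseless surface
    exactly; a fixed seed reproduces the dataset bit for bit.
    """
    if grid is None:
        T, P = default_grid()
    else:
        T = np.asarray(grid[0], float).ravel()
        P = np.asarray(grid[1], float).ravel()
    if T.size == 0 or T.size != P.size:
        raise ValueError("grid must be two equal-length nonempty vectors")
    y = surface_value(params, T, P)
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        y = y * np.exp(rng.normal(0.0, noise.sigma, size=y.shape))
    frame = pd.DataFrame(
        {"temperature_K": T, "pressure_bar": P, "solubility": y}
    )
    return SolubilityDataset(frame, name=name, provenance=f"synthetic surface {params}")


@dataclass(frozen=True)
class RecoveredParams:
    """Least-squares surface estimate plus a residual summary."""

    params: SurfaceParams
    log_rss: float
    n: int


def recover_params(ds: SolubilityDataset, fit_interaction: bool = False) -> RecoveredParams:
    """Estimate (base, temp_rate, pressure_slope) by log-scale least squares.

    Minimizes sum over records of
    ``(ln y - [ln base + temp_rate*(T-T0) + ln(1 + slope*(P-P0))])^2``
    with (T0, P0) fixed at the dataset minimum.  Requires at least six
    records spanning >= 2 temperature and >= 2 pressure levels.
    """
    if len(ds) < 6:
        raise ValueError("need at least 6 records to recover surface parameters")
    if ds.temperatures.size < 2 or ds.pressures.size < 2:
        raise ValueError(
            "degenerate design: need >= 2 distinct temperature and pressure levels"
        )
    T, P = ds.X[:, 0], ds.X[:, 1]
    y = np.log(ds.y)
    T0, P0 = T.min(), P.min()

    # linearized start: ln y ~ a + k*(T-T0) + c*(P-P0)  (good when slope*(P-P0) small)
    A = np.column_stack([np.ones_like(T), T - T0, P - P0])
    a0, k0, c0 = np.linalg.lstsq(A, y, rcond=None)[0]

    if fit_interaction:
        def model(X, la, k, c, gamma):
            t, p = X
            return la + k * (t - T0) + np.log1p(c * (p - P0)) + gamma * (t - T0) * (p - P0)
        p0 = [a0, max(k0, 0.0), max(c0, 1e-6), 0.0]
    else:
        def model(X, la, k, c):
            t, p = X
            return la + k * (t - T0) + np.log1p(c * (p - P0))
        p0 = [a0, max(k0, 0.0), max(c0, 1e-6)]

    popt, _ = curve_fit(model, (T, P), y, p0=p0, maxfev=20000)
    resid = y - model((T, P), *popt)
    params = SurfaceParams(
        base=float(np.exp(popt[0])),
        temp_rate=float(popt[1]),
        pressure_slope=float(popt[2]),
        T0=float(T0),
        P0=float(P0),
        interaction=float(popt[3]) if fit_interaction else 0.0,
    )
    return RecoveredParams(params=params, log_rss=float(resid @ resid), n=len(ds))
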
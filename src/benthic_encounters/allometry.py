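"""Power-law scaling relations used throughout the package.

Every allometric relationship — consumer/resource velocity versus body
length, encounter-region radius versus consumer mass, and the per-strategy
scalings of unitary resource mass and density versus consumer mass — is
represented by a single :class:`PowerLaw` container, ``y = coefficient *
x**exponent``.  Laws can come from three places: hard-coded literature
values (velocity-length, reaction-distance exponent), ordinary
least-squares fits on log-log axes (:func:`fit_power_law`), or user
configuration (the per-strategy resource regimes consumed by the
agent-based simulator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import statsmodels.api as sm
import yaml

__all__ = [
    "PowerLaw",
    "StrategyScalings",
    "velocity_from_length",
    "length_from_mass",
    "reaction_distance",
    "fit_power_law",
    "clearance_region_radius",
    "default_strategy_scalings",
    "save_laws",
    "load_laws",
]

#: Coefficient (m s^-1 at l = 1 m) and exponent of the velocity-length law
#: refitted from Vogel's compilation for marine body sizes: V = 2.67 * l**1.05.
VELOCITY_COEFF = 2.67
VELOCITY_EXPONENT = 1.05

#: Mass exponent of the reaction distance (encounter-region radius).
REACTION_EXPONENT = 0.36

#: Default radius coefficient, metres at 1 g consumer mass.  A calibration
#: constant: the literature reports only the exponent.
DEFAULT_R0 = 0.01


@dataclass(frozen=True)
class PowerLaw:
    """A power law ``y = coefficient * x**exponent`` with unit metadata.

    Parameters
    ----------
    coefficient : float
        Value of y at x = 1, in `y_units`.  Must be positive.
    exponent : float
        Dimensionless scaling exponent.
    x_units, y_units : str
        Free-text unit declarations (e.g. ``"g"``, ``"m s^-1"``).
    source : str
        One of ``{"paper", "fitted", "config"}`` — provenance of the values.
    coefficient_se, exponent_se : float or None
        Standard errors on the log-log scale when the law was fitted.
    """

    coefficient: float
    exponent: float
    x_units: str = ""
    y_units: str = ""
    source: str = "config"
    coefficient_se: float | None = None
    exponent_se: float | None = None

    def __post_init__(self) -> None:
        if not self.coefficient > 0:
            raise ValueError(f"coefficient must be > 0, got {self.coefficient}")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("power laws are evaluated on x >= 0 only")
        with np.errstate(divide="ignore"):
            out = self.coefficient * np.power(x, self.exponent)
        return float(out) if out.ndim == 0 else out


def velocity_from_length(l) -> float | np.ndarray:
    """Body velocity (m s^-1) of a swimming/crawling organism of length `l` (m).

    Evaluates V = 2.67 * l**1.05, the power law refit of Vogel's velocity
    compilation over the body-size range of benthic consumers and their
    resources.  Defined (as 0) at l = 0.
    """
    l = np.asarray(l, dtype=float)
    if np.any(l < 0):
        raise ValueError("body length must be non-negative")
    out = VELOCITY_COEFF * np.power(l, VELOCITY_EXPONENT)
    return float(out) if out.ndim == 0 else out


def length_from_mass(m, rho: float = 1.0, shape: float = 1.0) -> float | np.ndarray:
    """Characteristic body length (m) from wet mass `m` (g).

    Uses the cube-root volumetric conversion l = shape * (m / rho)^(1/3)
    with tissue density ``rho`` in g cm^-3 (default 1, i.e. neutral
    buoyancy) and a dimensionless shape factor; the cm result is returned
    in metres.  A 1 g organism maps to 1 cm.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mass must be positive")
    if rho <= 0:
        raise ValueError("tissue density must be positive")
    out = shape * np.cbrt(m / rho) / 100.0  # cm -> m
    return float(out) if out.ndim == 0 else out


def reaction_distance(m, r0: float = DEFAULT_R0) -> float | np.ndarray:
    """Encounter-region radius (m) for a consumer of mass `m` (g): r0 * m**0.36."""
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise ValueError("consumer mass must be positive")
    if r0 <= 0:
        raise ValueError("radius coefficient r0 must be positive")
    out = r0 * np.power(m, REACTION_EXPONENT)
    return float(out) if out.ndim == 0 else out


def clearance_region_radius(Q, U) -> float | np.ndarray:
    """Radius (m) of a seabed hemisphere whose flow-facing cross-section
    intercepts a clearance rate `Q` (m^3 s^-1) at current speed `U` (m s^-1).

    A hemisphere anchored to the seabed presents a half-disc of area
    pi r^2 / 2 to horizontal flow, so the volume flux through it is
    U * pi r^2 / 2.  Setting that flux equal to the clearance rate and
    inverting gives r = sqrt(2 Q / (pi U)).  This is a flux-balance
    reconstruction of how a measured clearance rate bounds the effective
    encounter region of a passive suspension feeder.
    """
    Q = np.asarray(Q, dtype=float)
    if np.any(Q < 0):
        raise ValueError("clearance rate must be non-negative")
    if np.any(np.asarray(U) <= 0):
        raise ValueError("current speed must be positive (still water undefined)")
    out = np.sqrt(2.0 * Q / (math.pi * U))
    return float(out) if out.ndim == 0 else out


def fit_power_law(
    x: Iterable[float],
    y: Iterable[float],
    x_units: str = "",
    y_units: str = "",
) -> PowerLaw:
    """Fit ``y = c * x**e`` by OLS regression of log y on log x.

    Returns a :class:`PowerLaw` with ``source="fitted"`` and standard
    errors for both the exponent (slope SE) and the log-coefficient
    (intercept SE).  Requires at least 3 strictly positive (x, y) pairs
    and non-degenerate x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points to fit a power law")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fitting requires strictly positive x and y")
    lx = np.log(x)
    if np.ptp(lx) == 0:
        raise ValueError("x values are degenerate (no spread on log scale)")
    res = sm.OLS(np.log(y), sm.add_constant(lx)).fit()
    intercept, slope = res.params
    se_int, se_slope = res.bse
    return PowerLaw(
        coefficient=float(np.exp(intercept)),
        exponent=float(slope),
        x_units=x_units,
        y_units=y_units,
        source="fitted",
        coefficient_se=float(se_int),
        exponent_se=float(se_slope),
    )


@dataclass(frozen=True)
class StrategyScalings:
    """Resource regime for one encounter strategy.

    ``resource_mass_law`` maps consumer mass (g) to unitary resource wet
    mass (g); ``resource_density_law`` maps consumer mass (g) to unitary
    resource density (individuals m^-2 for 2-D strategies, m^-3 for 3-D).
    Filter feeders search a volume (3-D); active searchers work the
    seabed plane (2-D).
    """

    strategy: str
    resource_mass_law: PowerLaw
    resource_density_law: PowerLaw
    dimensionality: int

    def __post_init__(self) -> None:
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        if self.strategy == "filter" and self.dimensionality != 3:
            raise ValueError("filter feeders encounter resources in 3-D")
        if self.strategy.startswith("active") and self.dimensionality != 2:
            raise ValueError("active strategies encounter resources in 2-D")


def default_strategy_scalings() -> dict[str, StrategyScalings]:
    """Default resource regimes for the three focal strategies.

    These are calibration inputs, not literature estimates: coefficients
    are chosen so that, across consumer masses of 1e-2 to 1e2 g, filter
    feeders face very small (~1e-8 g) planktonic resources at high
    volumetric densities (~1e7 m^-3) while active searchers face
    macroscopic resources (1e-2 to 1 g) at modest planar densities
    (1e1 to 1e2 m^-2), spanning the observed range of resource masses
    (1e-11 to 1e1 g).  Active-static resources are denser and slightly
    larger than active-mobile ones, reflecting sessile prey aggregation.
    All values are overridable from data via :func:`fit_power_law`.
    """
    return {
        "filter": StrategyScalings(
            strategy="filter",
            resource_mass_law=PowerLaw(1e-8, 0.33, "g", "g"),
            resource_density_law=PowerLaw(1e7, 0.0, "g", "m^-3"),
            dimensionality=3,
        ),
        "active-static": StrategyScalings(
            strategy="active-static",
            resource_mass_law=PowerLaw(0.1, 0.5, "g", "g"),
            resource_density_law=PowerLaw(30.0, 0.0, "g", "m^-2"),
            dimensionality=2,
        ),
        "active-mobile": StrategyScalings(
            strategy="active-mobile",
            resource_mass_law=PowerLaw(0.05, 0.5, "g", "g"),
            resource_density_law=PowerLaw(10.0, 0.0, "g", "m^-2"),
            dimensionality=2,
        ),
    }


def minimum_density_law(
    consumer_mass: Iterable[float],
    density: Iterable[float],
    quantile: float = 0.0,
) -> PowerLaw:
    """Fit the minimum (or low-quantile) resource-density scaling.

    Encounter-limited feeding is governed by how scarce resources get, so
    the simulator is parameterised from per-consumer-mass minima rather
    than means.  `quantile=0` takes the minimum within each unique
    consumer mass; a small positive quantile (e.g. 0.1) is a robust
    alternative when outliers are suspected.
    """
    df_mass = np.asarray(consumer_mass, dtype=float)
    dens = np.asarray(density, dtype=float)
    if not 0 <= quantile < 0.5:
        raise ValueError("quantile must be in [0, 0.5)")
    xs, ys = [], []
    for m in np.unique(df_mass):
        vals = dens[df_mass == m]
        ys.append(np.quantile(vals, quantile))
        xs.append(m)
    return fit_power_law(np.array(xs), np.array(ys), "g", "individuals")


# -- serialisation ----------------------------------------------------------

def save_laws(laws: dict[str, PowerLaw], path) -> None:
    """Write a named collection of power laws to a YAML file."""
    payload = {name: asdict(law) for name, law in laws.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_laws(path) -> dict[str, PowerLaw]:
    """Read a named collection of power laws from a YAML file."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {name: PowerLaw(**fields) for name, fields in payload.items()}
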
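"""From peptide solution concentration to vesicle division from within.

The chain: a His-tagged peptide binds NTA-anchor lipids with dissociation
constant K_d (Langmuir isotherm), the bound coverage phi induces spontaneous
curvature m = slope * phi / (2*kappa) (calibrated from bilayer simulations),
and a deflated vesicle of reduced volume v deforms into a two-sphere dumbbell
once m exceeds the neck curvature M_ne = (1/R1 + 1/R2)/2.  Beyond that
threshold the closed neck experiences a constriction force

    f = 8 * pi * kappa * (m - M_ne),

which drives membrane fission (division) when large enough.  Binding at the
inner leaflet reverses the sign of the induced curvature, so a peptide that
bends the membrane away from itself divides the vesicle from within.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from memcurv.errors import ConfigurationError, DomainError
from memcurv.curvature_stats import CurvatureSlope
from memcurv.units import DEFAULT_TEMPERATURE, kbt_per_nm_to_pn

#: Relative tolerance of the concentration root finders.
_ROOT_RTOL = 1e-9

REGIME_BELOW = "below-neck-closure"
REGIME_STABLE = "closed-neck-stable"
REGIME_FISSION = "fission-favored"


@dataclass(frozen=True)
class BindingModel:
    """Langmuir binding of a His peptide to NTA-anchor lipids.

    Defaults: K_d = 18.5 nM (6H-FITC to Ni-NTA lipids), 3 mol % anchor
    lipid, 0.64 nm^2 per lipid, a pi nm^2 peptide footprint (disk of 1 nm
    radius).  Saturation coverage phi_sat = anchor_fraction * peptide_area /
    area_per_lipid: one peptide per anchor lipid.
    """

    kd: float = 18.5
    anchor_fraction: float = 0.03
    area_per_lipid: float = 0.64
    peptide_area: float = float(np.pi)

    def __post_init__(self):
        if self.kd <= 0:
            raise DomainError(f"kd must be positive, got {self.kd}")
        if not 0 < self.anchor_fraction < 1:
            raise DomainError(f"anchor_fraction must be in (0, 1), got {self.anchor_fraction}")
        if self.area_per_lipid <= 0 or self.peptide_area <= 0:
            raise DomainError("areas must be positive")
        if self.phi_sat >= 1:
            raise ConfigurationError(
                f"saturation coverage {self.phi_sat:.3f} >= 1: "
                "one-peptide-per-anchor model breaks down"
            )

    @property
    def phi_sat(self) -> float:
        return self.anchor_fraction * self.peptide_area / self.area_per_lipid


@dataclass(frozen=True)
class VesicleSpec:
    """A deflated vesicle: size, reduced volume, and elastic parameters.

    ``r_ves`` is the radius (um) of the sphere with the vesicle's membrane
    area A = 4*pi*r_ves^2; the reduced volume v = V / ((4*pi/3)*r_ves^3)
    must lie in (1/sqrt(2), 1) for a two-sphere dumbbell to exist.
    """

    r_ves: float
    v: float = 0.8
    kappa: float = 25.2
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if self.r_ves <= 0:
            raise DomainError(f"r_ves must be positive, got {self.r_ves}")
        if not (2**-0.5 < self.v < 1.0):
            raise DomainError(
                f"reduced volume {self.v} outside (1/sqrt(2), 1): "
                "no two-sphere dumbbell"
            )
        if self.kappa <= 0:
            raise DomainError(f"kappa must be positive, got {self.kappa}")

    @property
    def area(self) -> float:
        """Membrane area (um^2)."""
        return 4.0 * np.pi * self.r_ves**2

    @property
    def volume(self) -> float:
        """Enclosed volume (um^3)."""
        return self.v * (4.0 * np.pi / 3.0) * self.r_ves**3


@dataclass(frozen=True)
class DumbbellGeometry:
    """Two-sphere dumbbell: radii r1 >= r2 (um) and neck curvature (um^-1)."""

    r1: float
    r2: float
    m_ne: float

    def __post_init__(self):
        if not self.r1 >= self.r2 > 0:
            raise DomainError("need r1 >= r2 > 0")


@dataclass(frozen=True)
class DivisionPrediction:
    """Concentration sweep of coverage, curvature, force, and regime labels."""

    c_grid: np.ndarray
    phi_of_c: np.ndarray
    m_of_c: np.ndarray
    f_of_c: np.ndarray
    regime: tuple[str, ...]
    c_dumbbell: float | None = None
    c_at_force: float | None = None
    f_target: float = 20.0
    status: str = "ok"
    geometry: DumbbellGeometry | None = None


def langmuir_occupancy(c: float, b: BindingModel) -> float:
    """Fraction of anchor sites occupied at solution concentration c (nM)."""
    if np.any(np.asarray(c) < 0):
        raise DomainError(f"concentration must be >= 0, got {c}")
    return c / (c + b.kd)


def coverage(c: float, b: BindingModel) -> float:
    """Membrane area fraction covered at concentration c: theta(c) * phi_sat."""
    return langmuir_occupancy(c, b) * b.phi_sat


def curvature_from_coverage(
    phi: float, slope: CurvatureSlope, inner_leaflet: bool = False
) -> float:
    """Spontaneous curvature m (um^-1) induced by coverage phi.

    m = slope * phi / (2*kappa) in nm^-1, converted to um^-1; the sign is
    negated for inner-leaflet binding (the membrane bulges the other way).
    """
    if np.any(np.asarray(phi) < 0) or np.any(np.asarray(phi) >= 1):
        raise DomainError(f"phi must be in [0, 1), got {phi}")
    m_per_nm = slope.m0 * phi
    if inner_leaflet:
        m_per_nm = -m_per_nm
    return m_per_nm * 1e3


def dumbbell_radii(spec: VesicleSpec) -> DumbbellGeometry:
    """Solve the two-sphere dumbbell for a vesicle of reduced volume v.

    In units of r_ves the spheres satisfy r1^2 + r2^2 = 1 (area) and
    r1^3 + r2^3 = v (volume); with r1 = sqrt(1 - r2^2) the volume equation
    is monotone in r2 on (0, 1/sqrt(2)] and is solved by bracketed root
    finding.  Neck curvature M_ne = (1/r1 + 1/r2) / 2.
    """
    v = spec.v
    inv_sqrt2 = 2**-0.5

    def volume_residual(r2: float) -> float:
        return (1.0 - r2 * r2) ** 1.5 + r2**3 - v

    # residual > 0 at r2 -> 0+ (value 1 - v) and < 0 at 1/sqrt(2) (2^-1/2 - v)
    r2_red = brentq(volume_residual, 1e-12, inv_sqrt2, xtol=1e-15, rtol=8.9e-16)
    r1_red = np.sqrt(1.0 - r2_red * r2_red)
    m_ne = (1.0 / r1_red + 1.0 / r2_red) / (2.0 * spec.r_ves)
    return DumbbellGeometry(
        r1=r1_red * spec.r_ves, r2=r2_red * spec.r_ves, m_ne=m_ne
    )


def neck_closure_threshold(g: DumbbellGeometry) -> float:
    """Spontaneous curvature m* (um^-1) above which the closed neck is stable."""
    return g.m_ne


def constriction_force(
    kappa: float,
    m: float,
    m_ne: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Constriction force f = 8*pi*kappa*(m - M_ne) on a closed neck, in pN.

    kappa in kBT, curvatures in um^-1; the kBT/nm result is converted to pN
    using kB*T at the given temperature.
    """
    if kappa <= 0:
        raise DomainError(f"kappa must be positive, got {kappa}")
    f_kbt_per_nm = 8.0 * np.pi * kappa * (m - m_ne) * 1e-3  # um^-1 -> nm^-1
    return kbt_per_nm_to_pn(f_kbt_per_nm, temperature)


def predict_division(
    b: BindingModel,
    slope: CurvatureSlope,
    spec: VesicleSpec,
    c_grid: Sequence[float] | None = None,
    f_target: float = 20.0,
    inner_leaflet: bool = True,
) -> DivisionPrediction:
    """Sweep solution concentration and predict dumbbell formation and fission.

    Composes coverage -> curvature (inner leaflet by default) -> dumbbell
    geometry -> constriction force over ``c_grid`` (log-spaced 1e-2..1e4 nM
    by default).  ``c_dumbbell`` solves m(c) = m* and ``c_at_force`` solves
    f(c) = f_target, both by bracketed root finding; each is None when not
    attained on the grid.  If the calibrated slope gives non-positive
    curvature at every concentration the prediction carries an explanatory
    ``status`` instead of thresholds.
    """
    if c_grid is None:
        c = np.logspace(-2, 4, 400)
    else:
        c = np.asarray(c_grid, dtype=float)
        if c.ndim != 1 or c.size < 2 or np.any(np.diff(c) <= 0):
            raise DomainError("c_grid must be a 1-D increasing sequence")
        if np.any(c < 0):
            raise DomainError("concentrations must be >= 0")

    geom = dumbbell_radii(spec)
    m_star = neck_closure_threshold(geom)

    def m_of(ci: float) -> float:
        return curvature_from_coverage(coverage(ci, b), slope, inner_leaflet)

    def f_of(ci: float) -> float:
        return constriction_force(spec.kappa, m_of(ci), m_star, spec.temperature)

    phi = np.array([coverage(ci, b) for ci in c])
    m = np.array([m_of(ci) for ci in c])
    f = np.array([f_of(ci) for ci in c])

    regime = tuple(
        REGIME_BELOW if mi < m_star else (REGIME_FISSION if fi >= f_target else REGIME_STABLE)
        for mi, fi in zip(m, f)
    )

    if np.all(m <= 0):
        return DivisionPrediction(
            c_grid=c, phi_of_c=phi, m_of_c=m, f_of_c=f, regime=regime,
            f_target=f_target, geometry=geom,
            status=(
                "calibrated slope gives non-positive spontaneous curvature "
                "at every concentration; no dumbbell or fission threshold"
            ),
        )

    c_dumbbell = None
    if m[0] < m_star <= m[-1]:
        c_dumbbell = float(
            brentq(lambda ci: m_of(ci) - m_star, c[0], c[-1], rtol=_ROOT_RTOL)
        )
    elif m[0] >= m_star:
        c_dumbbell = float(c[0])

    c_at_force = None
    if f[0] < f_target <= f[-1]:
        c_at_force = float(
            brentq(lambda ci: f_of(ci) - f_target, c[0], c[-1], rtol=_ROOT_RTOL)
        )
    elif f[0] >= f_target:
        c_at_force = float(c[0])

    return DivisionPrediction(
        c_grid=c, phi_of_c=phi, m_of_c=m, f_of_c=f, regime=regime,
        c_dumbbell=c_dumbbell, c_at_force=c_at_force, f_target=f_target,
        geometry=geom,
    )
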
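"""Spontaneous curvature from the stress-profile first moment, with errors.

An asymmetric bilayer prefers to bend; the product of bending rigidity and
spontaneous curvature, 2*kappa*m, equals minus the first moment of the
lateral stress profile,

    2*kappa*m = - integral z * s(z) dz,

evaluated with z = 0 at the midplane and the exterior solution at positive z.
With that convention, bulging toward the exterior compartment gives a
positive spontaneous curvature.  The sign can be flipped via ``moment_sign``
for data recorded under the opposite convention.

Per-block moment series carry autocorrelation; standard errors come from
Flyvbjerg-Petersen blocking (repeated pair averaging until the SEM estimate
plateaus).  Coverage-curvature calibration is a straight-line fit through the
origin, weighted by 1/SEM^2: zero bound peptide means zero induced curvature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, Union, overload

import numpy as np

from memcurv.errors import DomainError, InsufficientDataError, StateError
from memcurv.stress_io import StressProfile
from memcurv.units import DEFAULT_TEMPERATURE, bar_nm2_to_kbt_per_nm

#: Default bending rigidity (kBT) used for calibration, a literature value
#: for the POPC-class bilayers modeled here.
DEFAULT_KAPPA = 25.2


@dataclass(frozen=True)
class CurvatureEstimate:
    """A single 2*kappa*m estimate (kBT/nm) with its SEM and coverage."""

    two_kappa_m: float
    sem: float = 0.0
    phi: float = 0.0
    label: str = ""

    def __post_init__(self):
        if not np.isfinite(self.two_kappa_m):
            raise DomainError("two_kappa_m must be finite")
        if self.sem < 0:
            raise DomainError(f"sem must be >= 0, got {self.sem}")
        if not 0.0 <= self.phi < 1.0:
            raise DomainError(f"phi must be in [0, 1), got {self.phi}")


@dataclass(frozen=True)
class CoverageCurvatureSeries:
    """(phi, 2*kappa*m) points for one membrane composition."""

    points: tuple[CurvatureEstimate, ...]
    label: str = ""

    def __post_init__(self):
        pts = tuple(self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 1:
            raise InsufficientDataError("series needs at least one point")
        phis = [p.phi for p in pts]
        if len(set(phis)) != len(phis):
            raise DomainError("all phi values must be distinct")
        labels = {p.label for p in pts}
        if len(labels) > 1:
            raise DomainError(f"mixed labels in one series: {sorted(labels)}")

    @property
    def phi(self) -> np.ndarray:
        return np.array([p.phi for p in self.points])

    @property
    def y(self) -> np.ndarray:
        return np.array([p.two_kappa_m for p in self.points])

    @property
    def sem(self) -> np.ndarray:
        return np.array([p.sem for p in self.points])


@dataclass(frozen=True)
class CurvatureSlope:
    """Coverage-curvature slope d(2*kappa*m)/dphi and derived local curvature.

    ``m0`` = slope / (2*kappa) is the spontaneous curvature per unit coverage
    (nm^-1); ``m0_inv`` its inverse, the local curvature radius (nm).
    """

    slope: float
    slope_err: float
    kappa: float = DEFAULT_KAPPA
    m0: float = field(init=False)
    m0_inv: float = field(init=False)

    def __post_init__(self):
        if self.kappa <= 0:
            raise DomainError(f"kappa must be positive, got {self.kappa}")
        m0 = self.slope / (2.0 * self.kappa)
        object.__setattr__(self, "m0", m0)
        object.__setattr__(self, "m0_inv", 1.0 / m0 if m0 != 0 else np.inf)


def spontaneous_curvature_moment(
    p: StressProfile,
    temperature: float = DEFAULT_TEMPERATURE,
    moment_sign: float = -1.0,
) -> float:
    """2*kappa*m = -trapz(z * s(z)) converted from bar*nm^2 to kBT/nm.

    Requires a centered profile in the canonical orientation (exterior at
    positive z).  ``moment_sign`` (+-1) selects the sign convention; the
    default makes outward bulging positive.
    """
    if not p.centered:
        raise StateError("profile must be centered at the bilayer midplane")
    if p.exterior_at_positive_z is None:
        raise StateError("profile orientation must be set before the moment")
    if moment_sign not in (-1.0, 1.0):
        raise DomainError(f"moment_sign must be +-1, got {moment_sign}")
    moment_bar_nm2 = moment_sign * float(np.trapezoid(p.z * p.s, p.z))
    return bar_nm2_to_kbt_per_nm(moment_bar_nm2, temperature)


def moment_timeseries(
    profiles: Sequence[StressProfile],
    temperature: float = DEFAULT_TEMPERATURE,
    moment_sign: float = -1.0,
) -> np.ndarray:
    """Per-block/per-frame 2*kappa*m series (kBT/nm), order preserved."""
    profiles = list(profiles)
    if not profiles:
        raise InsufficientDataError("no profiles given")
    first = profiles[0]
    for i, p in enumerate(profiles[1:], start=1):
        if not first.same_grid(p):
            raise DomainError(f"profile {i} grid/flags differ from profile 0")
    return np.array(
        [spontaneous_curvature_moment(p, temperature, moment_sign) for p in profiles]
    )


def blocking_sem(series: Sequence[float]) -> tuple[float, bool]:
    """Flyvbjerg-Petersen blocking estimate of the SEM of a correlated series.

    Neighbor pairs are averaged repeatedly; each blocking level k yields
    s_k = sqrt(var_k / (n_k - 1)), which grows until block averages are
    effectively independent.  The estimate returned is the first level whose
    value is within its own one-sigma uncertainty (s_k / sqrt(2*(n_k - 1)))
    of the next level's; if no such plateau occurs before fewer than four
    blocks remain, the maximum across levels is returned with
    ``plateau_found = False``.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 16:
        raise InsufficientDataError(f"blocking needs >= 16 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise DomainError("series contains non-finite values")

    estimates: list[float] = []
    sigmas: list[float] = []
    while x.size >= 4:
        n = x.size
        var = float(np.var(x, ddof=1))
        s_k = np.sqrt(var / (n - 1))
        estimates.append(s_k)
        sigmas.append(s_k / np.sqrt(2.0 * (n - 1)))
        if x.size % 2:
            x = x[:-1]
        x = 0.5 * (x[0::2] + x[1::2])

    for k in range(len(estimates) - 1):
        if abs(estimates[k + 1] - estimates[k]) <= sigmas[k]:
            return estimates[k], True
    return max(estimates), False


def area_fraction(ree: float, n_peptides: int, box_area: float) -> float:
    """Peptide area fraction phi from the mean end-to-end distance.

    Each bound peptide covers a disk of diameter ``ree`` (the anchored
    complex is free to rotate, so the covered area is circular):
    phi = n * pi * (ree/2)^2 / box_area.
    """
    if ree < 0:
        raise DomainError(f"ree must be >= 0, got {ree}")
    if box_area <= 0:
        raise DomainError(f"box_area must be positive, got {box_area}")
    if n_peptides < 0:
        raise DomainError(f"n_peptides must be >= 0, got {n_peptides}")
    phi = n_peptides * np.pi * (ree / 2.0) ** 2 / box_area
    if phi >= 1.0:
        raise DomainError(
            f"area fraction {phi:.3f} >= 1 violates the dilute-regime assumption"
        )
    return float(phi)


def fit_through_origin(
    series: CoverageCurvatureSeries, kappa: float = DEFAULT_KAPPA
) -> CurvatureSlope:
    """Weighted least-squares line through the origin for 2*kappa*m vs phi.

    Weights are 1/sem^2 when every point carries a positive SEM and uniform
    when every SEM is zero (mixing the two is rejected).  For the weighted
    fit slope_err = sqrt(1 / sum(w * x^2)); the unweighted fit uses the
    residual variance (zero error for a single point, which the line
    interpolates exactly).
    """
    x = series.phi
    y = series.y
    sems = series.sem
    if np.all(x == 0):
        raise DomainError("all phi are zero: slope is unidentifiable")
    if np.all(sems > 0):
        w = 1.0 / sems**2
        weighted = True
    elif np.all(sems == 0):
        w = np.ones_like(x)
        weighted = False
    else:
        raise DomainError("either all sems must be positive or all zero")

    sxx = float(np.sum(w * x * x))
    slope = float(np.sum(w * x * y)) / sxx
    if weighted:
        slope_err = float(np.sqrt(1.0 / sxx))
    elif x.size > 1:
        resid = y - slope * x
        s2 = float(np.sum(resid**2)) / (x.size - 1)
        slope_err = float(np.sqrt(s2 / sxx))
    else:
        slope_err = 0.0
    return CurvatureSlope(slope=slope, slope_err=slope_err, kappa=kappa)


@overload
def leaflet_flip(obj: CurvatureEstimate) -> CurvatureEstimate: ...
@overload
def leaflet_flip(obj: CurvatureSlope) -> CurvatureSlope: ...
@overload
def leaflet_flip(obj: CoverageCurvatureSeries) -> CoverageCurvatureSeries: ...


def leaflet_flip(obj):
    """Sign inversion for binding at the inner instead of the outer leaflet.

    A species that bends the membrane away from itself on the outer leaflet
    bends it toward the exterior when bound inside; curvature values negate,
    uncertainties are unchanged.  Labels gain/lose an ``inner-leaflet`` tag
    so applying the flip twice is the identity.
    """
    tag = " [inner-leaflet]"

    def _toggle(label: str) -> str:
        return label[: -len(tag)] if label.endswith(tag) else label + tag

    if isinstance(obj, CurvatureEstimate):
        return replace(obj, two_kappa_m=-obj.two_kappa_m, label=_toggle(obj.label))
    if isinstance(obj, CurvatureSlope):
        return CurvatureSlope(slope=-obj.slope, slope_err=obj.slope_err, kappa=obj.kappa)
    if isinstance(obj, CoverageCurvatureSeries):
        return CoverageCurvatureSeries(
            points=tuple(leaflet_flip(p) for p in obj.points),
            label=_toggle(obj.label),
        )
    raise TypeError(f"cannot flip object of type {type(obj).__name__}")
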
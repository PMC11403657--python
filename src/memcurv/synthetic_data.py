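"""Synthetic stress profiles, moment series, and calibration data.

Every pipeline stage needs inputs with known ground truth.  The generators
here emulate the statistical shape of the real objects — tension-free
bilayer stress profiles with a planted first moment, autocorrelated moment
time series, and linear-through-origin coverage-curvature data with
heteroscedastic noise — without any molecular detail.  All generators are
deterministic given their seed and emit their ground truth alongside the
data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from memcurv.errors import ConfigurationError, DomainError
from memcurv.curvature_stats import CoverageCurvatureSeries, CurvatureEstimate
from memcurv.stress_io import DIALECTS, StressProfile
from memcurv.units import DEFAULT_TEMPERATURE, bar_nm2_to_kbt_per_nm


@dataclass(frozen=True)
class ProfileRecipe:
    """Recipe for a synthetic bilayer stress-profile ensemble.

    The mean profile is a symmetric pair of repulsive headgroup peaks at
    +-headgroup_position and a central attractive trough, balanced so the
    profile is tension-free (zero integral), plus an antisymmetric component
    c * z * exp(-z^2 / (2 * asym_width^2)) scaled so the first moment
    integral z*s(z) dz equals ``planted_first_moment`` (bar*nm^2) on the
    discrete grid.  Per-frame white Gaussian noise of sd ``noise_sd`` (bar)
    is added to every slab.  Scales mimic coarse-grained bilayer output:
    16 nm box, peaks at +-2 nm, ~100 bar amplitudes.
    """

    box_height: float = 16.0
    spacing: float = 0.05
    headgroup_position: float = 2.0
    peak_amplitude: float = 100.0
    trough_amplitude: float = 60.0
    peak_width: float = 0.5
    trough_width: float = 1.0
    asym_width: float = 1.0
    planted_first_moment: float = 0.0
    noise_sd: float = 0.0
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.box_height <= 0 or self.spacing <= 0:
            raise ConfigurationError("box_height and spacing must be positive")
        n = self.box_height / self.spacing
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"spacing {self.spacing} does not divide box_height {self.box_height}"
            )
        if round(n) < 8:
            raise ConfigurationError("recipe yields fewer than 8 slabs")
        if min(self.peak_width, self.trough_width, self.asym_width) <= 0:
            raise ConfigurationError("widths must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")

    @property
    def n_slabs(self) -> int:
        return round(self.box_height / self.spacing)

    def grid(self) -> np.ndarray:
        """Slab-center grid, symmetric about the midplane."""
        n = self.n_slabs
        return (np.arange(n) + 0.5) * self.spacing - self.box_height / 2.0


@dataclass(frozen=True)
class SeriesRecipe:
    """Recipe for a stationary AR(1) series with planted mean and variance."""

    n: int = 1024
    rho: float = 0.0
    marginal_sd: float = 1.0
    mean: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rho < 1.0:
            raise DomainError(f"rho must be in [0, 1), got {self.rho}")
        if self.n < 16:
            raise DomainError(f"n must be >= 16, got {self.n}")
        if self.marginal_sd < 0:
            raise DomainError("marginal_sd must be >= 0")


def _gauss(z: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((z - center) ** 2) / (2.0 * width**2))


def make_profile_ensemble(
    r: ProfileRecipe,
) -> tuple[list[StressProfile], dict]:
    """Generate per-frame stress profiles with planted tension and moment.

    Returns the frames (centered, canonical orientation) and a ground-truth
    record with the noiseless mean profile, the planted first moment
    (bar*nm^2) and the 2*kappa*m value (kBT/nm) the moment pipeline should
    recover.
    """
    z = r.grid()

    peaks = r.peak_amplitude * (
        _gauss(z, r.headgroup_position, r.peak_width)
        + _gauss(z, -r.headgroup_position, r.peak_width)
    )
    trough_shape = _gauss(z, 0.0, r.trough_width)
    # balance the trough so the discrete integral (tension) is exactly zero
    trough_scale = np.trapezoid(peaks, z) / np.trapezoid(trough_shape, z)
    base = peaks - trough_scale * trough_shape

    asym_unit = z * _gauss(z, 0.0, r.asym_width)
    m_base = float(np.trapezoid(z * base, z))
    m_asym_unit = float(np.trapezoid(z * asym_unit, z))
    c = (r.planted_first_moment - m_base) / m_asym_unit
    mean_s = base + c * asym_unit

    rng = np.random.default_rng(r.seed)
    frames = []
    for _ in range(r.n_frames):
        noise = rng.normal(0.0, r.noise_sd, size=z.size) if r.noise_sd > 0 else 0.0
        frames.append(
            StressProfile(
                z=z.copy(),
                s=mean_s + noise,
                exterior_at_positive_z=True,
                centered=True,
                n_frames=1,
                box_height=r.box_height,
            )
        )

    truth = {
        "mean_profile": StressProfile(
            z=z.copy(), s=mean_s.copy(), exterior_at_positive_z=True,
            centered=True, n_frames=r.n_frames, box_height=r.box_height,
        ),
        "first_moment_bar_nm2": r.planted_first_moment,
        "two_kappa_m_kbt_per_nm": bar_nm2_to_kbt_per_nm(
            -r.planted_first_moment, DEFAULT_TEMPERATURE
        ),
        "noise_sd": r.noise_sd,
        "n_frames": r.n_frames,
        "seed": r.seed,
    }
    return frames, truth


def make_ar1_series(r: SeriesRecipe) -> np.ndarray:
    """Stationary AR(1): x_t = mean + rho*(x_{t-1} - mean) + eps_t.

    Innovations have sd marginal_sd * sqrt(1 - rho^2) so the marginal
    standard deviation is exactly ``marginal_sd``; x_0 is drawn from the
    stationary distribution.
    """
    rng = np.random.default_rng(r.seed)
    eps_sd = r.marginal_sd * np.sqrt(1.0 - r.rho**2)
    x = np.empty(r.n)
    x[0] = rng.normal(0.0, r.marginal_sd)
    innovations = rng.normal(0.0, eps_sd, size=r.n - 1)
    for t in range(1, r.n):
        x[t] = r.rho * x[t - 1] + innovations[t - 1]
    return x + r.mean


def make_coverage_dataset(
    slope: float,
    phis: Sequence[float],
    sems: Sequence[float],
    seed: int = 0,
    label: str = "synthetic",
) -> CoverageCurvatureSeries:
    """Coverage-curvature points y_i = slope*phi_i + N(0, sem_i^2)."""
    phis = np.asarray(phis, dtype=float)
    sems = np.asarray(sems, dtype=float)
    if phis.shape != sems.shape:
        raise ConfigurationError("phis and sems must have the same length")
    if np.any(sems <= 0):
        raise ConfigurationError("sems must be positive")
    rng = np.random.default_rng(seed)
    y = slope * phis + rng.normal(0.0, sems)
    points = tuple(
        CurvatureEstimate(two_kappa_m=float(yi), sem=float(si), phi=float(p), label=label)
        for yi, si, p in zip(y, sems, phis)
    )
    return CoverageCurvatureSeries(points=points, label=label)


def write_profile(
    p: StressProfile,
    dialect: str,
    path: str | Path,
    szz: float = 0.0,
) -> None:
    """Write a profile in a dialect that ``read_stress_table`` reads back.

    Tensor dialects store sxx = syy = s + szz with a constant normal
    component ``szz`` (and zero off-diagonals for the 9-component layout),
    so lateral_stress reconstructs s exactly.
    """
    if dialect not in DIALECTS:
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    lines = [
        "# synthetic lateral-stress profile",
        f"# dialect={dialect} n_frames={p.n_frames}",
    ]
    for zi, si in zip(p.z, p.s):
        if dialect == "lateral-2col":
            row = [zi, si]
        elif dialect == "tensor-diag":
            row = [zi, si + szz, si + szz, szz]
        else:  # tensor-9col, row-major (xx xy xz yx yy yz zx zy zz)
            row = [zi, si + szz, 0.0, 0.0, 0.0, si + szz, 0.0, 0.0, 0.0, szz]
        lines.append(" ".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")
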
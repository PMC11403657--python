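"""Reading, validating, orienting and centering per-slab lateral-stress profiles.

Input files are whitespace-delimited tables as written by local-stress
post-processing of bilayer trajectories (one row per z-slab).  Three dialects
are supported:

``lateral-2col``
    z plus a precomputed lateral stress s(z).
``tensor-diag``
    z plus the three diagonal stress-tensor components sxx, syy, szz.
``tensor-9col``
    z plus the full tensor in row-major order
    (sxx, sxy, sxz, syx, syy, syz, szx, szy, szz).

Stress is in bar, coordinates in nm.  The canonical profile convention is:
z = 0 at the bilayer midplane, with the upper leaflet and the exterior
solution at positive z.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TextIO

import numpy as np

from memcurv.errors import (
    ConfigurationError,
    DomainError,
    FormatError,
    InsufficientDataError,
    ParseError,
    StateError,
)

#: Supported input dialects and the 0-based columns of (sxx, syy, szz).
DIALECTS = {
    "lateral-2col": None,
    "tensor-diag": (1, 2, 3),
    "tensor-9col": (1, 5, 9),
}

_MIN_ROWS = 8
_GRID_RTOL = 1e-6


@dataclass(frozen=True)
class RawStressTable:
    """Raw parsed stress table: slab coordinates plus stress columns (bar)."""

    z: np.ndarray
    sigma: np.ndarray  # shape (n, k): k = 1 (lateral) or 3 (diagonal)
    dialect: str

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float)
        sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        if sigma.shape[0] != z.size:
            sigma = sigma.T
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "sigma", sigma)
        if z.size < _MIN_ROWS:
            raise InsufficientDataError(
                f"need at least {_MIN_ROWS} slabs, got {z.size}"
            )
        if not (np.all(np.isfinite(z)) and np.all(np.isfinite(sigma))):
            raise FormatError("non-finite values in stress table")
        if sigma.shape[1] not in (1, 3):
            raise FormatError(
                f"expected 1 lateral or 3 diagonal stress columns, got {sigma.shape[1]}"
            )

    @property
    def n_rows(self) -> int:
        return self.z.size


@dataclass(frozen=True)
class StressProfile:
    """Canonical lateral-stress function s(z) on a uniform grid.

    Attributes
    ----------
    z : ndarray
        Slab coordinates (nm), uniform spacing, strictly increasing.
    s : ndarray
        Lateral stress per slab (bar), s = (sxx + syy)/2 - szz.
    exterior_at_positive_z : bool | None
        True once the profile is in the canonical orientation; None = unknown.
    centered : bool
        True once z = 0 is the bilayer midplane.
    n_frames : int
        Trajectory frames averaged into this profile.
    box_height : float
        Full z-span of the simulation box (nm), = n_slabs * spacing.
    """

    z: np.ndarray
    s: np.ndarray
    exterior_at_positive_z: bool | None = None
    centered: bool = False
    n_frames: int = 1
    box_height: float | None = None

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float)
        s = np.asarray(self.s, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "s", s)
        if z.size < _MIN_ROWS:
            raise InsufficientDataError(f"need >= {_MIN_ROWS} slabs, got {z.size}")
        if z.size != s.size:
            raise FormatError("z and s must have equal length")
        if not np.all(np.isfinite(s)) or not np.all(np.isfinite(z)):
            raise FormatError("non-finite values in profile")
        dz = np.diff(z)
        if np.any(dz <= 0):
            raise FormatError("z grid must be strictly increasing")
        h = dz.mean()
        if np.max(np.abs(dz - h)) > _GRID_RTOL * h:
            raise FormatError("non-uniform z grid (resampling is not supported)")
        if self.n_frames < 1:
            raise DomainError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.box_height is None:
            object.__setattr__(self, "box_height", z.size * h)
        else:
            expected = z.size * h
            if abs(self.box_height - expected) > 1e-6 * max(expected, 1.0):
                raise FormatError(
                    f"box_height {self.box_height} inconsistent with "
                    f"{z.size} slabs of spacing {h:.6g}"
                )

    @property
    def spacing(self) -> float:
        return float(np.diff(self.z).mean())

    def same_grid(self, other: "StressProfile", rtol: float = 1e-9) -> bool:
        return (
            self.z.size == other.z.size
            and np.allclose(self.z, other.z, rtol=rtol, atol=1e-12)
            and self.centered == other.centered
            and self.exterior_at_positive_z == other.exterior_at_positive_z
        )


def read_stress_table(source: str | Path | TextIO, dialect: str) -> RawStressTable:
    """Parse a whitespace-delimited local-stress table.

    Lines starting with '#' or '@' are comments.  ``dialect`` selects the
    column layout (see module docstring).

    Raises
    ------
    ConfigurationError
        Unknown dialect name.
    ParseError
        Non-numeric token, with the offending 1-based line number.
    FormatError
        Wrong number of columns for the dialect.
    InsufficientDataError
        Fewer than 8 data rows.
    """
    if dialect not in DIALECTS:
        raise ConfigurationError(
            f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}"
        )
    if hasattr(source, "read"):
        stream: TextIO = source  # type: ignore[assignment]
    else:
        stream = io.StringIO(Path(source).read_text())

    expected_cols = {"lateral-2col": 2, "tensor-diag": 4, "tensor-9col": 10}[dialect]
    rows: list[list[float]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line[0] in "#@":
            continue
        tokens = line.split()
        try:
            values = [float(tok) for tok in tokens]
        except ValueError:
            raise ParseError(
                f"non-numeric token on line {lineno}: {line!r}", line=lineno
            ) from None
        if len(values) < expected_cols:
            raise FormatError(
                f"line {lineno}: dialect {dialect!r} needs {expected_cols} "
                f"columns, found {len(values)}"
            )
        rows.append(values[:expected_cols])

    if len(rows) < _MIN_ROWS:
        raise InsufficientDataError(
            f"need at least {_MIN_ROWS} data rows, got {len(rows)}"
        )
    data = np.asarray(rows, dtype=float)
    z = data[:, 0]
    cols = DIALECTS[dialect]
    sigma = data[:, 1:2] if cols is None else data[:, list(cols)]
    return RawStressTable(z=z, sigma=sigma, dialect=dialect)


def lateral_stress(table: RawStressTable) -> StressProfile:
    """Collapse a raw table to the lateral stress s(z) = (sxx + syy)/2 - szz.

    For the ``lateral-2col`` dialect the stored column is passed through.
    Orientation and centering remain unknown until set explicitly.
    """
    if table.sigma.shape[1] == 1:
        s = table.sigma[:, 0]
    elif table.sigma.shape[1] == 3:
        sxx, syy, szz = table.sigma.T
        s = (sxx + syy) / 2.0 - szz
    else:  # pragma: no cover - guarded by RawStressTable
        raise FormatError("missing diagonal stress components")
    return StressProfile(z=table.z.copy(), s=np.asarray(s, dtype=float))


def center_profile(p: StressProfile, midplane: float | None = None) -> StressProfile:
    """Shift the grid so the bilayer midplane maps to z = 0.

    The default midplane is the geometric box center (z[0] + z[-1])/2; an
    explicit midplane must lie inside the grid range.
    """
    if midplane is None:
        midplane = 0.5 * (p.z[0] + p.z[-1])
    elif not (p.z[0] <= midplane <= p.z[-1]):
        raise DomainError(
            f"midplane {midplane} outside grid [{p.z[0]}, {p.z[-1]}]"
        )
    return replace(p, z=p.z - midplane, s=p.s.copy(), centered=True)


def set_orientation(p: StressProfile, exterior_at_positive_z: bool) -> StressProfile:
    """Put a centered profile into the canonical orientation.

    The canonical convention has the upper leaflet and exterior solution at
    positive z.  If the data were recorded with the exterior at negative z the
    grid is reflected (z -> -z, samples reversed) so the convention holds.
    """
    if not p.centered:
        raise StateError("profile must be centered before orienting")
    if exterior_at_positive_z:
        return replace(p, exterior_at_positive_z=True)
    return replace(
        p, z=-p.z[::-1], s=p.s[::-1].copy(), exterior_at_positive_z=True
    )


def tension(p: StressProfile, tolerance: float = 1.0) -> tuple[float, bool]:
    """Integrate the profile to get the membrane tension (bar*nm).

    For a tension-free bilayer the integral vanishes up to sampling noise.
    Returns the trapezoidal integral and a warning flag set when its
    magnitude exceeds ``tolerance``.
    """
    if not p.centered:
        raise StateError("profile must be centered before computing tension")
    value = float(np.trapezoid(p.s, p.z))
    return value, abs(value) > tolerance


def write_canonical_csv(p: StressProfile, path: str | Path) -> None:
    """Write the canonical profile as CSV (z_nm, s_bar) with metadata comments."""
    lines = [
        f"# centered={p.centered}",
        f"# exterior_at_positive_z={p.exterior_at_positive_z}",
        f"# n_frames={p.n_frames}",
        f"# box_height_nm={p.box_height!r}",
        "z_nm,s_bar",
    ]
    lines += [f"{z!r},{s!r}" for z, s in zip(p.z, p.s)]
    Path(path).write_text("\n".join(lines) + "\n")
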
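"""Magnetic forward model: current dipole in a homogeneous conducting sphere.

The external magnetic field of a current dipole inside a spherically
symmetric volume conductor has a closed analytic form (the standard MEG
sphere solution).  Two properties of that solution matter downstream:
radially oriented dipoles are magnetically silent, and the field is
linear in the dipole moment, so a channels x 3 leadfield fully describes
a source location.

Units: user-facing geometry in millimetres (RAS, conductor centre at a
configurable origin), moments in nAm; conversion to SI happens at the
module boundary and fields are returned in tesla.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MU0 = 4e-7 * np.pi  # vacuum permeability, T m / A


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent source/sensor geometry."""


@dataclass(frozen=True)
class ConductorModel:
    """Homogeneous spherical volume conductor.

    Parameters
    ----------
    centre_mm : (3,) array
        Sphere centre in world coordinates (mm).
    radius_mm : float
        Conductor radius; sensors must lie strictly outside, sources
        strictly inside.
    label : str
        Free-form description.
    """

    centre_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius_mm: float = 90.0
    label: str = "homogeneous sphere"

    def __post_init__(self):
        object.__setattr__(self, "centre_mm", np.asarray(self.centre_mm, float))
        if self.centre_mm.shape != (3,):
            raise GeometryError("conductor centre must be a 3-vector")
        if self.radius_mm <= 0:
            raise GeometryError("conductor radius must be positive")


@dataclass(frozen=True)
class SensorArray:
    """Magnetometer / axial-gradiometer array.

    positions_mm : (n, 3) coil positions (inner coil for gradiometers).
    orientations : (n, 3) unit coil orientations (sensitive axis).
    baseline_mm : axial gradiometer baseline; ``None`` for magnetometers.
        A gradiometer channel reads the difference of the field projection
        at the inner coil and at the coil displaced by ``baseline_mm``
        along the orientation.
    """

    positions_mm: np.ndarray
    orientations: np.ndarray
    baseline_mm: float | None = None
    name: str = "synthetic helmet"

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions_mm, float))
        ori = np.atleast_2d(np.asarray(self.orientations, float))
        if pos.shape != ori.shape or pos.shape[1] != 3:
            raise GeometryError("positions and orientations must be (n, 3)")
        norms = np.linalg.norm(ori, axis=1)
        if np.any(norms == 0):
            raise GeometryError("zero-length sensor orientation")
        object.__setattr__(self, "positions_mm", pos)
        object.__setattr__(self, "orientations", ori / norms[:, None])

    @property
    def n_channels(self) -> int:
        return self.positions_mm.shape[0]


@dataclass(frozen=True)
class Leadfield:
    """Leadfield of one source location: channels x 3, tesla per A m.

    Column j is the channel response to a unit (1 A m) dipole along
    world axis j, so the field of a moment ``m`` (nAm) is
    ``1e-9 * matrix @ m``.
    """

    matrix: np.ndarray
    source_location_mm: np.ndarray

    def predict(self, moment_nAm: np.ndarray) -> np.ndarray:
        """Channel field (tesla) for a dipole moment in nAm."""
        return self.matrix @ (np.asarray(moment_nAm, float) * 1e-9)


def _sphere_field_at(points_m: np.ndarray, r0_m: np.ndarray, q_Am: np.ndarray) -> np.ndarray:
    """Analytic sphere-conductor field (tesla) at free-space points.

    ``points_m``: (n, 3) observation points, ``r0_m``: source location,
    both relative to the conductor centre, metres; ``q_Am``: moment in A m.
    """
    r = points_m
    rn = np.linalg.norm(r, axis=1)
    a = r - r0_m
    an = np.linalg.norm(a, axis=1)
    if np.any(an == 0):
        raise GeometryError("observation point coincides with the source")
    ar = np.einsum("ij,j->i", r, r0_m)  # r . r0 -> used via a.r below
    adotr = np.einsum("ij,ij->i", a, r)
    F = an * (rn * an + rn**2 - ar)
    if np.any(F == 0):
        raise GeometryError("degenerate geometry (F = 0) in sphere solution")
    gradF = (
        (an**2 / rn + adotr / an + 2.0 * an + 2.0 * rn)[:, None] * r
        - (an + 2.0 * rn + adotr / an)[:, None] * r0_m
    )
    qxr0 = np.cross(q_Am, r0_m)
    qxr0_dot_r = np.einsum("ij,j->i", r, qxr0)
    B = (MU0 / (4.0 * np.pi * F**2))[:, None] * (
        F[:, None] * qxr0 - qxr0_dot_r[:, None] * gradF
    )
    return B


def _check_geometry(location_mm, conductor: ConductorModel, array: SensorArray):
    r0 = np.asarray(location_mm, float) - conductor.centre_mm
    if np.linalg.norm(r0) < 1e-9:
        raise GeometryError("source at the conductor centre is degenerate")
    if np.linalg.norm(r0) >= conductor.radius_mm:
        raise GeometryError("source must lie strictly inside the conductor")
    sensor_r = np.linalg.norm(array.positions_mm - conductor.centre_mm, axis=1)
    if np.any(sensor_r <= conductor.radius_mm):
        raise GeometryError("all sensors must lie strictly outside the conductor")
    return r0


def dipole_field(
    location_mm,
    moment_nAm,
    conductor: ConductorModel,
    array: SensorArray,
) -> np.ndarray:
    """Channel readings (tesla) of a current dipole.

    Magnetometer channels read the field projected on the coil
    orientation; axial gradiometers the difference of projections at the
    two coil positions.  Radial dipoles produce an identically zero
    field, and the reading is exactly linear in the moment.
    """
    r0 = _check_geometry(location_mm, conductor, array) * 1e-3
    q = np.asarray(moment_nAm, float) * 1e-9
    pos = (array.positions_mm - conductor.centre_mm) * 1e-3
    B = _sphere_field_at(pos, r0, q)
    out = np.einsum("ij,ij->i", B, array.orientations)
    if array.baseline_mm is not None:
        pos2 = pos + array.orientations * (array.baseline_mm * 1e-3)
        B2 = _sphere_field_at(pos2, r0, q)
        out = out - np.einsum("ij,ij->i", B2, array.orientations)
    return out


def leadfield(location_mm, conductor: ConductorModel, array: SensorArray) -> Leadfield:
    """Leadfield matrix (channels x 3, T per A m) at one source location."""
    loc = np.asarray(location_mm, float)
    cols = [dipole_field(loc, np.eye(3)[j] * 1e9, conductor, array) for j in range(3)]
    return Leadfield(matrix=np.column_stack(cols), source_location_mm=loc)
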
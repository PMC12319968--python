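"""Point-magnetometer lead fields for a spherically symmetric conductor.

The magnetic field of a current dipole inside a homogeneous conducting
sphere has the closed form derived by Sarvas (1987):

    B(r) = mu0 / (4 pi F^2) * ( F (Q x r0) - ((Q x r0) . r) grad F )

with r0 the dipole location, r the field point (both relative to the sphere
centre), a = r - r0, F = a (r a + r^2 - r0.r), and

    grad F = (a^2/r + (a.r)/a + 2a + 2r) r - (a + 2r + (a.r)/a) r0.

Volume currents contribute no external field component from the radial part
of the dipole moment, so a radial dipole is magnetically silent -- the
symmetry the laminar problem lives off, since nearly-radial pial/white
dipoles differ slightly in both depth and orientation.

Units: positions mm, dipole moments nAm, fields fT (typical MEG scales).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SensorArray, SurfaceMesh

__all__ = [
    "HeadConductor",
    "LeadField",
    "dipole_field",
    "assemble_leadfield",
    "fit_conductor",
]

_MU0_4PI = 1e-7  # T m / A


@dataclass
class HeadConductor:
    """Homogeneous conducting sphere (centre mm, radius mm)."""

    centre: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.centre = np.asarray(self.centre, dtype=float)
        if self.radius <= 0:
            raise ValueError("conductor radius must be > 0")


@dataclass
class LeadField:
    """Channels x oriented-sources gain matrix in fT per nAm."""

    gain: np.ndarray  # (n_channels, n_sources)
    channel_ids: list[str]
    source_positions: np.ndarray  # (n_sources, 3) mm
    source_orientations: np.ndarray  # (n_sources, 3) unit
    surface_label: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


def dipole_field(
    conductor: HeadConductor,
    dipole_pos_mm: np.ndarray,
    dipole_moment_nam: np.ndarray,
    field_points_mm: np.ndarray,
) -> np.ndarray:
    """Sarvas field (fT) of one current dipole at one or more field points.

    The dipole must lie strictly inside the conductor and every field point
    strictly outside.
    """
    r0 = (np.asarray(dipole_pos_mm, dtype=float) - conductor.centre) * 1e-3
    q = np.asarray(dipole_moment_nam, dtype=float) * 1e-9
    pts = np.atleast_2d(np.asarray(field_points_mm, dtype=float))
    r = (pts - conductor.centre) * 1e-3

    rad_m = conductor.radius * 1e-3
    if np.linalg.norm(r0) >= rad_m:
        raise ValueError("dipole must lie strictly inside the conductor")
    rn = np.linalg.norm(r, axis=1)
    if np.any(rn <= rad_m):
        raise ValueError("field point inside (or on) the conductor")

    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    if np.any(a < 1e-12):
        raise ValueError("field point coincides with the dipole")
    r0_dot_r = r @ r0
    a_dot_r = (a_vec * r).sum(axis=1)

    f = a * (rn * a + rn**2 - r0_dot_r)
    grad_f = (
        (a**2 / rn + a_dot_r / a + 2.0 * a + 2.0 * rn)[:, None] * r
        - (a + 2.0 * rn + a_dot_r / a)[:, None] * r0
    )
    qxr0 = np.cross(q, r0)
    b = _MU0_4PI / f[:, None] ** 2 * (f[:, None] * qxr0 - (r @ qxr0)[:, None] * grad_f)
    b_ft = b * 1e15
    return b_ft[0] if np.asarray(field_points_mm).ndim == 1 else b_ft


def fit_conductor(
    pial: SurfaceMesh, array: SensorArray, centre: np.ndarray | None = None
) -> HeadConductor:
    """Sphere containing all pial vertices with all sensors outside it."""
    c = np.zeros(3) if centre is None else np.asarray(centre, dtype=float)
    r_src = np.linalg.norm(pial.vertices - c, axis=1).max()
    r_sens = np.linalg.norm(array.positions - c, axis=1).min()
    if r_sens <= r_src:
        raise ValueError("sensors are not all outside the source space")
    return HeadConductor(c, 0.5 * (r_src + r_sens))


def assemble_leadfield(
    positions_mm: np.ndarray,
    orientations: np.ndarray,
    array: SensorArray,
    conductor: HeadConductor,
    surface_label: str = "",
    moment_nam: float = 1.0,
) -> LeadField:
    """Gain matrix: unit dipoles along ``orientations`` onto channel axes.

    Channel ordering is sensor-major then axis, matching
    ``SensorArray.channel_ids``.
    """
    positions_mm = np.atleast_2d(np.asarray(positions_mm, dtype=float))
    orientations = np.atleast_2d(np.asarray(orientations, dtype=float))

    sens_r = np.linalg.norm(array.positions - conductor.centre, axis=1)
    inside = np.nonzero(sens_r <= conductor.radius)[0]
    if inside.size:
        raise ValueError(
            f"sensor(s) inside conductor: {', '.join(f's{i:03d}' for i in inside)}"
        )
    n_axes = array.n_axes
    gain = np.empty((array.n_sensors * n_axes, len(positions_mm)))
    for s, (pos, ori) in enumerate(zip(positions_mm, orientations)):
        b = dipole_field(conductor, pos, moment_nam * ori, array.positions)
        # (n_sensors, n_axes): field projected on each measurement axis
        proj = np.einsum("ni,nki->nk", b, array.channel_axes)
        gain[:, s] = proj.reshape(-1)
    return LeadField(
        gain=gain,
        channel_ids=array.channel_ids,
        source_positions=positions_mm,
        source_orientations=orientations,
        surface_label=surface_label,
        metadata={
            "forward_model": "sarvas_conducting_sphere",
            "units": "fT_per_nAm",
            "conductor_centre_mm": conductor.centre.tolist(),
            "conductor_radius_mm": float(conductor.radius),
        },
    )


def leadfield_for_surface(
    mesh: SurfaceMesh,
    array: SensorArray,
    conductor: HeadConductor,
    label: str = "",
) -> LeadField:
    """Lead field for all vertices of a surface, oriented along its normals."""
    return assemble_leadfield(
        mesh.vertices, mesh.vertex_normals, array, conductor, surface_label=label
    )
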
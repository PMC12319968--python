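"""Synthetic layered cortical geometry and OPM sensor arrays.

The laminar-inference problem needs two nested, near-parallel cortical
surfaces (a deep white-matter boundary and a superficial pial surface) with
one-to-one vertex correspondence, a mid-cortical surface for interfering
sources, and a surrounding scalp surface on which magnetometers are packed.
Here those surfaces are nested, smoothly perturbed icospheres: the same
radial bump pattern is applied to every layer, so the layers stay parallel
and the per-vertex layer separation is exactly the difference of the nominal
radii.  This keeps the geometry fully synthetic and seedable while
preserving the layered structure the inference exploits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import ConvexHull

__all__ = [
    "SurfaceMesh",
    "LayeredSourceSpace",
    "SensorArray",
    "RigidTransform",
    "make_head_geometry",
    "pack_sensors",
    "build_channel_axes",
    "offset_sensors",
    "perturb_fiducials",
    "make_alternative_geometry",
]

_UNIT_TOL = 1e-9


@dataclass
class SurfaceMesh:
    """Triangulated surface: vertices in mm, outward unit vertex normals."""

    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray  # (m, 3) int
    vertex_normals: np.ndarray  # (n, 3) unit, outward

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.vertex_normals = np.asarray(self.vertex_normals, dtype=float)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def validate(self) -> None:
        n = self.n_vertices
        if self.faces.min() < 0 or self.faces.max() >= n:
            raise ValueError("face index out of range")
        norms = np.linalg.norm(self.vertex_normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("vertex normals must be unit length")
        v = self.vertices
        a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        areas = 0.5 * np.linalg.norm(np.cross(a, b), axis=1)
        if np.any(areas <= 0):
            raise ValueError("degenerate (zero-area) triangle in mesh")

    def edges(self) -> np.ndarray:
        """Unique undirected edges (k, 2) of the triangulation."""
        f = self.faces
        e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)


@dataclass
class LayeredSourceSpace:
    """White/pial/mid surfaces with identity vertex correspondence."""

    white: SurfaceMesh
    pial: SurfaceMesh
    mid: SurfaceMesh
    # parameters the geometry was built from; carried so that alternative
    # (simulation-side) geometries can be derived from the same generator
    build_params: dict = field(default_factory=dict)

    def validate(self) -> None:
        nw, np_, nm = (
            self.white.n_vertices,
            self.pial.n_vertices,
            self.mid.n_vertices,
        )
        if not (nw == np_ == nm):
            raise ValueError("layer vertex counts differ")
        rw = np.linalg.norm(self.white.vertices, axis=1)
        rp = np.linalg.norm(self.pial.vertices, axis=1)
        rm = np.linalg.norm(self.mid.vertices, axis=1)
        if np.any(rp < rw - 1e-9):
            raise ValueError("pial vertex inside its white partner")
        if np.any((rm < rw - 1e-9) | (rm > rp + 1e-9)):
            raise ValueError("mid vertex not between white and pial")


@dataclass
class RigidTransform:
    rotation: np.ndarray  # (3, 3) orthonormal, det +1
    translation: np.ndarray  # (3,) mm

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply_points(self, p: np.ndarray) -> np.ndarray:
        return p @ self.rotation.T + self.translation

    def apply_vectors(self, v: np.ndarray) -> np.ndarray:
        return v @ self.rotation.T


@dataclass
class SensorArray:
    """Point-magnetometer array on (or offset from) the scalp.

    ``channel_axes`` has shape (n_sensors, n_axes, 3); the first axis of each
    sensor is the radial (outward scalp normal) axis.  ``scalp_points`` are
    the scalp-surface foot points of the sensors, kept so that the
    scalp--sensor offset can be changed exactly along the radial axis.
    """

    positions: np.ndarray  # (n, 3) mm
    radial_axes: np.ndarray  # (n, 3) unit
    channel_axes: np.ndarray  # (n, n_axes, 3) unit, mutually orthogonal
    offset_mm: float
    fiducials: dict  # {"nasion"|"lpa"|"rpa": (3,) mm}
    scalp_points: np.ndarray | None = None
    min_distance_mm: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.radial_axes = np.asarray(self.radial_axes, dtype=float)
        self.channel_axes = np.asarray(self.channel_axes, dtype=float)
        if self.offset_mm < 0:
            raise ValueError("offset must be >= 0")
        fids = np.array(
            [self.fiducials[k] for k in ("nasion", "lpa", "rpa")], dtype=float
        )
        if np.linalg.norm(np.cross(fids[1] - fids[0], fids[2] - fids[0])) < 1e-6:
            raise ValueError("fiducials are collinear")

    @property
    def n_sensors(self) -> int:
        return len(self.positions)

    @property
    def n_axes(self) -> int:
        return self.channel_axes.shape[1]

    @property
    def n_channels(self) -> int:
        return self.n_sensors * self.n_axes

    @property
    def channel_ids(self) -> list[str]:
        return [
            f"s{i:03d}a{j}"
            for i in range(self.n_sensors)
            for j in range(self.n_axes)
        ]

    def fiducial_matrix(self) -> np.ndarray:
        return np.array(
            [self.fiducials[k] for k in ("nasion", "lpa", "rpa")], dtype=float
        )

    def validate(self) -> None:
        for i in range(self.n_sensors):
            axes = self.channel_axes[i]
            gram = axes @ axes.T
            if not np.allclose(gram, np.eye(len(axes)), atol=1e-9):
                raise ValueError(f"sensor {i}: channel axes not orthonormal")
        if self.min_distance_mm is not None and self.n_sensors > 1:
            d = np.linalg.norm(
                self.positions[:, None, :] - self.positions[None, :, :], axis=-1
            )
            np.fill_diagonal(d, np.inf)
            if d.min() < self.min_distance_mm - 1e-9:
                raise ValueError("sensor pair closer than packing distance")

    def take(self, n: int) -> "SensorArray":
        """First ``n`` sensors (packing order), e.g. for a fixed-count array."""
        return dataclasses.replace(
            self,
            positions=self.positions[:n].copy(),
            radial_axes=self.radial_axes[:n].copy(),
            channel_axes=self.channel_axes[:n].copy(),
            scalp_points=None if self.scalp_points is None else self.scalp_points[:n].copy(),
        )


# ---------------------------------------------------------------------------
# geometry construction


def _bump_field(unit_dirs: np.ndarray, seed: int, n_lobes: int = 6) -> np.ndarray:
    """Smooth scalar field on the unit sphere with max |value| = 1.

    A fixed, seeded mixture of broad von-Mises-like lobes; evaluated at any
    set of unit directions, so every layer (and any resampling of the
    sphere) sees the same pattern.
    """
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_lobes, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    amps = rng.uniform(-1.0, 1.0, size=n_lobes)
    f = (amps[None, :] * np.exp((unit_dirs @ dirs.T - 1.0) / 0.25)).sum(axis=1)
    scale = np.abs(f).max()
    if scale > 0:
        f = f / scale
    return f


def _mesh_from_dirs(
    unit_dirs: np.ndarray,
    faces: np.ndarray,
    radius: float,
    bump_amplitude_mm: float,
    bump_seed: int,
) -> SurfaceMesh:
    r = radius + (
        bump_amplitude_mm * _bump_field(unit_dirs, bump_seed)
        if bump_amplitude_mm != 0.0
        else 0.0
    )
    vertices = unit_dirs * np.atleast_1d(r)[:, None]
    tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    normals = np.asarray(tm.vertex_normals, dtype=float).copy()
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    # enforce outward orientation (dot with radial direction positive)
    flip = (normals * unit_dirs).sum(axis=1) < 0
    normals[flip] *= -1.0
    return SurfaceMesh(vertices, faces, normals)


def make_head_geometry(
    white_radius_mm: float = 70.0,
    pial_radius_mm: float = 72.0,
    scalp_radius_mm: float = 85.0,
    subdivisions: int = 4,
    bump_amplitude_mm: float = 0.0,
    seed: int = 0,
) -> tuple[LayeredSourceSpace, SurfaceMesh]:
    """Nested white/pial/mid cortical layers plus a scalp surface.

    All layers are icospheres sharing topology and unit directions; a common
    smooth radial bump (amplitude ``bump_amplitude_mm``) makes them
    non-spherical but parallel.  The default radii give a 2 mm layer
    separation, mirroring human cortical thickness.
    """
    if not (0 < white_radius_mm < pial_radius_mm < scalp_radius_mm):
        raise ValueError("radii must satisfy 0 < white < pial < scalp")
    if subdivisions < 1:
        raise ValueError("subdivisions must be >= 1")

    base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    dirs = np.asarray(base.vertices, dtype=float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    faces = np.asarray(base.faces, dtype=int)

    white = _mesh_from_dirs(dirs, faces, white_radius_mm, bump_amplitude_mm, seed)
    pial = _mesh_from_dirs(dirs, faces, pial_radius_mm, bump_amplitude_mm, seed)
    mid_vertices = 0.5 * (white.vertices + pial.vertices)
    tm_mid = trimesh.Trimesh(vertices=mid_vertices, faces=faces, process=False)
    mid_normals = np.asarray(tm_mid.vertex_normals, dtype=float).copy()
    mid_normals /= np.linalg.norm(mid_normals, axis=1, keepdims=True)
    mid = SurfaceMesh(mid_vertices, faces, mid_normals)

    scalp = _mesh_from_dirs(dirs, faces, scalp_radius_mm, bump_amplitude_mm, seed)

    space = LayeredSourceSpace(
        white=white,
        pial=pial,
        mid=mid,
        build_params=dict(
            white_radius_mm=white_radius_mm,
            pial_radius_mm=pial_radius_mm,
            scalp_radius_mm=scalp_radius_mm,
            subdivisions=subdivisions,
            bump_amplitude_mm=bump_amplitude_mm,
            seed=seed,
        ),
    )
    return space, scalp


# ---------------------------------------------------------------------------
# sensor packing and axes


_FID_DIRS = {
    # canonical fiducial directions on the scalp sphere: nasion towards +y,
    # pre-auricular analogues towards -/+ x
    "nasion": np.array([0.0, 1.0, 0.0]),
    "lpa": np.array([-1.0, 0.0, 0.0]),
    "rpa": np.array([1.0, 0.0, 0.0]),
}


def _place_fiducials(scalp: SurfaceMesh) -> dict:
    dirs = scalp.vertices / np.linalg.norm(scalp.vertices, axis=1, keepdims=True)
    fids = {}
    for name, d in _FID_DIRS.items():
        idx = int(np.argmax(dirs @ d))
        fids[name] = scalp.vertices[idx].copy()
    return fids


def pack_sensors(scalp: SurfaceMesh, min_distance_mm: float, seed: int = 0) -> SensorArray:
    """Greedy maximal packing of sensors on scalp vertices.

    Scalp vertices are scanned in a seeded shuffled order; a vertex becomes a
    sensor site iff it is at least ``min_distance_mm`` from every accepted
    site.  The result is maximal: no remaining vertex can be added.  Each
    sensor starts with a single radial measurement axis (the outward scalp
    normal) and zero scalp offset.
    """
    if min_distance_mm <= 0:
        raise ValueError("min_distance_mm must be > 0")
    if scalp.n_vertices == 0:
        raise ValueError("empty scalp mesh")
    rng = np.random.default_rng(seed)
    order = rng.permutation(scalp.n_vertices)
    accepted: list[int] = []
    pos = scalp.vertices
    for idx in order:
        p = pos[idx]
        if accepted:
            d2 = np.sum((pos[accepted] - p) ** 2, axis=1)
            if d2.min() < min_distance_mm**2:
                continue
        accepted.append(int(idx))
    accepted_arr = np.array(accepted, dtype=int)
    positions = pos[accepted_arr].copy()
    radial = scalp.vertex_normals[accepted_arr].copy()
    return SensorArray(
        positions=positions,
        radial_axes=radial,
        channel_axes=radial[:, None, :].copy(),
        offset_mm=0.0,
        fiducials=_place_fiducials(scalp),
        scalp_points=positions.copy(),
        min_distance_mm=min_distance_mm,
    )


def _tangential_axes(radial: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and second tangential axes for unit radial vectors.

    axis2 = normalize([y, -x, 0]); where that vanishes (radial = +/-z) the
    fallback axis2 = normalize(e_x - (r.e_x) r) keeps the triad defined.
    axis3 = radial x axis2.
    """
    x, y, z = radial[:, 0], radial[:, 1], radial[:, 2]
    t1 = np.stack([y, -x, np.zeros_like(x)], axis=1)
    n1 = np.linalg.norm(t1, axis=1)
    degen = n1 < 1e-12
    if np.any(degen):
        ex = np.zeros_like(radial[degen])
        ex[:, 0] = 1.0
        proj = (radial[degen] * ex).sum(axis=1, keepdims=True)
        fb = ex - proj * radial[degen]
        fb /= np.linalg.norm(fb, axis=1, keepdims=True)
        t1[degen] = fb
        n1 = np.linalg.norm(t1, axis=1)
    t1 = t1 / n1[:, None]
    t2 = np.cross(radial, t1)
    t2 /= np.linalg.norm(t2, axis=1, keepdims=True)
    return t1, t2


def build_channel_axes(array: SensorArray, n_axes: int) -> SensorArray:
    """Attach 1-3 orthonormal measurement axes per sensor (first = radial)."""
    if n_axes not in (1, 2, 3):
        raise ValueError("n_axes must be 1, 2 or 3")
    radial = array.radial_axes
    t1, t2 = _tangential_axes(radial)
    axes = np.stack([radial, t1, t2], axis=1)[:, :n_axes, :]
    return dataclasses.replace(array, channel_axes=axes.copy())


def offset_sensors(
    array: SensorArray, scalp: SurfaceMesh, target_offset_mm: float
) -> SensorArray:
    """Move each sensor along its radial axis to the requested scalp offset."""
    if target_offset_mm < 0:
        raise ValueError("target offset must be >= 0")
    if array.scalp_points is None:
        raise ValueError("array has no scalp foot points; cannot re-offset")
    positions = array.scalp_points + target_offset_mm * array.radial_axes
    return dataclasses.replace(
        array, positions=positions, offset_mm=float(target_offset_mm)
    )


# ---------------------------------------------------------------------------
# co-registration error


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``src`` points onto ``dst``."""
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cd - rot @ cs
    return RigidTransform(rot, trans)


def perturb_fiducials(
    array: SensorArray, sd_mm: float, seed: int = 0
) -> tuple[SensorArray, RigidTransform]:
    """Model co-registration error through fiducial displacement.

    Each of the three fiducials is displaced by iid Gaussian noise
    (sd ``sd_mm`` per coordinate); the least-squares rigid transform from
    the true to the displaced fiducials is applied to the whole array
    (positions and axes), emulating a mis-aligned rigid sensor helmet.
    """
    if sd_mm < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    true_f = array.fiducial_matrix()
    if sd_mm == 0.0:
        return dataclasses.replace(array), RigidTransform.identity()
    displaced = true_f + rng.normal(0.0, sd_mm, size=true_f.shape)
    tf = _kabsch(true_f, displaced)
    new = dataclasses.replace(
        array,
        positions=tf.apply_points(array.positions),
        radial_axes=tf.apply_vectors(array.radial_axes),
        channel_axes=np.einsum("ij,nkj->nki", tf.rotation, array.channel_axes),
        scalp_points=None
        if array.scalp_points is None
        else tf.apply_points(array.scalp_points),
        fiducials={
            "nasion": displaced[0],
            "lpa": displaced[1],
            "rpa": displaced[2],
        },
        min_distance_mm=array.min_distance_mm,
    )
    return new, tf


# ---------------------------------------------------------------------------
# alternative generative model geometry


def _farthest_point_sample(dirs: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Indices of ``n`` approximately uniform points via farthest-point greedy."""
    rng = np.random.default_rng(seed)
    start = int(rng.integers(len(dirs)))
    chosen = [start]
    d2 = np.sum((dirs - dirs[start]) ** 2, axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(d2))
        chosen.append(nxt)
        d2 = np.minimum(d2, np.sum((dirs - dirs[nxt]) ** 2, axis=1))
    return np.array(chosen, dtype=int)


def _hull_faces(unit_dirs: np.ndarray) -> np.ndarray:
    """Outward-wound triangulation of points on the unit sphere."""
    hull = ConvexHull(unit_dirs)
    faces = hull.simplices.copy()
    v = unit_dirs
    centroid_dir = v[faces].mean(axis=1)
    nrm = np.cross(v[faces[:, 1]] - v[faces[:, 0]], v[faces[:, 2]] - v[faces[:, 0]])
    flip = (nrm * centroid_dir).sum(axis=1) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return faces


def make_alternative_geometry(
    space: LayeredSourceSpace,
    array: SensorArray,
    sensor_jitter_sd_mm: float = 1.0,
    alt_vertex_fraction: float | None = None,
    seed: int = 0,
) -> tuple[LayeredSourceSpace, SensorArray]:
    """Simulation-side geometry mismatched to the reconstruction model.

    To avoid the "inverse crime" of simulating and reconstructing with the
    same model, the cortical layers are resampled from a one-level-denser
    icosphere at ``alt_vertex_fraction`` of its vertices (the reconstruction
    mesh corresponds to ~0.25 of it; the default requests 10% more vertices
    than the reconstruction mesh), and the sensor positions receive iid
    Gaussian jitter.  Requesting exactly the reconstruction mesh's vertex
    count with zero jitter returns the inputs unchanged.
    """
    params = space.build_params
    if not params:
        raise ValueError("source space lacks build parameters")
    sub = params["subdivisions"]
    dense = trimesh.creation.icosphere(subdivisions=sub + 1, radius=1.0)
    dense_dirs = np.asarray(dense.vertices, dtype=float)
    dense_dirs /= np.linalg.norm(dense_dirs, axis=1, keepdims=True)
    n_dense = len(dense_dirs)
    n_recon = space.white.n_vertices
    if alt_vertex_fraction is None:
        alt_vertex_fraction = 1.1 * n_recon / n_dense
    if not (0 < alt_vertex_fraction <= 1):
        raise ValueError("alt_vertex_fraction must be in (0, 1]")
    n_alt = int(round(alt_vertex_fraction * n_dense))

    rng = np.random.default_rng(seed)

    if n_alt == n_recon:
        alt_space = space
    else:
        # exclude candidate directions that coincide with the reconstruction
        # mesh: the alternative dipoles must not share source locations
        recon_dirs = space.white.vertices / np.linalg.norm(
            space.white.vertices, axis=1, keepdims=True
        )
        overlap = (dense_dirs @ recon_dirs.T).max(axis=1) > 1.0 - 1e-12
        candidates = dense_dirs[~overlap]
        if n_alt > len(candidates):
            raise ValueError("alt_vertex_fraction too large for the base mesh")
        idx = _farthest_point_sample(candidates, n_alt, seed)
        dirs = candidates[idx]
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        faces = _hull_faces(dirs)
        bseed = params["seed"]
        bamp = params["bump_amplitude_mm"]
        white = _mesh_from_dirs(dirs, faces, params["white_radius_mm"], bamp, bseed)
        pial = _mesh_from_dirs(dirs, faces, params["pial_radius_mm"], bamp, bseed)
        mid_v = 0.5 * (white.vertices + pial.vertices)
        tm_mid = trimesh.Trimesh(vertices=mid_v, faces=faces, process=False)
        mid_n = np.asarray(tm_mid.vertex_normals, dtype=float).copy()
        mid_n /= np.linalg.norm(mid_n, axis=1, keepdims=True)
        alt_space = LayeredSourceSpace(
            white=white,
            pial=pial,
            mid=SurfaceMesh(mid_v, faces, mid_n),
            build_params=dict(params, alt_vertex_fraction=alt_vertex_fraction),
        )

    if sensor_jitter_sd_mm == 0.0:
        alt_array = dataclasses.replace(array)
    else:
        jitter = rng.normal(0.0, sensor_jitter_sd_mm, size=array.positions.shape)
        axes = array.channel_axes.copy()
        # re-orthonormalise per sensor (Gram-Schmidt keeping the radial axis)
        for i in range(len(axes)):
            q, _ = np.linalg.qr(axes[i].T)
            signs = np.sign((q * axes[i].T).sum(axis=0))
            axes[i] = (q * signs).T
        alt_array = dataclasses.replace(
            array,
            positions=array.positions + jitter,
            channel_axes=axes,
            min_distance_mm=None,
        )
    return alt_space, alt_array
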
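"""Slice triangulated stent/aorta surfaces into a gap slice stack.

At every requested axial level the two surfaces are cut by the plane
perpendicular to the device axis and sampled along rays from the axis:
the inner boundary R_i is the *farthest* stent-surface hit (outermost
strut surface), and the outer boundary R_o is the *nearest* aortic-wall
hit beyond it.  A wall hit that falls inside the stent boundary is kept
as a contact station (R_i >= R_o, zero gap).  Lumina that are not
star-shaped with respect to the axis defeat this single-ray sampling
and are flagged, not handled.
"""

from __future__ import annotations

import logging

import numpy as np
import trimesh

from .geometry import SliceStack

__all__ = ["slice_surfaces", "load_surface"]

log = logging.getLogger(__name__)


def load_surface(path) -> trimesh.Trimesh:
    """Load a triangulated surface (STL, binary or ASCII)."""
    mesh = trimesh.load_mesh(path)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise ValueError(f"{path}: not a triangulated surface")
    return mesh


def _axis_frame(axis_origin, axis_direction):
    """Rotation matrix whose third row is the (unit) axis direction."""
    d = np.asarray(axis_direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("axis direction must be non-zero")
    d = d / norm
    # seed chosen so the default +z axis yields the identity frame
    seed = np.array([0.0, 1.0, 0.0]) if abs(d[1]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(seed, d)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return np.stack([u, v, d])


def _section_segments(vertices: np.ndarray, faces: np.ndarray, z: float) -> np.ndarray:
    """2-D segments of the plane-z cross-section, shape (S, 2, 2)."""
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    seg3 = trimesh.intersections.mesh_plane(
        mesh, plane_normal=[0.0, 0.0, 1.0], plane_origin=[0.0, 0.0, z]
    )
    if len(seg3) == 0:
        return np.empty((0, 2, 2))
    return np.asarray(seg3)[:, :, :2]


def _ray_hits(segments: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Positive distances along a ray from the origin to segment crossings."""
    if segments.size == 0:
        return np.empty(0)
    a = segments[:, 0]
    d = segments[:, 1] - segments[:, 0]
    u = direction
    # solve a + s*d = t*u (ray origin at 0): cross-product elimination
    denom = u[0] * d[:, 1] - u[1] * d[:, 0]
    ok = np.abs(denom) > 1e-300
    a, d, denom = a[ok], d[ok], denom[ok]
    s = (a[:, 0] * u[1] - a[:, 1] * u[0]) / denom
    t = (a[:, 0] * d[:, 1] - a[:, 1] * d[:, 0]) / denom
    hit = (s >= -1e-9) & (s <= 1 + 1e-9) & (t > 1e-12)
    return np.unique(t[hit])


def slice_surfaces(
    stent_surface: trimesh.Trimesh,
    aorta_surface: trimesh.Trimesh,
    z_levels: np.ndarray,
    n_theta: int = 256,
    axis_origin=(0.0, 0.0, 0.0),
    axis_direction=(0.0, 0.0, 1.0),
) -> SliceStack:
    """Sample both surfaces on rays from the axis at every level.

    Raises when a ray misses either surface (naming the (θ, z) station);
    odd per-ray intersection counts (non-watertight patches) are logged
    as warnings and resolved by the farthest-stent / nearest-wall rule.
    """
    z_levels = np.asarray(z_levels, dtype=float)
    frame = _axis_frame(axis_origin, axis_direction)
    origin = np.asarray(axis_origin, dtype=float)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    dirs = np.stack([np.cos(theta), np.sin(theta)], axis=1)

    vs = (np.asarray(stent_surface.vertices) - origin) @ frame.T
    va = (np.asarray(aorta_surface.vertices) - origin) @ frame.T

    K = z_levels.size
    R_i = np.empty((K, n_theta))
    R_o = np.empty((K, n_theta))
    for k, z in enumerate(z_levels):
        seg_s = _section_segments(vs, stent_surface.faces, z)
        seg_a = _section_segments(va, aorta_surface.faces, z)
        if seg_s.size == 0 or seg_a.size == 0:
            which = "stent" if seg_s.size == 0 else "aorta"
            raise ValueError(f"{which} surface does not intersect the plane z={z:g}")
        for j in range(n_theta):
            ts = _ray_hits(seg_s, dirs[j])
            ta = _ray_hits(seg_a, dirs[j])
            if ts.size == 0:
                raise ValueError(
                    f"ray at theta={theta[j]:.4f}, z={z:g} misses the stent surface"
                )
            if ta.size == 0:
                raise ValueError(
                    f"ray at theta={theta[j]:.4f}, z={z:g} misses the aorta surface"
                )
            if ts.size % 2 or ta.size % 2:
                log.warning(
                    "odd intersection count at theta=%.4f, z=%g "
                    "(non-watertight surface?); using nearest-pair fallback",
                    theta[j],
                    z,
                )
            r_i = ts.max()
            beyond = ta[ta >= r_i - 1e-12]
            r_o = beyond.min() if beyond.size else ta.max()  # contact if none beyond
            R_i[k, j] = r_i
            R_o[k, j] = r_o
    return SliceStack(z=z_levels, theta=theta, inner_radius=R_i, outer_radius=R_o)
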
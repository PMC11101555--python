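"""Paravalvular-gap geometry: slice stacks and mid-gap shell meshes.

The gap between the stent frame and the aortic wall is described by a
*slice stack*: at each axial height ``z_k`` the inner (stent) boundary
``R_i(θ)`` and the outer (wall) boundary ``R_o(θ)`` are sampled at a common
set of angular stations.  Contact between stent and wall is encoded as
``R_i >= R_o``; the effective gap ``h = max(R_o - R_i, 0)`` is never
negative.

A stack is lofted into a triangulated *mid-gap shell mesh*: one node per
(θ, z) station placed at the radial midpoint ``r_m = (R_i + R_o)/2``,
carrying the local gap width ``h`` as a nodal field.  The Reynolds solver
operates on this mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SliceStack",
    "ShellMesh",
    "build_midgap_mesh",
    "slice_area",
    "leakage_volume",
]

_TWO_PI = 2.0 * np.pi


@dataclass(eq=False)
class SliceStack:
    """Ordered axial cross-sections of the paravalvular gap (SI units, m).

    Parameters
    ----------
    z : (K,) array
        Strictly increasing axial coordinates of the slices.
    theta : (n,) array
        Angular stations in [0, 2π), strictly increasing, shared by all
        slices.
    inner_radius : (K, n) array
        Stent boundary radius R_i(z_k, θ_j) >= 0.
    outer_radius : (K, n) array
        Aortic-wall boundary radius R_o(z_k, θ_j) >= 0.  Stations with
        ``inner_radius >= outer_radius`` are contact stations.
    """

    z: np.ndarray
    theta: np.ndarray
    inner_radius: np.ndarray
    outer_radius: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.inner_radius = np.atleast_2d(np.asarray(self.inner_radius, dtype=float))
        self.outer_radius = np.atleast_2d(np.asarray(self.outer_radius, dtype=float))
        if self.z.ndim != 1 or self.z.size < 1:
            raise ValueError("z must be a 1-D array with at least one slice")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z must be strictly increasing")
        if self.theta.ndim != 1 or self.theta.size < 3:
            raise ValueError("at least 3 angular stations are required")
        if np.any(np.diff(self.theta) <= 0):
            raise ValueError("theta must be strictly increasing")
        if self.theta[0] < 0 or self.theta[-1] >= _TWO_PI:
            raise ValueError("theta stations must lie in [0, 2*pi)")
        shape = (self.z.size, self.theta.size)
        if self.inner_radius.shape != shape or self.outer_radius.shape != shape:
            raise ValueError(
                f"radius arrays must have shape {shape}, got "
                f"{self.inner_radius.shape} and {self.outer_radius.shape}"
            )
        if np.any(self.inner_radius < 0) or np.any(self.outer_radius < 0):
            raise ValueError("radii must be non-negative")

    # -- derived quantities -------------------------------------------------

    @property
    def n_slices(self) -> int:
        return self.z.size

    @property
    def n_theta(self) -> int:
        return self.theta.size

    @property
    def gap(self) -> np.ndarray:
        """Effective gap h = max(R_o - R_i, 0), shape (K, n)."""
        return np.maximum(self.outer_radius - self.inner_radius, 0.0)

    @property
    def h_max(self) -> np.ndarray:
        """Maximum gap of every slice, shape (K,)."""
        return self.gap.max(axis=1)

    @property
    def axial_length(self) -> float:
        return float(self.z[-1] - self.z[0])

    @property
    def theta_weights(self) -> np.ndarray:
        """Periodic trapezoid weights over the angular stations (sum 2π)."""
        dtheta = np.diff(self.theta, append=self.theta[0] + _TWO_PI)
        return 0.5 * (dtheta + np.roll(dtheta, 1))

    @property
    def axial_weights(self) -> np.ndarray:
        """Midpoint-rule weights Δl_k (half spacing at the ends; sum = L)."""
        if self.n_slices == 1:
            return np.zeros(1)
        dz = np.diff(self.z)
        w = np.empty(self.n_slices)
        w[0] = 0.5 * dz[0]
        w[-1] = 0.5 * dz[-1]
        w[1:-1] = 0.5 * (dz[:-1] + dz[1:])
        return w

    def areas(self) -> np.ndarray:
        """Cross-sectional gap area of every slice, shape (K,)."""
        integrand = 0.5 * np.maximum(
            self.outer_radius**2 - self.inner_radius**2, 0.0
        )
        return integrand @ self.theta_weights


def slice_area(stack: SliceStack, k: int) -> float:
    """Gap cross-sectional area of slice ``k``.

    A = ∮ ½ max(R_o² − R_i², 0) dθ by the periodic composite trapezoid
    rule over the angular stations; zero on fully occluded slices.
    """
    return float(stack.areas()[k])


def leakage_volume(stack: SliceStack) -> float:
    """Total gap volume V = Σ_k A_k Δl_k (midpoint axial weights)."""
    if stack.n_slices < 2:
        raise ValueError("leakage volume requires at least 2 slices")
    return float(stack.areas() @ stack.axial_weights)


@dataclass(eq=False)
class ShellMesh:
    """Triangulated mid-gap surface carrying the nodal gap field.

    Parameters
    ----------
    points : (N, 3) array
        Node coordinates (m).
    triangles : (M, 3) int array
        Triangle connectivity.
    h : (N,) array
        Nodal gap width (m), >= 0.
    inlet, outlet : int arrays
        Disjoint, non-empty boundary node sets.  The inlet is the
        high-pressure (aortic) side, the outlet the ventricular side.
    """

    points: np.ndarray
    triangles: np.ndarray
    h: np.ndarray
    inlet: np.ndarray
    outlet: np.ndarray
    area_tol: float = field(default=1e-18, repr=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.h = np.asarray(self.h, dtype=float)
        self.inlet = np.unique(np.asarray(self.inlet, dtype=np.int64))
        self.outlet = np.unique(np.asarray(self.outlet, dtype=np.int64))
        n = self.points.shape[0]
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (N, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (M, 3)")
        if self.triangles.min(initial=0) < 0 or self.triangles.max(initial=-1) >= n:
            raise ValueError("triangle indices out of range")
        if self.h.shape != (n,):
            raise ValueError("h must have one value per node")
        if np.any(self.h < 0):
            raise ValueError("nodal gap h must be non-negative")
        if self.inlet.size == 0 or self.outlet.size == 0:
            raise ValueError("inlet and outlet node sets must be non-empty")
        if np.intersect1d(self.inlet, self.outlet).size:
            raise ValueError("inlet and outlet node sets must be disjoint")
        used = np.zeros(n, dtype=bool)
        used[self.triangles.ravel()] = True
        if not used.all():
            orphans = np.flatnonzero(~used)
            raise ValueError(f"nodes not referenced by any triangle: {orphans[:10]}")
        areas = self.triangle_areas()
        if np.any(areas <= self.area_tol):
            bad = np.flatnonzero(areas <= self.area_tol)
            raise ValueError(f"degenerate triangles (area <= tol): {bad[:10]}")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def triangle_areas(self) -> np.ndarray:
        p = self.points[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)


def build_midgap_mesh(stack: SliceStack) -> ShellMesh:
    """Loft a slice stack into the mid-gap shell mesh.

    One node per (θ_j, z_k) station at radius r_m = (R_i + R_o)/2 (at
    contact stations this is the midpoint of the clamped pair), with
    nodal gap ``h = max(R_o − R_i, 0)`` taken from the stack without
    smoothing.  Quads between adjacent stations are split into two
    triangles; the seam at θ = 2π is closed periodically without
    duplicating nodes.  Inlet = top slice (largest z, aortic side),
    outlet = bottom slice.
    """
    if stack.n_slices < 2:
        raise ValueError("meshing requires at least 2 slices")
    K, n = stack.n_slices, stack.n_theta
    r_m = 0.5 * (stack.inner_radius + stack.outer_radius)
    if np.any(r_m <= 0):
        raise ValueError("mid-gap radius must be positive at every station")
    cos_t, sin_t = np.cos(stack.theta), np.sin(stack.theta)
    points = np.empty((K * n, 3))
    points[:, 0] = (r_m * cos_t).ravel()
    points[:, 1] = (r_m * sin_t).ravel()
    points[:, 2] = np.repeat(stack.z, n)
    h = stack.gap.ravel()

    j = np.arange(n)
    j2 = (j + 1) % n
    tris = []
    for k in range(K - 1):
        a = k * n + j
        b = k * n + j2
        c = (k + 1) * n + j2
        d = (k + 1) * n + j
        tris.append(np.stack([a, b, c], axis=1))
        tris.append(np.stack([a, c, d], axis=1))
    triangles = np.concatenate(tris, axis=0)

    outlet = np.arange(n)               # bottom slice (smallest z)
    inlet = (K - 1) * n + np.arange(n)  # top slice (largest z)
    return ShellMesh(points=points, triangles=triangles, h=h, inlet=inlet, outlet=outlet)
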
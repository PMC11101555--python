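"""Parametric gap geometries with known closed-form behaviour.

These generators stand in for segmented patient or bench geometries in
every test: concentric and eccentric annular dies, annuli carrying
calcification nodules (ISO 5840 bench nodule: 2.0 mm radial protrusion,
4.0 mm circumferential extent), and flat "pocket" channels with a
controlled gap gradient.  All functions are deterministic: identical
parameters give bit-identical output.

Lengths are accepted in metres (SI), consistent with the rest of the
package; the CLI converts from millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ShellMesh, SliceStack

__all__ = [
    "NoduleSpec",
    "make_annular_die",
    "make_eccentric_annulus",
    "make_nodule_annulus",
    "make_pocket_channel",
]

_TWO_PI = 2.0 * np.pi


def _theta_stations(n_theta: int) -> np.ndarray:
    return np.linspace(0.0, _TWO_PI, n_theta, endpoint=False)


@dataclass(frozen=True)
class NoduleSpec:
    """A calcification nodule protruding from the stent boundary.

    theta_center : angular position of the crest (rad)
    radial_protrusion : crest height d_r above the base inner radius (m)
    circumferential_extent : full arc length d_c of the bump (m)
    axial_center, axial_extent : centre and full axial span of the bump (m)
    """

    theta_center: float
    radial_protrusion: float
    circumferential_extent: float
    axial_center: float
    axial_extent: float

    def __post_init__(self) -> None:
        if self.radial_protrusion <= 0:
            raise ValueError("radial_protrusion must be positive")
        if self.circumferential_extent <= 0:
            raise ValueError("circumferential_extent must be positive")
        if self.axial_extent <= 0:
            raise ValueError("axial_extent must be positive")


def make_annular_die(
    R_i: float,
    R_o: float,
    L: float,
    n_theta: int = 256,
    n_slices: int = 64,
) -> SliceStack:
    """Uniform concentric annulus spanning [0, L]; gap h = R_o − R_i."""
    if not (0 < R_i < R_o):
        raise ValueError("need 0 < R_i < R_o")
    if L <= 0:
        raise ValueError("L must be positive")
    theta = _theta_stations(n_theta)
    z = np.linspace(0.0, L, n_slices)
    inner = np.full((n_slices, n_theta), R_i)
    outer = np.full((n_slices, n_theta), R_o)
    return SliceStack(z=z, theta=theta, inner_radius=inner, outer_radius=outer)


def make_eccentric_annulus(
    R_i: float,
    R_o: float,
    e: float,
    L: float,
    n_theta: int = 256,
    n_slices: int = 64,
) -> SliceStack:
    """Inner circle offset by ``e`` along θ=0; gap varies smoothly in θ.

    Measured from the outer-circle centre, the inner boundary is
    R_i(θ) = e·cosθ + sqrt(R_i² − e² sin²θ); the gap is widest at θ = π
    (R_o − R_i + e) and narrowest at θ = 0 (R_o − R_i − e, i.e. tangency
    when e = R_o − R_i).
    """
    if e < 0:
        raise ValueError("offset e must be non-negative")
    if e > R_i:
        raise ValueError("offset must not exceed the inner radius")
    if e + R_i > R_o:
        raise ValueError("inner circle must stay inside the outer circle (e + R_i <= R_o)")
    if L <= 0:
        raise ValueError("L must be positive")
    theta = _theta_stations(n_theta)
    z = np.linspace(0.0, L, n_slices)
    r_in = e * np.cos(theta) + np.sqrt(R_i**2 - (e * np.sin(theta)) ** 2)
    inner = np.tile(r_in, (n_slices, 1))
    outer = np.full((n_slices, n_theta), R_o)
    return SliceStack(z=z, theta=theta, inner_radius=inner, outer_radius=outer)


def _wrap_angle(dtheta: np.ndarray) -> np.ndarray:
    return (dtheta + np.pi) % _TWO_PI - np.pi


def make_nodule_annulus(
    R_i: float,
    R_o: float,
    L: float,
    nodules: list[NoduleSpec],
    n_theta: int = 256,
    n_slices: int = 64,
) -> SliceStack:
    """Concentric annulus with cosine-bump nodules raised on the stent side.

    Each nodule raises R_i locally by up to its radial protrusion with a
    separable cosine bump over its circumferential arc and axial extent;
    overlapping nodules combine by the pointwise maximum.  Where a bump
    reaches past R_o the station becomes a contact station (gap 0).
    """
    base = make_annular_die(R_i, R_o, L, n_theta=n_theta, n_slices=n_slices)
    if not nodules:
        return base
    theta = base.theta
    z = base.z
    bump_total = np.zeros((n_slices, n_theta))
    for nod in nodules:
        if not (0 <= nod.axial_center <= L):
            raise ValueError("nodule axial_center must lie within [0, L]")
        half_arc_angle = 0.5 * nod.circumferential_extent / R_i
        u_t = np.abs(_wrap_angle(theta - nod.theta_center)) / half_arc_angle
        u_z = np.abs(z - nod.axial_center) / (0.5 * nod.axial_extent)
        bt = np.where(u_t < 1.0, 0.5 * (1.0 + np.cos(np.pi * np.clip(u_t, 0, 1))), 0.0)
        bz = np.where(u_z < 1.0, 0.5 * (1.0 + np.cos(np.pi * np.clip(u_z, 0, 1))), 0.0)
        bump = nod.radial_protrusion * np.outer(bz, bt)
        bump_total = np.maximum(bump_total, bump)
    return SliceStack(
        z=z,
        theta=theta,
        inner_radius=base.inner_radius + bump_total,
        outer_radius=base.outer_radius,
    )


def iso5840_nodule(
    theta_center: float = 0.0,
    axial_center: float = 0.0,
    axial_extent: float = 4.0e-3,
) -> NoduleSpec:
    """The ISO 5840 bench calcification nodule (d_r = 2 mm, d_c = 4 mm)."""
    return NoduleSpec(
        theta_center=theta_center,
        radial_protrusion=2.0e-3,
        circumferential_extent=4.0e-3,
        axial_center=axial_center,
        axial_extent=axial_extent,
    )


def make_pocket_channel(
    width: float,
    length: float,
    h_base: float,
    h_pocket: float,
    pocket_extent: tuple[float, float, float, float],
    transition_length: float,
    n_x: int = 96,
    n_y: int = 32,
) -> ShellMesh:
    """Flat rectangular strip with a rectangular pocket of deeper gap.

    The strip lies in the plane z = 0 with the flow (x) axis spanning
    [0, length] and the transverse (y) axis spanning [0, width]; the
    inlet is the short end at x = 0, the outlet at x = length.  Inside
    ``pocket_extent`` = (x0, x1, y0, y1) the gap is ``h_pocket``; it
    ramps linearly back to ``h_base`` over ``transition_length``, so the
    largest gap gradient is (h_pocket − h_base)/transition_length.
    """
    if not (h_pocket >= h_base > 0):
        raise ValueError("need h_pocket >= h_base > 0")
    if transition_length <= 0:
        raise ValueError("transition_length must be positive")
    x0, x1, y0, y1 = pocket_extent
    if not (x0 < x1 and y0 < y1):
        raise ValueError("pocket_extent must be a non-empty (x0, x1, y0, y1) box")
    x = np.linspace(0.0, length, n_x)
    y = np.linspace(0.0, width, n_y)
    X, Y = np.meshgrid(x, y, indexing="ij")
    # distance outside the pocket rectangle
    dx = np.maximum(np.maximum(x0 - X, X - x1), 0.0)
    dy = np.maximum(np.maximum(y0 - Y, Y - y1), 0.0)
    d = np.hypot(dx, dy)
    ramp = np.clip(1.0 - d / transition_length, 0.0, 1.0)
    h = h_base + (h_pocket - h_base) * ramp

    points = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    idx = np.arange(n_x * n_y).reshape(n_x, n_y)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d4 = idx[:-1, 1:].ravel()
    triangles = np.concatenate(
        [np.stack([a, b, c], axis=1), np.stack([a, c, d4], axis=1)], axis=0
    )
    return ShellMesh(
        points=points,
        triangles=triangles,
        h=h.ravel(),
        inlet=idx[0, :],
        outlet=idx[-1, :],
    )
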
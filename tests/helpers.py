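"""Independent oracles used by the test suite.

``network_flow_rate`` is a finite-volume / resistor-network solver of
the lubrication equation on the structured (θ, z) grid of a slice
stack.  It shares no code with the finite-element path in
``pvleak.reynolds``: nodes are joined by edge conductances
g = c · (control width) / (edge length) with c = h³/(12μ) at the edge
midpoint, and the Kirchhoff system is solved directly.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from pvleak.geometry import SliceStack


def network_flow_rate(stack: SliceStack, mu: float, dp: float, eps: float = 1e-9) -> float:
    """Flow rate (m³/s) through the mid-gap surface, top→bottom, by FV."""
    K, n = stack.n_slices, stack.n_theta
    r_m = 0.5 * (stack.inner_radius + stack.outer_radius)
    h = np.maximum(stack.gap, eps)
    x = r_m * np.cos(stack.theta)
    y = r_m * np.sin(stack.theta)
    z = np.broadcast_to(stack.z[:, None], (K, n))
    idx = np.arange(K * n).reshape(K, n)
    wz = stack.axial_weights          # axial control widths
    wt = stack.theta_weights          # angular control widths

    rows, cols, g = [], [], []

    def add_edges(i_a, i_b, cond):
        rows.append(i_a.ravel())
        cols.append(i_b.ravel())
        g.append(cond.ravel())

    # circumferential edges (k, j) -- (k, j+1 mod n)
    jp = (np.arange(n) + 1) % n
    dx = x[:, jp] - x
    dy = y[:, jp] - y
    length = np.hypot(dx, dy)
    c_edge = (0.5 * (h + h[:, jp])) ** 3 / (12.0 * mu)
    add_edges(idx, idx[:, jp], c_edge * wz[:, None] / length)

    # axial edges (k, j) -- (k+1, j)
    dxa = x[1:] - x[:-1]
    dya = y[1:] - y[:-1]
    dza = z[1:] - z[:-1]
    length_a = np.sqrt(dxa**2 + dya**2 + dza**2)
    c_a = (0.5 * (h[1:] + h[:-1])) ** 3 / (12.0 * mu)
    width_a = 0.5 * (r_m[1:] + r_m[:-1]) * wt[None, :]
    add_edges(idx[:-1], idx[1:], c_a * width_a / length_a)

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    g = np.concatenate(g)
    N = K * n
    L = sp.coo_array(
        (np.concatenate([g, g, -g, -g]),
         (np.concatenate([rows, cols, rows, cols]),
          np.concatenate([rows, cols, cols, rows]))),
        shape=(N, N),
    ).tocsr()

    top = idx[-1]
    bottom = idx[0]
    dirichlet = np.concatenate([top, bottom])
    vals = np.concatenate([np.full(n, dp), np.zeros(n)])
    free = np.setdiff1d(np.arange(N), dirichlet)
    p = np.zeros(N)
    p[dirichlet] = vals
    A = L[free][:, free]
    b = -L[free][:, dirichlet] @ vals
    p[free] = spla.spsolve(A.tocsc(), b)
    residual = L @ p
    return float(residual[top].sum())
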
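"""Trilinear hexahedral element utilities: shape functions, Gauss rules,
isoparametric gradients and Jacobians.

Node ordering follows the VTK hexahedron convention: nodes 0-3 are the
bottom face counter-clockwise (viewed from +z), nodes 4-7 the top face.
"""

from __future__ import annotations

import numpy as np

# reference-element corner signs, VTK hex ordering
XI_NODES = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)


def shape_functions(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions N_a(xi) for points xi (..., 3) -> (..., 8)."""
    xi = np.asarray(xi, dtype=float)
    return np.prod(1.0 + xi[..., None, :] * XI_NODES, axis=-1) / 8.0


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN_a/dxi at points xi (..., 3) -> (..., 8, 3)."""
    xi = np.asarray(xi, dtype=float)
    terms = 1.0 + xi[..., None, :] * XI_NODES  # (..., 8, 3)
    out = np.empty(terms.shape)
    for d in range(3):
        prod = np.prod(np.delete(terms, d, axis=-1), axis=-1)
        out[..., d] = XI_NODES[:, d] * prod
    return out / 8.0


def gauss_points(order: int = 2):
    """Tensor-product Gauss rule on [-1,1]^3: points (n^3, 3), weights (n^3,).

    Points are ordered with the z (axial) coordinate varying slowest, so
    points [0:n^2] share the lowest z-level; this ordering is relied on when
    stacking axial Gauss columns for the rupture run-length criterion.
    """
    x, w = np.polynomial.legendre.leggauss(order)
    pts = np.array([[a, b, c] for c in x for b in x for a in x])
    wts = np.array([wc * wb * wa for wc in w for wb in w for wa in w])
    return pts, wts


def jacobians(node_coords: np.ndarray, hexes: np.ndarray, xi_pts: np.ndarray):
    """Reference Jacobians for all elements at the given points.

    Returns ``detJ`` (Ne, npts) and ``gradN`` (Ne, npts, 8, 3), the shape
    function gradients with respect to the element's physical coordinates.
    """
    dN = shape_gradients(xi_pts)  # (npts, 8, 3)
    Xe = node_coords[hexes]  # (Ne, 8, 3)
    # J[e,g,i,j] = dX_i/dxi_j = sum_a Xe[e,a,i] dN[g,a,j]
    J = np.einsum("eai,gaj->egij", Xe, dN)
    detJ = np.linalg.det(J)
    Jinv = np.linalg.inv(J)
    gradN = np.einsum("gaj,egji->egai", dN, Jinv)
    return detJ, gradN


def gauss_coords(node_coords: np.ndarray, hexes: np.ndarray, xi_pts: np.ndarray):
    """Physical coordinates of the given reference points in every element."""
    N = shape_functions(xi_pts)  # (npts, 8)
    return np.einsum("ga,eai->egi", N, node_coords[hexes])
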
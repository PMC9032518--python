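"""Shared P1 simplex finite-element kernels.

Linear (P1) shape functions on triangles / tetrahedra with a single
quadrature point per element.  All routines are vectorised over elements.
"""
from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "shape_gradients",
    "element_volumes",
    "lumped_mass",
    "stiffness_matrix",
    "deformation_gradients",
]


def element_volumes(nodes: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Signed areas (2D) or volumes (3D) of the simplices."""
    dim = nodes.shape[1]
    v = nodes[simplices[:, 1:]] - nodes[simplices[:, [0]]]
    if dim == 2:
        det = v[:, 0, 0] * v[:, 1, 1] - v[:, 0, 1] * v[:, 1, 0]
        return det / 2.0
    det = np.linalg.det(v)
    return det / 6.0


def shape_gradients(nodes: np.ndarray, simplices: np.ndarray):
    """Gradients of the P1 shape functions.

    Returns ``(grads, vols)`` with ``grads`` of shape
    ``(n_elem, dim + 1, dim)`` (constant per element) and ``vols`` the
    signed measures.
    """
    n_elem, nv = simplices.shape
    dim = nodes.shape[1]
    # Edge matrix J with rows x_a - x_0, a = 1..dim; grad N_a rows of J^{-T}.
    J = nodes[simplices[:, 1:]] - nodes[simplices[:, [0]]]
    Jinv = np.linalg.inv(J)
    grads = np.empty((n_elem, nv, dim))
    grads[:, 1:, :] = np.transpose(Jinv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    vols = element_volumes(nodes, simplices)
    return grads, vols


def lumped_mass(nodes: np.ndarray, simplices: np.ndarray,
                density: np.ndarray | float = 1.0) -> np.ndarray:
    """Row-sum lumped mass: each vertex receives measure/(dim+1)."""
    vols = np.abs(element_volumes(nodes, simplices))
    nv = simplices.shape[1]
    contrib = np.broadcast_to(
        (vols * np.asarray(density)) [:, None] / nv, simplices.shape)
    m = np.zeros(len(nodes))
    np.add.at(m, simplices, contrib)
    return m


def stiffness_matrix(nodes: np.ndarray, simplices: np.ndarray,
                     coeff: np.ndarray | float = 1.0) -> sp.csr_matrix:
    """Assemble int coeff grad u . grad v with piecewise-constant coeff."""
    grads, vols = shape_gradients(nodes, simplices)
    vols = np.abs(vols)
    c = np.broadcast_to(np.asarray(coeff, dtype=float), vols.shape)
    ke = np.einsum("e,eai,ebi->eab", c * vols, grads, grads)
    nv = simplices.shape[1]
    rows = np.repeat(simplices, nv, axis=1).ravel()
    cols = np.tile(simplices, (1, nv)).ravel()
    n = len(nodes)
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n))
    return K.tocsr()


def deformation_gradients(grads: np.ndarray, simplices: np.ndarray,
                          u: np.ndarray) -> np.ndarray:
    """Per-element F = I + sum_a u_a (grad N_a)^T for nodal displacements u."""
    dim = grads.shape[2]
    F = np.einsum("eai,eaj->eij", u[simplices], grads)
    F += np.eye(dim)[None, :, :]
    return F
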
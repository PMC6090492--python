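"""Linear-elastic finite elements on the hexahedral construct mesh.

Element: standard 8-node isoparametric trilinear hexahedron, 2x2x2 Gauss
quadrature, with a mean-dilatation (B-bar) treatment of the volumetric strain
term.  The collagen hydrogel is nearly incompressible (Poisson ratio 0.45)
and fully integrated trilinear bricks lock volumetrically in that regime;
projecting the volumetric part of the strain-displacement operator onto its
element mean removes the spurious stiffness while leaving constant-strain
states (and hence the patch test) exact.

Strain is recovered at the element centroid from the compatible
strain-displacement operator, giving one small-strain tensor per 1-mm cube —
the granularity at which the cell agents sample their mechanical environment.

Quantities are SI: coordinates in metres, forces in Newtons, moduli in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import HexMesh, _CORNERS

__all__ = [
    "MaterialModel",
    "assemble_stiffness",
    "solve_displacements",
    "compute_strain",
    "StrainField",
    "principal_strain",
    "principal_guidance",
]

# corner signs (+-1) for the trilinear shape functions, VTK ordering
_XI = 2.0 * _CORNERS.astype(float) - 1.0
_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)
# 2x2x2 Gauss points, unit weights
_GAUSS = np.array([[a, b, c] for c in _GP for b in _GP for a in _GP])


@dataclass(frozen=True)
class MaterialModel:
    """Isotropic linear-elastic constants of the collagen hydrogel.

    Defaults are the construct gel values: elastic modulus 100 kPa, Poisson
    ratio 0.45 (near-incompressible), density 1100 kg/m^3.  Density is stored
    for completeness but plays no role in the quasi-static equilibrium solves.
    """

    elastic_modulus: float = 100e3  # Pa
    poisson_ratio: float = 0.45
    density: float = 1100.0  # kg/m^3

    def __post_init__(self):
        if self.elastic_modulus <= 0:
            raise ValueError("elastic_modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError(
                "poisson_ratio must lie in [0, 0.5); the incompressible limit "
                "is not supported by the displacement formulation"
            )
        if self.density <= 0:
            raise ValueError("density must be positive")

    @property
    def lame_lambda(self) -> float:
        E, nu = self.elastic_modulus, self.poisson_ratio
        return E * nu / ((1 + nu) * (1 - 2 * nu))

    @property
    def shear_modulus(self) -> float:
        return self.elastic_modulus / (2 * (1 + self.poisson_ratio))

    def d_matrix(self) -> np.ndarray:
        """6x6 elasticity matrix in Voigt order (xx, yy, zz, xy, yz, zx),
        engineering shear strains."""
        lam, mu = self.lame_lambda, self.shear_modulus
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.diag_indices(3)] += 2 * mu
        D[3, 3] = D[4, 4] = D[5, 5] = mu
        return D


def _dN_dxi(points: np.ndarray) -> np.ndarray:
    """Shape-function gradients w.r.t. natural coords at given points.

    Returns array of shape (n_points, 8, 3)."""
    pts = np.atleast_2d(points)
    xi, eta, zeta = pts[:, 0:1], pts[:, 1:2], pts[:, 2:3]
    sx, sy, sz = _XI[:, 0], _XI[:, 1], _XI[:, 2]
    g = np.empty((pts.shape[0], 8, 3))
    g[:, :, 0] = 0.125 * sx * (1 + eta * sy) * (1 + zeta * sz)
    g[:, :, 1] = 0.125 * sy * (1 + xi * sx) * (1 + zeta * sz)
    g[:, :, 2] = 0.125 * sz * (1 + xi * sx) * (1 + eta * sy)
    return g


def shape_functions(points: np.ndarray) -> np.ndarray:
    """Trilinear shape-function values, shape (n_points, 8)."""
    pts = np.atleast_2d(points)
    return 0.125 * (
        (1 + pts[:, 0:1] * _XI[:, 0])
        * (1 + pts[:, 1:2] * _XI[:, 1])
        * (1 + pts[:, 2:3] * _XI[:, 2])
    )


_DN_GAUSS = _dN_dxi(_GAUSS)  # (8 gp, 8 nodes, 3)
_DN_CENTROID = _dN_dxi(np.zeros((1, 3)))  # (1, 8, 3)


def _physical_gradients(elem_coords: np.ndarray, dN: np.ndarray):
    """Shape-function gradients in physical coordinates.

    Parameters
    ----------
    elem_coords : (E, 8, 3) nodal coordinates per element
    dN : (G, 8, 3) natural gradients at G evaluation points

    Returns
    -------
    dNdx : (E, G, 8, 3), detJ : (E, G)
    """
    # J[e,g,i,j] = d x_j / d xi_i
    J = np.einsum("gai,eaj->egij", dN, elem_coords)
    detJ = np.linalg.det(J)
    Jinv = np.linalg.inv(J)
    dNdx = np.einsum("gai,egij->egaj", dN, Jinv)
    return dNdx, detJ


def _b_matrices(dNdx: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices, shape (E, G, 6, 24).

    Voigt rows (xx, yy, zz, xy, yz, zx) with engineering shear; DOF columns
    interleaved (node0_x, node0_y, node0_z, node1_x, ...).
    """
    E, G = dNdx.shape[:2]
    B = np.zeros((E, G, 6, 24))
    dx, dy, dz = dNdx[..., 0], dNdx[..., 1], dNdx[..., 2]
    B[:, :, 0, 0::3] = dx
    B[:, :, 1, 1::3] = dy
    B[:, :, 2, 2::3] = dz
    B[:, :, 3, 0::3] = dy
    B[:, :, 3, 1::3] = dx
    B[:, :, 4, 1::3] = dz
    B[:, :, 4, 2::3] = dy
    B[:, :, 5, 0::3] = dz
    B[:, :, 5, 2::3] = dx
    return B


def element_stiffness(
    elem_coords: np.ndarray, material: MaterialModel, *, b_bar: bool = True
) -> np.ndarray:
    """Element stiffness matrices for a batch of hexahedra, (E, 24, 24)."""
    elem_coords = np.asarray(elem_coords, dtype=float)
    if elem_coords.ndim == 2:
        elem_coords = elem_coords[None]
    dNdx, detJ = _physical_gradients(elem_coords, _DN_GAUSS)
    if np.any(detJ <= 0):
        bad = int(np.argwhere(detJ <= 0)[0, 0])
        raise ValueError(f"degenerate (inverted) element geometry at element {bad}")
    B = _b_matrices(dNdx)
    if b_bar:
        vol = detJ.sum(axis=1)  # unit Gauss weights
        bvol = B[:, :, 0, :] + B[:, :, 1, :] + B[:, :, 2, :]  # (E, G, 24)
        bvol_bar = np.einsum("eg,egk->ek", detJ, bvol) / vol[:, None]
        corr = (bvol_bar[:, None, :] - bvol) / 3.0
        for r in range(3):
            B[:, :, r, :] += corr
    D = material.d_matrix()
    Ke = np.einsum("eg,egki,kl,eglj->eij", detJ, B, D, B, optimize=True)
    return Ke


def assemble_stiffness(
    mesh: HexMesh,
    material: MaterialModel,
    *,
    node_coords: np.ndarray | None = None,
    b_bar: bool = True,
) -> sp.csr_matrix:
    """Assemble the global stiffness operator (sparse CSR, symmetric).

    ``node_coords`` overrides the mesh's reference coordinates so the operator
    can be rebuilt on a deformed geometry.  No boundary conditions are applied
    here: the free operator annihilates all six rigid-body modes.
    """
    coords = mesh.node_coords if node_coords is None else np.asarray(node_coords)
    elem_coords = coords[mesh.elements]  # (E, 8, 3)
    Ke = element_stiffness(elem_coords, material, b_bar=b_bar)

    dof = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(-1, 24)
    rows = np.repeat(dof, 24, axis=1).ravel()
    cols = np.tile(dof, (1, 24)).ravel()
    n = 3 * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    # enforce exact symmetry against round-off in assembly order
    K = (K + K.T) * 0.5
    return K


def _free_dof_mask(n_nodes: int, fixed_node_set: np.ndarray) -> np.ndarray:
    mask = np.ones(3 * n_nodes, dtype=bool)
    fixed = np.asarray(fixed_node_set, dtype=np.intp)
    mask[(3 * fixed[:, None] + np.arange(3)).ravel()] = False
    return mask


def solve_displacements(
    stiffness: sp.spmatrix,
    nodal_forces: np.ndarray,
    fixed_node_set: np.ndarray,
    *,
    factor=None,
) -> np.ndarray:
    """Solve constrained equilibrium ``K u = f`` with fixed nodes clamped.

    Parameters
    ----------
    stiffness : (3N, 3N) sparse operator from :func:`assemble_stiffness`.
    nodal_forces : (N, 3) applied nodal forces in Newtons.
    fixed_node_set : node indices clamped to zero displacement in all three
        components.
    factor : optional pre-computed LU factor of the reduced operator
        (see :func:`factorize`); reused across solves on a fixed geometry.

    Returns
    -------
    (N, 3) nodal displacements in metres; exactly zero on fixed nodes.
    """
    f = np.asarray(nodal_forces, dtype=float)
    n_nodes = f.shape[0]
    fixed = np.asarray(fixed_node_set, dtype=np.intp)
    if fixed.size == 0:
        raise ValueError(
            "insufficient constraints: empty fixed node set leaves the "
            "stiffness singular (rigid-body modes)"
        )
    free = _free_dof_mask(n_nodes, fixed)
    if factor is None:
        factor = factorize(stiffness, fixed_node_set, n_nodes)
    u = np.zeros(3 * n_nodes)
    u[free] = factor(f.ravel()[free])
    return u.reshape(n_nodes, 3)


def factorize(stiffness: sp.spmatrix, fixed_node_set: np.ndarray, n_nodes: int):
    """LU-factorise the constrained operator; returns a solve callable."""
    free = _free_dof_mask(n_nodes, np.asarray(fixed_node_set, dtype=np.intp))
    Kff = stiffness.tocsr()[free][:, free].tocsc()
    try:
        lu = spla.splu(Kff)
    except RuntimeError as exc:  # pragma: no cover - singular operator
        raise ValueError(f"constrained stiffness is singular: {exc}") from exc
    return lu.solve


@dataclass
class StrainField:
    """Per-element small-strain state evaluated at element centroids.

    ``tensors`` are the symmetric 3x3 strain tensors; ``values`` their
    eigenvalues sorted descending with matching unit ``directions`` (columns),
    both per element.
    """

    tensors: np.ndarray  # (E, 3, 3)
    values: np.ndarray  # (E, 3) descending
    directions: np.ndarray  # (E, 3, 3), directions[e, :, k] pairs values[e, k]

    @property
    def max_abs(self) -> np.ndarray:
        """Largest-magnitude principal strain per element."""
        return np.abs(self.values).max(axis=1)


def compute_strain(
    mesh: HexMesh,
    displacements: np.ndarray,
    *,
    node_coords: np.ndarray | None = None,
) -> StrainField:
    """Small-strain tensors eps = sym(grad u) at element centroids.

    The gradient is taken with respect to the geometry the displacement
    increment was solved on (``node_coords``, defaulting to the reference
    mesh), via the element shape-function gradients at the centroid.
    """
    coords = mesh.node_coords if node_coords is None else np.asarray(node_coords)
    elem_coords = coords[mesh.elements]
    dNdx, detJ = _physical_gradients(elem_coords, _DN_CENTROID)
    if np.any(detJ <= 0):
        bad = int(np.argwhere(detJ <= 0)[0, 0])
        raise ValueError(f"degenerate (inverted) element geometry at element {bad}")
    u_elem = np.asarray(displacements)[mesh.elements]  # (E, 8, 3)
    grad = np.einsum("eaj,eGai->eij", u_elem, dNdx)  # du_j/dx_i -> (E,3,3)
    eps = 0.5 * (grad + grad.transpose(0, 2, 1))
    values, directions = _eig_descending(eps)
    return StrainField(tensors=eps, values=values, directions=directions)


def _canonical_sign(vectors: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Flip vectors so the first component exceeding ``tol`` is positive."""
    v = np.asarray(vectors, dtype=float)
    flat = v.reshape(-1, 3)
    use0 = np.abs(flat[:, 0]) > tol
    use1 = ~use0 & (np.abs(flat[:, 1]) > tol)
    lead = np.where(use0, flat[:, 0], np.where(use1, flat[:, 1], flat[:, 2]))
    flat = np.where(lead[:, None] < 0, -flat, flat)
    return flat.reshape(v.shape)


def _eig_descending(tensors: np.ndarray):
    """Batched symmetric eigen-decomposition, values descending, canonical
    eigenvector signs."""
    w, v = np.linalg.eigh(tensors)  # ascending
    w = w[..., ::-1]
    v = v[..., ::-1]
    # canonicalise column signs: operate per eigenvector
    v = np.stack(
        [_canonical_sign(v[..., :, k]) for k in range(3)], axis=-1
    )
    return w, v


def principal_strain(tensor: np.ndarray, *, sym_tol: float = 1e-8):
    """Principal strains of one symmetric 3x3 tensor.

    Returns ``(values, directions)`` with eigenvalues sorted descending and
    unit eigenvectors as the columns of ``directions``, sign-fixed so each
    eigenvector's first nonzero component is positive.  For repeated
    eigenvalues the decomposition is the deterministic one produced by the
    symmetric eigensolver under this sign convention (an isotropic tensor
    yields the coordinate axes).

    Raises ``ValueError`` if the input is not symmetric within ``sym_tol``
    (relative to its norm).
    """
    t = np.asarray(tensor, dtype=float)
    if t.shape != (3, 3):
        raise ValueError("tensor must be 3x3")
    scale = max(np.abs(t).max(), 1.0)
    if np.abs(t - t.T).max() > sym_tol * scale:
        raise ValueError("tensor is not symmetric within tolerance")
    t = 0.5 * (t + t.T)
    w, v = _eig_descending(t[None])
    return w[0], v[0]


def principal_guidance(
    field: StrainField,
    *,
    mode: str = "tensile",
    rel_tol: float = 1e-6,
):
    """Per-element cell-guidance direction from the principal strain state.

    Cells in a tethered contracting gel align along the principal strain
    direction.  Two conventions are supported for which eigenpair carries the
    cue:

    - ``"tensile"`` (default): the algebraically largest eigenvalue.  In a
      construct whose ends are fixed, contraction is resisted axially, so the
      largest (least compressive) principal direction runs along the long
      axis away from the clamped corners — the direction of relative tension.
    - ``"magnitude"``: the largest-absolute eigenvalue (dominant compression
      in this problem).

    Returns ``(directions, degenerate)``: unit axial vectors (E, 3) with the
    canonical sign convention, and a boolean mask of elements whose relevant
    eigenvalue is (nearly) repeated or whose strain is numerically zero —
    there the cue is undefined and callers should leave agents unchanged.
    """
    w = field.values  # (E, 3) descending
    scale = np.abs(w).max(axis=1)
    tiny = scale < 1e-30
    safe = np.where(tiny, 1.0, scale)
    if mode == "tensile":
        k = np.zeros(w.shape[0], dtype=np.intp)
        gap = w[:, 0] - w[:, 1]
    elif mode == "magnitude":
        absw = np.abs(w)
        order = np.argsort(absw, axis=1)
        k = order[:, 2]
        gap = absw[np.arange(len(w)), order[:, 2]] - absw[np.arange(len(w)), order[:, 1]]
    else:
        raise ValueError(f"unknown guidance mode {mode!r}")
    degenerate = tiny | (gap <= rel_tol * safe)
    dirs = np.take_along_axis(
        field.directions, k[:, None, None], axis=2
    )[:, :, 0]
    return dirs, degenerate
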
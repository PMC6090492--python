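"""Structured hexahedral meshing of the cuboidal construct.

The construct occupies ``[0, Lx] x [0, Ly] x [0, Lz]`` with the origin at a
corner, x the long axis, y the width and z the thickness.  It is discretised
into identical axis-aligned cube elements of edge ``element_size``.  Node ids
run x-fastest: ``node(ix, iy, iz) = ix + (nx+1)*(iy + (ny+1)*iz)`` for a grid
of ``nx × ny × nz`` elements.  Element corner ordering follows the VTK
hexahedron convention (bottom face counter-clockwise, then top face).

All lengths are metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HexMesh", "build_mesh"]

# local corner offsets (VTK_HEXAHEDRON ordering)
_CORNERS = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [1, 1, 1],
        [0, 1, 1],
    ],
    dtype=np.intp,
)


@dataclass
class HexMesh:
    """Structured grid of 8-node hexahedra with the two x-extreme faces fixed.

    Attributes
    ----------
    node_coords : (n_nodes, 3) float array
        Undeformed (reference) nodal positions in metres.
    elements : (n_elements, 8) int array
        Node indices per hexahedron, VTK corner ordering.
    fixed_node_set : (n_fixed,) int array
        Nodes on the x = 0 and x = Lx faces, clamped in all three components.
    element_size : float
        Cube edge length in metres.
    shape : (3,) tuple
        Element counts (nx, ny, nz) along each axis.
    extents : (3,) float array
        Construct dimensions (Lx, Ly, Lz) in metres.
    """

    node_coords: np.ndarray
    elements: np.ndarray
    fixed_node_set: np.ndarray
    element_size: float
    shape: tuple[int, int, int]
    extents: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def node_grid_shape(self) -> tuple[int, int, int]:
        nx, ny, nz = self.shape
        return nx + 1, ny + 1, nz + 1

    def element_index(self, ex, ey, ez):
        """Flattened element id for grid indices (x fastest)."""
        nx, ny, _ = self.shape
        return ex + nx * (ey + ny * np.asarray(ez))

    def top_face_elements(self) -> np.ndarray:
        """Element ids of the top layer (maximum z), used for the top view."""
        nx, ny, nz = self.shape
        ex, ey = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        return self.element_index(ex.ravel(), ey.ravel(), nz - 1)


def build_mesh(extents, element_size: float, *, rtol: float = 1e-9) -> HexMesh:
    """Mesh the cuboidal construct into cube elements.

    Parameters
    ----------
    extents : length-3 sequence of floats
        Construct dimensions (Lx, Ly, Lz) in metres; each must be a positive
        integer multiple of ``element_size`` (within ``rtol``).
    element_size : float
        Edge length of the cube elements in metres.

    Returns
    -------
    HexMesh

    Raises
    ------
    ValueError
        If an extent is not commensurate with the element size; the message
        names the offending axis.
    """
    extents = np.asarray(extents, dtype=float)
    if extents.shape != (3,) or np.any(extents <= 0):
        raise ValueError("extents must be three positive lengths")
    if element_size <= 0:
        raise ValueError("element_size must be positive")

    counts = []
    for axis, name in enumerate("xyz"):
        ratio = extents[axis] / element_size
        n = int(round(ratio))
        if n < 1 or abs(ratio - n) > rtol * max(ratio, 1.0):
            raise ValueError(
                f"extent along {name} ({extents[axis]:g} m) is not an integer "
                f"multiple of element_size ({element_size:g} m)"
            )
        counts.append(n)
    nx, ny, nz = counts

    xs = np.arange(nx + 1) * element_size
    ys = np.arange(ny + 1) * element_size
    zs = np.arange(nz + 1) * element_size
    # x fastest in the flattened node ordering
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    node_coords = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    ex, ey, ez = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    # flatten with x fastest
    ex = ex.transpose(2, 1, 0).ravel()
    ey = ey.transpose(2, 1, 0).ravel()
    ez = ez.transpose(2, 1, 0).ravel()

    def node_id(ix, iy, iz):
        return ix + (nx + 1) * (iy + (ny + 1) * iz)

    elements = np.empty((nx * ny * nz, 8), dtype=np.intp)
    for c, (dx, dy, dz) in enumerate(_CORNERS):
        elements[:, c] = node_id(ex + dx, ey + dy, ez + dz)

    ix = node_coords[:, 0]
    fixed = np.flatnonzero(
        (np.abs(ix) < 0.5 * element_size)
        | (np.abs(ix - extents[0]) < 0.5 * element_size)
    )

    return HexMesh(
        node_coords=node_coords,
        elements=elements,
        fixed_node_set=fixed,
        element_size=float(element_size),
        shape=(nx, ny, nz),
        extents=extents,
    )
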
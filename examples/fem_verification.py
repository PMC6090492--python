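"""Verify the hexahedral finite-element core on classical benchmarks.

Three standard checks of a displacement-based element formulation:

1. rigid-body modes: a free element must have exactly six zero-energy modes
   (three translations, three rotations);
2. the patch test: a linear displacement field prescribed on the boundary is
   reproduced exactly in the interior, with the exact constant strain;
3. the uniaxial bar: tip displacement sigma*L/E under uniform end traction.
"""

import numpy as np
import scipy.sparse.linalg as spla

from constructsim import (
    MaterialModel,
    assemble_stiffness,
    build_mesh,
    compute_strain,
    solve_displacements,
)

material = MaterialModel()  # collagen gel: 100 kPa, nu = 0.45

# 1. rigid-body modes of one 1-mm cube
element = build_mesh((0.001, 0.001, 0.001), 0.001)
w = np.linalg.eigvalsh(assemble_stiffness(element, material).toarray())
n_zero = int(np.sum(np.abs(w) < 1e-9 * w[-1]))
print(f"zero-energy modes of a free element: {n_zero} (expect 6)")

# 2. patch test on a 2x2x2-element cube
mesh = build_mesh((0.002, 0.002, 0.002), 0.001)
A = np.array([[1e-3, 2e-4, -1e-4], [2e-4, -5e-4, 3e-4], [-1e-4, 3e-4, 4e-4]])
u_exact = mesh.node_coords @ A.T
c, eps = mesh.node_coords, 1e-12
boundary = np.flatnonzero(
    (c < eps).any(axis=1) | (c > 0.002 - eps).any(axis=1)
)
K = assemble_stiffness(mesh, material).tocsr()
free = np.ones(3 * mesh.n_nodes, bool)
free[(3 * boundary[:, None] + np.arange(3)).ravel()] = False
u = u_exact.ravel().copy()
u[free] = spla.spsolve(K[free][:, free].tocsc(), -(K[free][:, ~free] @ u[~free]))
field = compute_strain(mesh, u.reshape(-1, 3))
err = np.abs(field.tensors - 0.5 * (A + A.T)).max()
print(f"patch-test strain error: {err:.2e} (machine precision expected)")

# 3. uniaxial bar, nu = 0 so the closed form sigma*L/E is exact
bar = build_mesh((0.010, 0.001, 0.001), 0.001)
mat0 = MaterialModel(poisson_ratio=0.0)
Kb = assemble_stiffness(bar, mat0)
sigma, L = 100.0, 0.010
tip = np.flatnonzero(bar.node_coords[:, 0] > L - 1e-12)
f = np.zeros((bar.n_nodes, 3))
f[tip, 0] = sigma * 1e-6 / len(tip)
fixed = np.flatnonzero(bar.node_coords[:, 0] < 1e-12)
ub = solve_displacements(Kb, f, fixed)
print(
    f"bar tip displacement: {ub[tip, 0].mean():.6e} m "
    f"(closed form {sigma * L / mat0.elastic_modulus:.6e} m)"
)
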
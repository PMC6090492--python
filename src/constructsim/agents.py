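"""Muscle-derived cells as contractile, strain-following agents.

Each agent is a particle with a position inside the construct and an axial
orientation (a unit vector with v and -v physically equivalent — a cell has
no head or tail).  An agent stands for ``cells_per_agent`` real cells, so a
population of 60 000 agents at 100 cells per agent carries the full
contractile load of the 6 million cells seeded in the 7.2 mL construct while
staying cheap to simulate; the effective force per agent is
``cells_per_agent * force_per_cell``.

Behavioural rules are deliberately minimal: (1) agents reorient to the local
principal-strain guidance direction each coupling step, and (2) each cell
exerts a contractile force of 1.0 nN (the midpoint of the 0.1–10 nN range
reported for single cells in collagen matrices), represented mechanically as
a self-equilibrated force dipole along the agent's axis.  There is no
proliferation, death, or active migration: agents move only by advecting with
the deforming gel.

Agent positions are tracked in the material (reference) frame of the
undeformed construct.  Because the gel deforms continuously and agents move
with it, an agent's material coordinates are constant through a run; its
spatial position at any time is the isoparametric image of those coordinates
under the current mesh geometry.  This makes advection exact and element
lookup a closed-form floor operation on the structured grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .fem import StrainField, principal_guidance, shape_functions
from .mesh import HexMesh

__all__ = ["AgentPopulation", "init_agents", "reorient_agents", "agent_contraction"]

#: default single-cell contractile force, Newtons
DEFAULT_FORCE_PER_CELL = 1.0e-9


@dataclass
class AgentPopulation:
    """State of the cell agents.

    Attributes
    ----------
    positions : (n, 3) float array
        Material-frame positions in metres, inside the undeformed construct.
    orientations : (n, 3) float array
        Unit axial orientation vectors (v equivalent to -v).
    cells_per_agent : int
        Number of real cells each agent represents.
    force_per_cell : float
        Contractile force of one cell in Newtons.
    """

    positions: np.ndarray
    orientations: np.ndarray
    cells_per_agent: int
    force_per_cell: float = DEFAULT_FORCE_PER_CELL

    @property
    def n_agents(self) -> int:
        return self.positions.shape[0]

    @property
    def force_per_agent(self) -> float:
        return self.cells_per_agent * self.force_per_cell

    def spatial_positions(
        self, mesh: HexMesh, node_coords: np.ndarray | None = None
    ) -> np.ndarray:
        """Current physical positions under the (possibly deformed) geometry.

        Interpolates the given nodal coordinates at each agent's material
        point with the element shape functions.  With the reference
        coordinates this returns ``positions`` itself.
        """
        from .coupling import locate_agents  # local import: no cycle at runtime

        coords = mesh.node_coords if node_coords is None else node_coords
        elem, xi = locate_agents(self, mesh)
        N = shape_functions(xi)  # (n, 8)
        return np.einsum("na,naj->nj", N, coords[mesh.elements[elem]])


def init_agents(
    mesh: HexMesh,
    total_cells: int,
    cells_per_agent: int = 100,
    force_per_cell: float = DEFAULT_FORCE_PER_CELL,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> AgentPopulation:
    """Seed agents uniformly at random in the construct volume.

    Positions are uniform in the cuboid; orientations are uniform axial
    directions (isotropic on the sphere, with the two hemispheres
    identified).  Fully reproducible from ``seed``.

    ``total_cells`` should be divisible by ``cells_per_agent``; otherwise the
    agent count is rounded down with a warning and the represented cell count
    is ``n_agents * cells_per_agent``.
    """
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or generator) is required for reproducibility")
        rng = np.random.default_rng(seed)
    if total_cells <= 0 or cells_per_agent <= 0:
        raise ValueError("total_cells and cells_per_agent must be positive")
    n_agents, rem = divmod(int(total_cells), int(cells_per_agent))
    if rem:
        warnings.warn(
            f"total_cells={total_cells} is not divisible by "
            f"cells_per_agent={cells_per_agent}; simulating "
            f"{n_agents * cells_per_agent} cells",
            stacklevel=2,
        )
    if n_agents == 0:
        raise ValueError("configuration yields zero agents")

    extents = mesh.extents
    positions = rng.uniform(0.0, 1.0, size=(n_agents, 3)) * extents
    orientations = _random_axial(rng, n_agents)
    return AgentPopulation(
        positions=positions,
        orientations=orientations,
        cells_per_agent=int(cells_per_agent),
        force_per_cell=float(force_per_cell),
    )


def _random_axial(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform axial unit vectors (Gaussian sphere trick)."""
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def reorient_agents(
    pop: AgentPopulation,
    field: StrainField,
    element_of: np.ndarray,
    *,
    mode: str = "tensile",
) -> AgentPopulation:
    """Realign every agent with its element's principal-strain guidance axis.

    Agents in elements whose strain offers no preferred direction (zero or
    repeated relevant eigenvalues) keep their previous orientation.
    Reorientation is instantaneous and complete — the simplest kinetics
    consistent with alignment emerging within the first simulated day — and
    is therefore idempotent on a fixed strain field.
    """
    element_of = np.asarray(element_of, dtype=np.intp)
    if element_of.shape[0] != pop.n_agents:
        raise ValueError("element_of must map every agent")
    if element_of.min(initial=0) < 0 or element_of.max(initial=0) >= len(field.values):
        bad = int(
            np.flatnonzero(
                (element_of < 0) | (element_of >= len(field.values))
            )[0]
        )
        raise ValueError(f"agent {bad} is not mapped to a valid element")
    dirs, degenerate = principal_guidance(field, mode=mode)
    cue = ~degenerate[element_of]
    new_orient = pop.orientations.copy()
    new_orient[cue] = dirs[element_of[cue]]
    return replace(pop, orientations=new_orient)


def agent_contraction(pop: AgentPopulation) -> np.ndarray:
    """Contractile force dipole of each agent.

    Returns an (n, 2, 3) array: for each agent, the forces applied at the two
    ends of its axis (the end on the +orientation side first).  Each end pulls
    toward the agent's centre with magnitude ``force_per_agent / 2``, so every
    dipole — and hence the whole population — sums to exactly zero force.
    """
    F = pop.force_per_agent
    half = 0.5 * F * pop.orientations  # (n, 3)
    return np.stack([-half, half], axis=1)
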
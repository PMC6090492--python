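"""The hourly two-scale coupling loop between cells and construct.

Each coupling step runs, in order:

1. the contractile dipoles of all agents are turned into a global nodal
   force vector (momentum-free by construction; see
   :func:`assemble_agent_loads`);
2. the quasi-static equilibrium of the construct under those loads is solved
   on the current geometry with both x-extreme faces clamped;
3. the construct's strain state — the small-strain tensor of the *total*
   deformation accumulated since day 0 — and its principal directions are
   recovered at element centroids;
4. agents reorient to their element's guidance direction;
5. with the geometry update enabled, the incremental displacements are added
   to the node coordinates (an updated-Lagrangian scheme: each hour is an
   independent small-strain solve, and permanence of contraction is carried
   entirely by the accumulated geometry) and agents advect with the material;
6. a metric record (footprint area, alignment, strain summary) is appended.

Guidance from the accumulated rather than the hourly-incremental strain is
deliberate: once cells align axially between fixed ends, the *incremental*
field they generate is nearly pure noise (axial contraction is blocked and
the transverse active stress vanishes with alignment), so an
increment-guided population disorders itself again.  The deformation state
of the construct retains the frozen-in lateral contraction and provides a
stable cue, which is also what an hourly re-solve of the full problem on the
original geometry would report.

Numerical notes.  Loads change every step but the stiffness operator only
changes with geometry; the operator (with its sparse LU factor and the
load-integration tensors) is rebuilt lazily, once any node has moved by more
than ``reassembly_drift`` element lengths since the last assembly.  Agent
bookkeeping is in the material frame (see :mod:`constructsim.agents`), so
element lookup is closed-form on the structured grid and advection with the
gel is exact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import metrics as _metrics
from .agents import (
    AgentPopulation,
    DEFAULT_FORCE_PER_CELL,
    agent_contraction,
    init_agents,
    reorient_agents,
)
from .fem import (
    MaterialModel,
    StrainField,
    _DN_GAUSS,
    _b_matrices,
    _free_dof_mask,
    _physical_gradients,
    assemble_stiffness,
    compute_strain,
    factorize,
    shape_functions,
)
from .mesh import HexMesh, build_mesh

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "locate_agents",
    "assemble_agent_loads",
    "FemContext",
    "init_state",
    "step",
    "run",
]

logger = logging.getLogger(__name__)

DAY = 86400.0


@dataclass(frozen=True)
class SimulationConfig:
    """Complete, SI-unit description of one simulation run.

    The defaults reproduce the reference construct: a 30 x 20 x 12 mm
    collagen gel meshed into 1-mm cubes, E = 100 kPa, nu = 0.45, six million
    cells of 1.0 nN contractility represented 100-to-1 by agents, one
    coupling step per hour for seven days, with incremental geometry update.
    ``seed`` is mandatory: all randomness (initial agent placement and
    orientation) derives from it.

    ``load_mode`` selects how cell forces reach the mesh: ``"element"``
    (default) aggregates the dipoles of all cells within each 1-mm cube into
    one element-level active stress before assembling equivalent nodal
    loads; ``"dipole"`` splats each agent's two endpoint forces individually
    (see :func:`assemble_agent_loads`).  ``guidance_mode`` picks the
    principal-strain eigenpair cells follow (see
    :func:`constructsim.fem.principal_guidance`).
    """

    seed: int
    extents: tuple[float, float, float] = (0.030, 0.020, 0.012)  # m
    element_size: float = 0.001  # m
    material: MaterialModel = field(default_factory=MaterialModel)
    total_cells: int = 6_000_000
    cells_per_agent: int = 100
    force_per_cell: float = DEFAULT_FORCE_PER_CELL  # N
    timestep: float = 3600.0  # s
    duration: float = 7 * DAY  # s
    geometry_update: bool = True
    snapshot_days: tuple[float, ...] = (0.0, 1.0, 4.0, 7.0)
    guidance_mode: str = "tensile"
    load_mode: str = "element"
    reassembly_drift: float = 1e-3  # node drift triggering re-assembly,
    # in units of element_size

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.total_cells < 0:
            raise ValueError("total_cells must be non-negative")
        if self.load_mode not in ("element", "dipole"):
            raise ValueError(f"unknown load_mode {self.load_mode!r}")

    @property
    def n_steps(self) -> int:
        ratio = self.duration / self.timestep
        n = int(ratio + 1e-9)
        if abs(ratio - n) > 1e-9:
            warnings.warn(
                f"duration is not an integer number of timesteps; running "
                f"{n} steps",
                stacklevel=2,
            )
        return n


@dataclass
class SimulationState:
    """Mutable state advanced by :func:`step`.

    ``node_coords`` is the current (deformed) geometry; the mesh object keeps
    the undeformed reference.  ``snapshots`` maps snapshot time (seconds) to
    a dict with deep-copied geometry, agent spatial state and the total
    strain field at that time.
    """

    mesh: HexMesh
    node_coords: np.ndarray
    population: AgentPopulation
    step_index: int = 0
    history: list = field(default_factory=list)
    snapshots: dict = field(default_factory=dict)
    last_strain: StrainField | None = None

    @property
    def total_displacement(self) -> np.ndarray:
        return self.node_coords - self.mesh.node_coords

    def history_frame(self):
        """Metric history as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame([r.as_dict() for r in self.history])


def locate_agents(pop: AgentPopulation, mesh: HexMesh):
    """Map each agent to its containing element and natural coordinates.

    Works in the material frame on the structured reference grid, so the
    element index is closed-form: along each axis, a coordinate strictly
    inside cell k maps to k, and a coordinate exactly on a shared face is
    assigned to the lower-index element.  Points outside the construct (only
    possible through round-off) are clamped to the nearest face and logged.

    Returns ``(element_ids, natural_coords)`` with natural coordinates in
    [-1, 1]^3.
    """
    return _locate_points(pop.positions, mesh)


def _locate_points(points: np.ndarray, mesh: HexMesh, *, warn: bool = True):
    pts = np.asarray(points, dtype=float)
    h = mesh.element_size
    n_axis = np.asarray(mesh.shape)
    outside = (pts < 0) | (pts > mesh.extents)
    if np.any(outside):
        if warn:
            logger.warning(
                "%d point coordinates outside the construct; clamped to the "
                "nearest face",
                int(outside.sum()),
            )
        pts = np.clip(pts, 0.0, mesh.extents)
    # ceil(p/h) - 1: interior points -> floor(p/h); shared-face points -> the
    # lower-index neighbour; p = 0 -> element 0 after clamping
    idx = np.ceil(pts / h).astype(np.intp) - 1
    idx = np.clip(idx, 0, n_axis - 1)
    xi = 2.0 * (pts / h - idx) - 1.0
    xi = np.clip(xi, -1.0, 1.0)
    elem = mesh.element_index(idx[:, 0], idx[:, 1], idx[:, 2])
    return elem, xi


def _load_integrals(mesh: HexMesh, node_coords: np.ndarray):
    """Per-element volumes and integrated strain-displacement operators
    (E, 24, 6) used to turn an element active stress into nodal forces."""
    ec = np.asarray(node_coords)[mesh.elements]
    dNdx, detJ = _physical_gradients(ec, _DN_GAUSS)
    B = _b_matrices(dNdx)
    BTint = np.einsum("eg,egka->eak", detJ, B)
    return detJ.sum(axis=1), BTint


def _element_dipole_tensors(pop: AgentPopulation, mesh: HexMesh) -> np.ndarray:
    """Aggregate dipole-moment tensor per element, Voigt (E, 6).

    Each agent contributes a contractile dipole moment ``F_agent * d``
    (d = element size, the coupling length) times its orientation outer
    product, summed over the agents inside each cube — the discrete analogue
    of integrating the cell forces within the cube.
    """
    elem, _ = locate_agents(pop, mesh)
    v = pop.orientations
    Fd = pop.force_per_agent * mesh.element_size
    voigt = np.stack(
        [
            v[:, 0] * v[:, 0],
            v[:, 1] * v[:, 1],
            v[:, 2] * v[:, 2],
            v[:, 0] * v[:, 1],
            v[:, 1] * v[:, 2],
            v[:, 2] * v[:, 0],
        ],
        axis=1,
    )
    M = np.empty((mesh.n_elements, 6))
    for c in range(6):
        M[:, c] = np.bincount(
            elem, weights=Fd * voigt[:, c], minlength=mesh.n_elements
        )
    return M


def _scatter_element_forces(mesh: HexMesh, fe: np.ndarray) -> np.ndarray:
    """Sum per-element 24-vectors of nodal forces into the global (N, 3)."""
    loads = np.zeros((mesh.n_nodes, 3))
    nodes = mesh.elements.ravel()
    fe3 = fe.reshape(-1, 8, 3)
    for c in range(3):
        loads[:, c] = np.bincount(
            nodes, weights=fe3[:, :, c].ravel(), minlength=mesh.n_nodes
        )
    return loads


def assemble_agent_loads(
    pop: AgentPopulation,
    mesh: HexMesh,
    *,
    node_coords: np.ndarray | None = None,
    mode: str = "element",
    arm: float | None = None,
) -> np.ndarray:
    """Global nodal force vector from all agent contraction dipoles.

    ``mode="element"`` (default): the dipole tensors of the cells inside
    each cube are summed into one element-level active stress (dipole moment
    density), whose equivalent nodal forces are assembled with the element's
    integrated strain-displacement operator on the current geometry.  This
    is the cube-granular coupling — the force within each unit cube is what
    the construct model sees — and it is free of the spurious point-load
    near-fields of individual dipoles.

    ``mode="dipole"``: each agent's endpoint forces (at position +- arm/2
    along its orientation, arm defaulting to the element size) are spread
    onto the nodes of each endpoint's containing element with trilinear
    shape-function weights.  Endpoints falling outside the construct are
    clamped onto its surface.

    Either way the result, shape (n_nodes, 3), sums to zero to round-off,
    and flipping any agent's orientation leaves it unchanged (v and -v are
    the same axis).
    """
    if pop.n_agents == 0:
        return np.zeros((mesh.n_nodes, 3))
    if mode == "element":
        coords = mesh.node_coords if node_coords is None else node_coords
        vol, BTint = _load_integrals(mesh, coords)
        M = _element_dipole_tensors(pop, mesh)
        fe = -np.einsum("eak,ek->ea", BTint, M / vol[:, None])
        return _scatter_element_forces(mesh, fe)
    if mode == "dipole":
        if arm is None:
            arm = mesh.element_size
        loads = np.zeros((mesh.n_nodes, 3))
        forces = agent_contraction(pop)  # (n, 2, 3): [+end, -end]
        offsets = 0.5 * arm * pop.orientations
        for sign, f in ((+1.0, forces[:, 0]), (-1.0, forces[:, 1])):
            pts = pop.positions + sign * offsets
            elem, xi = _locate_points(pts, mesh, warn=False)
            N = shape_functions(xi)  # (n, 8)
            contrib = N[:, :, None] * f[:, None, :]  # (n, 8, 3)
            nodes = mesh.elements[elem].ravel()
            for c in range(3):
                loads[:, c] += np.bincount(
                    nodes, weights=contrib[:, :, c].ravel(), minlength=mesh.n_nodes
                )
        return loads
    raise ValueError(f"unknown load mode {mode!r}")


class FemContext:
    """Caches geometry-dependent operators across coupling steps.

    The stiffness, its LU factor and the load-integration tensors are built
    on a given geometry and re-used until any node has drifted more than
    ``drift * element_size`` from that geometry, then rebuilt.  With the
    reference cell forces the hourly geometry increments are far below an
    element length, so a run performs only a handful of factorisations.
    """

    def __init__(
        self, mesh: HexMesh, material: MaterialModel, *, drift: float = 1e-3
    ):
        self.mesh = mesh
        self.material = material
        self.drift = drift
        self._coords_at_assembly: np.ndarray | None = None
        self._solve = None
        self._vol = None
        self._BTint = None
        self._free = _free_dof_mask(mesh.n_nodes, mesh.fixed_node_set)
        self.n_assemblies = 0

    def ensure(self, node_coords: np.ndarray) -> None:
        if self._solve is not None:
            delta = np.abs(node_coords - self._coords_at_assembly).max()
            if delta <= self.drift * self.mesh.element_size:
                return
        K = assemble_stiffness(self.mesh, self.material, node_coords=node_coords)
        self._solve = factorize(K, self.mesh.fixed_node_set, self.mesh.n_nodes)
        self._vol, self._BTint = _load_integrals(self.mesh, node_coords)
        self._coords_at_assembly = node_coords.copy()
        self.n_assemblies += 1

    def element_loads(self, pop: AgentPopulation, node_coords: np.ndarray):
        """Cube-aggregated loads using the cached integration tensors."""
        self.ensure(node_coords)
        M = _element_dipole_tensors(pop, self.mesh)
        fe = -np.einsum("eak,ek->ea", self._BTint, M / self._vol[:, None])
        return _scatter_element_forces(self.mesh, fe)

    def solve(self, node_coords: np.ndarray, loads: np.ndarray) -> np.ndarray:
        self.ensure(node_coords)
        u = np.zeros(3 * self.mesh.n_nodes)
        u[self._free] = self._solve(loads.ravel()[self._free])
        return u.reshape(-1, 3)


def init_state(config: SimulationConfig) -> SimulationState:
    """Build mesh and population for a run and record the t = 0 metrics."""
    mesh = build_mesh(config.extents, config.element_size)
    if config.total_cells == 0:
        pop = AgentPopulation(
            positions=np.empty((0, 3)),
            orientations=np.empty((0, 3)),
            cells_per_agent=config.cells_per_agent,
            force_per_cell=config.force_per_cell,
        )
    else:
        pop = init_agents(
            mesh,
            config.total_cells,
            config.cells_per_agent,
            config.force_per_cell,
            seed=config.seed,
        )
    state = SimulationState(
        mesh=mesh, node_coords=mesh.node_coords.copy(), population=pop
    )
    state.history.append(_record(state, time=0.0, strain=None))
    return state


def _record(state: SimulationState, time: float, strain: StrainField | None):
    area = _metrics.projected_area(state.mesh, state.node_coords)
    if state.history:
        a0 = state.history[0].projected_area
        change = 100.0 * (a0 - area) / a0
    else:
        change = 0.0
    pop = state.population
    op = (
        _metrics.order_parameter(pop, (1.0, 0.0, 0.0))
        if pop.n_agents
        else float("nan")
    )
    if strain is None:
        smax = smean = 0.0
    else:
        mags = strain.max_abs
        smax, smean = float(mags.max()), float(mags.mean())
    return _metrics.MetricRecord(
        time=time,
        projected_area=area,
        area_change_percent=change,
        order_parameter=op,
        max_principal_strain=smax,
        mean_principal_strain=smean,
    )


def step(
    state: SimulationState, config: SimulationConfig, ctx: FemContext
) -> SimulationState:
    """Advance the coupled simulation by one timestep (in place)."""
    mesh, pop = state.mesh, state.population
    try:
        if config.load_mode == "element" and pop.n_agents:
            loads = ctx.element_loads(pop, state.node_coords)
        else:
            loads = assemble_agent_loads(
                pop, mesh, node_coords=state.node_coords, mode=config.load_mode
            )
        u = ctx.solve(state.node_coords, loads)
    except ValueError as exc:
        raise RuntimeError(f"FEM solve failed at step {state.step_index}: {exc}")
    # construct strain state = total deformation since day 0, on the
    # reference geometry (small-strain measure of the accumulated field)
    if config.geometry_update:
        total_disp = state.total_displacement + u
    else:
        total_disp = u
    strain = compute_strain(mesh, total_disp)
    if pop.n_agents:
        elem_of, _ = locate_agents(pop, mesh)
        state.population = reorient_agents(
            pop, strain, elem_of, mode=config.guidance_mode
        )
    if config.geometry_update:
        state.node_coords = state.node_coords + u
    state.last_strain = strain
    state.step_index += 1
    state.history.append(
        _record(state, time=state.step_index * config.timestep, strain=strain)
    )
    return state


def _take_snapshot(state: SimulationState, time: float) -> None:
    pop = state.population
    state.snapshots[time] = {
        "time": time,
        "node_coords": state.node_coords.copy(),
        "agent_positions": (
            pop.spatial_positions(state.mesh, state.node_coords)
            if pop.n_agents
            else np.empty((0, 3))
        ),
        "agent_orientations": pop.orientations.copy(),
        "strain": state.last_strain,
    }


def run(config: SimulationConfig) -> SimulationState:
    """Run the full coupled simulation described by ``config``.

    Executes ``duration / timestep`` hourly steps, recording one metric row
    per step (plus t = 0) and a geometry/agent snapshot at each requested
    day.  Two runs from the same seed produce bit-identical histories.
    """
    state = init_state(config)
    ctx = FemContext(state.mesh, config.material, drift=config.reassembly_drift)
    snap_times = sorted({float(d) * DAY for d in config.snapshot_days})
    if any(abs(t) < 1e-9 for t in snap_times):
        _take_snapshot(state, 0.0)
    for _ in range(config.n_steps):
        step(state, config, ctx)
        t = state.step_index * config.timestep
        for ts in snap_times:
            if ts > 0 and abs(t - ts) < 0.5 * config.timestep:
                _take_snapshot(state, ts)
        if state.step_index % 24 == 0:
            rec = state.history[-1]
            logger.info(
                "day %.1f: area %.1f mm^2 (%.3g%% change), order %.3f",
                t / DAY,
                rec.projected_area * 1e6,
                rec.area_change_percent,
                rec.order_parameter,
            )
    return state
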
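"""Quantitative observables of construct development.

The experimental readout the simulation is compared against is the top-view
footprint of the construct photographed over a week of culture, together with
the degree of longitudinal cell alignment.  This module computes:

- ``projected_area``: the area of the construct's projection onto the x-y
  plane (z is the thickness, so x-y is the top view), as the exact polygon
  union of the projected top-surface element faces;
- ``area_change``: the percent reduction of that footprint relative to day 0,
  ``100 * (A0 - A_t) / A0`` — positive for contraction;
- ``order_parameter``: an axial (nematic) alignment statistic of the agent
  orientations about a reference axis.

The order parameter is defined as ``<cos^2 theta>`` over agents, where theta
is the angle between an agent's axis and the reference axis.  This is the
classic nematic order parameter S = (3<cos^2 theta> - 1)/2 rescaled from
[-1/2, 1] to [0, 1] via (S + 1/2)/(3/2): it equals 1 iff all agents share the
reference axis, 0 iff all are perpendicular to it, and 1/3 in expectation for
isotropic orientations.  It is invariant under sign flips of any subset of
orientations, as befits axes without head or tail.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import shapely

from .mesh import HexMesh

__all__ = [
    "MetricRecord",
    "projected_area",
    "area_change",
    "order_parameter",
]

#: top-face corner slots in the VTK hexahedron ordering (max-z face,
#: counter-clockwise seen from +z)
_TOP_FACE = (4, 5, 6, 7)


@dataclass
class MetricRecord:
    """One row of the simulation's metric history.

    ``max_principal_strain`` / ``mean_principal_strain`` summarise the
    largest-magnitude principal value of the incremental strain field of the
    step that produced this record (zero at t = 0).  ``order_parameter`` is
    NaN for an empty population.
    """

    time: float  # s
    projected_area: float  # m^2
    area_change_percent: float  # relative to t = 0; positive = contraction
    order_parameter: float  # [0, 1]
    max_principal_strain: float
    mean_principal_strain: float

    def as_dict(self) -> dict:
        return asdict(self)


def projected_area(
    mesh: HexMesh, node_coords: np.ndarray | None = None
) -> float:
    """Top-view footprint of the (possibly deformed) construct, in m^2.

    The top-surface element faces are projected onto the x-y plane and their
    exact polygon union taken, so overlapping or folded faces are not double
    counted.  Degenerate (zero-area) projected faces raise ``ValueError``
    naming the element.
    """
    coords = mesh.node_coords if node_coords is None else np.asarray(node_coords)
    top = mesh.top_face_elements()
    quads = coords[mesh.elements[top][:, _TOP_FACE], :2]  # (n, 4, 2)
    # shoelace per quad to detect degeneracy before the union
    x, y = quads[..., 0], quads[..., 1]
    signed = 0.5 * np.sum(
        x * np.roll(y, -1, axis=1) - np.roll(x, -1, axis=1) * y, axis=1
    )
    h2 = mesh.element_size**2
    bad = np.flatnonzero(np.abs(signed) < 1e-12 * h2)
    if bad.size:
        raise ValueError(
            f"degenerate projected top face on element {int(top[bad[0]])}"
        )
    polys = shapely.polygons(quads)
    return float(shapely.union_all(polys).area)


def area_change(
    history: Sequence[MetricRecord], time: float | None = None
) -> float:
    """Percent footprint reduction between t = 0 and ``time``.

    ``100 * (A0 - A_t) / A0``; positive numbers mean the construct
    contracted.  ``time`` defaults to the last record.  Raises ``ValueError``
    if the history lacks a t = 0 record or the query time.
    """
    if not history:
        raise ValueError("empty metric history")
    t0 = [r for r in history if r.time == 0.0]
    if not t0:
        raise ValueError("history has no t = 0 record")
    a0 = t0[0].projected_area
    if time is None:
        at = history[-1].projected_area
    else:
        match = [r for r in history if np.isclose(r.time, time)]
        if not match:
            raise ValueError(f"history has no record at t = {time}")
        at = match[0].projected_area
    return 100.0 * (a0 - at) / a0


def order_parameter(pop, axis=(1.0, 0.0, 0.0)) -> float:
    """Axial alignment order parameter ``<cos^2 theta>`` in [0, 1].

    ``pop`` may be an :class:`~constructsim.agents.AgentPopulation` or an
    (n, 3) array of unit orientation vectors.  ``axis`` is normalised before
    use.  Raises ``ValueError`` for an empty population.
    """
    orientations = getattr(pop, "orientations", pop)
    orientations = np.asarray(orientations, dtype=float)
    if orientations.size == 0:
        raise ValueError("order parameter is undefined for an empty population")
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("axis must be a nonzero vector")
    cos = orientations @ (axis / norm)
    return float(np.mean(cos**2))
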
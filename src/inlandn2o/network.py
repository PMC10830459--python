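"""Watershed graph construction and lentic-body classification.

A routing network is a forest of grid cells draining to one or more outlets.
Each cell carries three subgrid flow elements (hillslope -> subnetwork ->
main channel); standing water bodies are attached either to the subnetwork
corridor (small bodies, fed by an intercepted share of hillslope flow) or
in-line on the main channel (large bodies, receiving the full upstream flow).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import pandas as pd

__all__ = [
    "EARTH_RADIUS_M",
    "OUTLET_MARKERS",
    "GridCell",
    "ChannelReach",
    "LenticBody",
    "RoutingNetwork",
    "TopologyError",
    "DanglingReferenceError",
    "SchemaError",
    "cell_area_from_latitude",
    "classify_lentic",
    "interception_fraction",
    "sequential_interception",
    "build_network",
]

EARTH_RADIUS_M = 6_371_000.0

#: downstream-id values that mark a basin outlet
OUTLET_MARKERS = {-1, "-1", "", "outlet", "OUTLET", None}


class TopologyError(ValueError):
    """Drainage links do not form a forest (a cycle exists)."""


class DanglingReferenceError(KeyError):
    """A foreign key points at a row that does not exist."""


class SchemaError(ValueError):
    """An input table violates its schema contract."""


@dataclass(frozen=True)
class GridCell:
    cell_id: int
    area: float                      # m2
    latitude: float
    longitude: float
    downstream_cell: Optional[int]   # None at an outlet
    country_code: int = 0

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise SchemaError(f"cell {self.cell_id}: area must be > 0")


@dataclass(frozen=True)
class ChannelReach:
    cell_id: int
    corridor: str                    # "subnetwork" | "main"
    length: float                    # m
    width: float                     # m
    slope: float                     # dimensionless

    def __post_init__(self) -> None:
        if self.corridor not in ("subnetwork", "main"):
            raise SchemaError(
                f"reach in cell {self.cell_id}: corridor must be "
                f"'subnetwork' or 'main', got {self.corridor!r}"
            )
        if self.length <= 0 or self.width <= 0:
            raise SchemaError(f"reach in cell {self.cell_id}: length and width must be > 0")
        if self.slope < 0:
            raise SchemaError(f"reach in cell {self.cell_id}: slope must be >= 0")

    @property
    def bed_area(self) -> float:
        return self.length * self.width


@dataclass(frozen=True)
class LenticBody:
    body_id: int
    cell_id: int
    kind: str                        # "lake" | "reservoir"
    surface_area: float              # m2
    volume: float                    # m3
    mean_depth: float                # m
    residence_time: float            # days
    upstream_area: float             # m2
    construction_year: Optional[int] = None
    size_class: str = ""             # filled by build_network when empty

    def __post_init__(self) -> None:
        if self.kind not in ("lake", "reservoir"):
            raise SchemaError(f"body {self.body_id}: kind must be 'lake' or 'reservoir'")
        if self.residence_time <= 0:
            raise SchemaError(f"body {self.body_id}: residence_time must be > 0")
        if min(self.surface_area, self.volume, self.mean_depth) <= 0:
            raise SchemaError(f"body {self.body_id}: geometry must be positive")
        if self.upstream_area < 0:
            raise SchemaError(f"body {self.body_id}: upstream_area must be >= 0")
        geom = self.surface_area * self.mean_depth
        if abs(self.volume - geom) > 0.10 * geom:
            raise SchemaError(
                f"body {self.body_id}: volume {self.volume:.3g} deviates >10% from "
                f"surface_area*mean_depth = {geom:.3g}"
            )
        if self.kind == "reservoir" and self.construction_year is None:
            raise SchemaError(f"reservoir {self.body_id}: construction_year required")
        if self.kind == "lake" and self.construction_year is not None:
            raise SchemaError(f"lake {self.body_id}: construction_year must be empty")


def cell_area_from_latitude(latitude: float, resolution: float) -> float:
    """Area (m2) of the spherical quadrangle centred at ``latitude``.

    Uses A = R^2 * dlambda * (sin(phi2) - sin(phi1)) on a sphere of radius
    6 371 000 m; the band is clipped at the poles.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    half = resolution / 2.0
    phi1 = math.radians(max(latitude - half, -90.0))
    phi2 = math.radians(min(latitude + half, 90.0))
    dlam = math.radians(resolution)
    return EARTH_RADIUS_M**2 * dlam * (math.sin(phi2) - math.sin(phi1))


def classify_lentic(upstream_area: float, cell_area: float) -> str:
    """Classify a standing water body by its upstream catchment area.

    ``large`` iff the upstream area strictly exceeds the grid-cell area
    (large bodies sit on the main channel); ties and smaller areas are
    ``small`` (subnetwork corridor).
    """
    if upstream_area < 0 or cell_area < 0:
        raise ValueError("areas must be >= 0")
    return "large" if upstream_area > cell_area else "small"


def interception_fraction(body: LenticBody, cell_area: float) -> float:
    """Share of a cell's hillslope flow intercepted by a small body.

    Equals upstream_area / cell_area clamped to [0, 1].  Large bodies do not
    intercept hillslope flow (they receive the full main-channel flow), so
    calling this on one is a usage error.
    """
    if body.size_class == "large":
        raise ValueError(
            f"body {body.body_id} is large-class; interception applies to small bodies only"
        )
    if cell_area <= 0:
        raise ValueError("cell_area must be > 0")
    return min(body.upstream_area / cell_area, 1.0)


def sequential_interception(bodies: list[LenticBody], cell_area: float) -> list[float]:
    """Effective hillslope shares for co-located small bodies.

    Bodies intercept sequentially in descending upstream area: each takes its
    interception fraction of the flow remaining after the previous one, so
    the total intercepted share never exceeds 1 and water balance is kept.
    Returns shares aligned with the (re-sorted) input order.
    """
    ordered = sorted(bodies, key=lambda b: -b.upstream_area)
    shares: dict[int, float] = {}
    remaining = 1.0
    for body in ordered:
        f = interception_fraction(body, cell_area)
        shares[body.body_id] = f * remaining
        remaining *= 1.0 - f
    return [shares[b.body_id] for b in bodies]


@dataclass
class RoutingNetwork:
    """Validated, topologically sorted watershed graph."""

    cells: dict[int, GridCell]
    order: list[int]                                   # cell ids, upstream first
    reaches: dict[tuple[int, str], ChannelReach]
    bodies: list[LenticBody]
    graph: nx.DiGraph = field(repr=False, default_factory=nx.DiGraph)
    resolution_deg: float = 0.5

    @property
    def outlets(self) -> list[int]:
        return [cid for cid, c in self.cells.items() if c.downstream_cell is None]

    def bodies_in_cell(self, cell_id: int) -> list[LenticBody]:
        return [b for b in self.bodies if b.cell_id == cell_id]

    def cell_index(self) -> dict[int, int]:
        return {cid: i for i, cid in enumerate(self.order)}


def _parse_downstream(value) -> Optional[int]:
    if value in OUTLET_MARKERS:
        return None
    if isinstance(value, float):
        if math.isnan(value):
            return None
        value = int(value)
    if isinstance(value, str):
        value = value.strip()
        if value in OUTLET_MARKERS:
            return None
        value = int(value)
    if value < 0:
        return None
    return int(value)


def build_network(
    cells: pd.DataFrame,
    reaches: pd.DataFrame,
    bodies: pd.DataFrame,
    resolution_deg: float = 0.5,
) -> RoutingNetwork:
    """Assemble and validate the routing network from its three input tables.

    Raises :class:`TopologyError` naming the cycle if the drainage links are
    cyclic, :class:`DanglingReferenceError` for unresolved foreign keys, and
    :class:`SchemaError` for malformed rows.  Bodies with an empty size class
    are classified here against the resolution-implied cell area.
    """
    cell_objs: dict[int, GridCell] = {}
    for row in cells.itertuples(index=False):
        cid = int(row.cell_id)
        if cid in cell_objs:
            raise SchemaError(f"duplicate cell_id {cid}")
        area = cell_area_from_latitude(float(row.lat), resolution_deg)
        cell_objs[cid] = GridCell(
            cell_id=cid,
            area=area,
            latitude=float(row.lat),
            longitude=float(row.lon),
            downstream_cell=_parse_downstream(row.downstream_id),
            country_code=int(getattr(row, "country_code", 0)),
        )

    graph = nx.DiGraph()
    graph.add_nodes_from(cell_objs)
    for cell in cell_objs.values():
        down = cell.downstream_cell
        if down is None:
            continue
        if down == cell.cell_id:
            raise TopologyError(f"cell {cell.cell_id} drains to itself")
        if down not in cell_objs:
            raise DanglingReferenceError(
                f"cell {cell.cell_id} drains to unknown cell {down}"
            )
        graph.add_edge(cell.cell_id, down)

    try:
        cycle = nx.find_cycle(graph)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
        raise TopologyError(f"drainage cycle detected: {path}")
    order = list(nx.topological_sort(graph))

    reach_objs: dict[tuple[int, str], ChannelReach] = {}
    for row in reaches.itertuples(index=False):
        cid = int(row.cell_id)
        if cid not in cell_objs:
            raise DanglingReferenceError(f"reach references unknown cell {cid}")
        reach = ChannelReach(
            cell_id=cid,
            corridor=str(row.corridor),
            length=float(row.length_m),
            width=float(row.width_m),
            slope=float(row.slope),
        )
        key = (cid, reach.corridor)
        if key in reach_objs:
            raise SchemaError(f"duplicate {reach.corridor} reach in cell {cid}")
        reach_objs[key] = reach
    for cid in cell_objs:
        for corridor in ("subnetwork", "main"):
            if (cid, corridor) not in reach_objs:
                raise SchemaError(f"cell {cid} is missing its {corridor} reach")

    body_objs: list[LenticBody] = []
    seen_ids: set[int] = set()
    for row in bodies.itertuples(index=False):
        cid = int(row.cell_id)
        if cid not in cell_objs:
            raise DanglingReferenceError(f"body references unknown cell {cid}")
        built = getattr(row, "built_year", None)
        if built is not None and isinstance(built, float) and math.isnan(built):
            built = None
        body = LenticBody(
            body_id=int(row.body_id),
            cell_id=cid,
            kind=str(row.kind),
            surface_area=float(row.area_m2),
            volume=float(row.volume_m3),
            mean_depth=float(row.depth_m),
            residence_time=float(row.residence_days),
            upstream_area=float(row.upstream_m2),
            construction_year=None if built is None else int(built),
            size_class=classify_lentic(float(row.upstream_m2), cell_objs[cid].area),
        )
        if body.body_id in seen_ids:
            raise SchemaError(f"duplicate body_id {body.body_id}")
        seen_ids.add(body.body_id)
        body_objs.append(body)

    return RoutingNetwork(
        cells=cell_objs,
        order=order,
        reaches=reach_objs,
        bodies=body_objs,
        graph=graph,
        resolution_deg=resolution_deg,
    )
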
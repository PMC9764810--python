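"""Hydraulic network solver by the electrical-circuit analogy.

A perfusion board is a directed graph of nodes and elements (resistors,
check valves, ideal pressure sources).  Pressure plays the role of
voltage and volumetric flow of current; Kirchhoff's current law (mass
conservation) holds at every interior node and each resistive element
obeys Q = ΔP / R.

The solver is a modified nodal analysis: node pressures of non-boundary
nodes are unknowns, plus one flow unknown per "constrained" element —
pressure sources, and zero-resistance resistors or open valves, whose
pressure drop is fixed rather than flow-dependent.  Check valves are
ideal diodes with a cracking pressure: closed (Q = 0) unless the forward
drop exceeds the cracking pressure, open with the drop offset by it.
A consistent valve-state assignment is found by fixed-point iteration
with an exhaustive-enumeration fallback (a Graetz bridge has only 2⁴
states).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkNode",
    "HydraulicElement",
    "FluidicNetwork",
    "NetworkSolution",
    "TopologyError",
    "ValveSolverError",
    "solve_linear",
    "solve_with_valves",
    "branch_pressure_uniformity",
    "BoardLayout",
    "build_board",
    "network_to_dict",
    "network_from_dict",
    "solution_to_table",
]

RESISTOR = "resistor"
CHECK_VALVE = "check_valve"
PRESSURE_SOURCE = "pressure_source"


class TopologyError(ValueError):
    """The network has no unique solution (floating subgraph, no boundary…)."""


class ValveSolverError(RuntimeError):
    """No self-consistent valve-state assignment exists."""


@dataclass
class NetworkNode:
    id: str
    boundary_pressure: float | None = None


@dataclass
class HydraulicElement:
    """One branch of the network.

    kind = "resistor":        Q = (P_from − P_to) / resistance
    kind = "check_valve":     ideal diode, forward direction from→to,
                              open-state Q = (ΔP − cracking) / resistance
                              (pure ΔP = cracking constraint if resistance 0)
    kind = "pressure_source": fixes P_to − P_from = pressure, any flow
    """

    id: str
    from_node: str
    to_node: str
    kind: str = RESISTOR
    resistance: float = 0.0
    cracking_pressure: float = 0.0
    pressure: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in (RESISTOR, CHECK_VALVE, PRESSURE_SOURCE):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.resistance < 0:
            raise ValueError("resistance must be >= 0")
        if self.cracking_pressure < 0:
            raise ValueError("cracking pressure must be >= 0")


@dataclass
class FluidicNetwork:
    nodes: dict[str, NetworkNode] = field(default_factory=dict)
    elements: list[HydraulicElement] = field(default_factory=list)

    # -- construction helpers -------------------------------------------------
    def add_node(self, node_id: str, boundary_pressure: float | None = None) -> NetworkNode:
        if node_id in self.nodes:
            node = self.nodes[node_id]
            if boundary_pressure is not None:
                node.boundary_pressure = boundary_pressure
            return node
        node = NetworkNode(node_id, boundary_pressure)
        self.nodes[node_id] = node
        return node

    def _add_element(self, element: HydraulicElement) -> HydraulicElement:
        if any(e.id == element.id for e in self.elements):
            raise ValueError(f"duplicate element id {element.id!r}")
        self.add_node(element.from_node)
        self.add_node(element.to_node)
        self.elements.append(element)
        return element

    def add_resistor(self, eid: str, from_node: str, to_node: str, resistance: float):
        return self._add_element(
            HydraulicElement(eid, from_node, to_node, RESISTOR, resistance=resistance)
        )

    def add_check_valve(
        self, eid: str, from_node: str, to_node: str,
        cracking_pressure: float, open_resistance: float = 0.0,
    ):
        return self._add_element(
            HydraulicElement(
                eid, from_node, to_node, CHECK_VALVE,
                resistance=open_resistance, cracking_pressure=cracking_pressure,
            )
        )

    def add_pressure_source(self, eid: str, from_node: str, to_node: str, pressure: float):
        return self._add_element(
            HydraulicElement(eid, from_node, to_node, PRESSURE_SOURCE, pressure=pressure)
        )

    def set_boundary_pressure(self, node_id: str, pressure: float | None) -> None:
        self.nodes[node_id].boundary_pressure = pressure

    # -- queries --------------------------------------------------------------
    @property
    def valves(self) -> list[HydraulicElement]:
        return [e for e in self.elements if e.kind == CHECK_VALVE]

    def boundary_nodes(self) -> list[str]:
        return [n.id for n in self.nodes.values() if n.boundary_pressure is not None]


@dataclass
class NetworkSolution:
    node_pressures: dict[str, float]
    element_flows: dict[str, float]
    valve_states: dict[str, bool]
    kcl_residual: float

    def flow(self, element_id: str) -> float:
        return self.element_flows[element_id]

    def pressure_drop(self, network: FluidicNetwork, element_id: str) -> float:
        e = next(el for el in network.elements if el.id == element_id)
        return self.node_pressures[e.from_node] - self.node_pressures[e.to_node]


# ---------------------------------------------------------------------------
# Core linear solve (modified nodal analysis)
# ---------------------------------------------------------------------------

def _assemble_and_solve(
    network: FluidicNetwork,
    open_valves: dict[str, bool],
) -> NetworkSolution:
    """Solve the network with the given valve states (closed valves removed).

    Uses a least-squares solve so that physically indeterminate floating
    subgraphs (e.g. everything downstream of closed valves) get the
    minimum-norm pressure assignment with zero flow, and verifies mass
    conservation on the result.
    """
    node_ids = list(network.nodes)
    free = [nid for nid in node_ids if network.nodes[nid].boundary_pressure is None]
    free_idx = {nid: i for i, nid in enumerate(free)}
    bound = {nid: network.nodes[nid].boundary_pressure
             for nid in node_ids if network.nodes[nid].boundary_pressure is not None}
    if not bound:
        raise TopologyError("network has no boundary pressure")

    # active elements: (element, offset) with either conductance or flow unknown
    resistive: list[tuple[HydraulicElement, float]] = []   # Q = (ΔP − offset)/R
    constrained: list[tuple[HydraulicElement, float]] = [] # ΔP = offset, Q unknown
    for e in network.elements:
        if e.kind == CHECK_VALVE:
            if not open_valves.get(e.id, False):
                continue
            offset = e.cracking_pressure
            if e.resistance > 0:
                resistive.append((e, offset))
            else:
                constrained.append((e, offset))
        elif e.kind == PRESSURE_SOURCE:
            constrained.append((e, -e.pressure))  # P_from − P_to = −pressure
        else:
            if e.resistance > 0:
                resistive.append((e, 0.0))
            else:
                constrained.append((e, 0.0))

    n_free, n_con = len(free), len(constrained)
    n_unknown = n_free + n_con
    rows = n_free + n_con
    A = np.zeros((max(rows, 1), max(n_unknown, 1)))
    b = np.zeros(max(rows, 1))

    # KCL rows at free nodes: sum of outflows = 0
    for e, offset in resistive:
        g = 1.0 / e.resistance
        # Q = g·(P_from − P_to − offset), leaves from_node, enters to_node
        for nid, sign in ((e.from_node, +1.0), (e.to_node, -1.0)):
            if nid in free_idx:
                r = free_idx[nid]
                if e.from_node in free_idx:
                    A[r, free_idx[e.from_node]] += sign * g
                else:
                    b[r] -= sign * g * bound[e.from_node]
                if e.to_node in free_idx:
                    A[r, free_idx[e.to_node]] -= sign * g
                else:
                    b[r] += sign * g * bound[e.to_node]
                b[r] += sign * g * offset
    for k, (e, offset) in enumerate(constrained):
        col = n_free + k
        if e.from_node in free_idx:
            A[free_idx[e.from_node], col] += 1.0  # flow leaves from_node
        if e.to_node in free_idx:
            A[free_idx[e.to_node], col] -= 1.0
        # constraint row: P_from − P_to = offset
        r = n_free + k
        if e.from_node in free_idx:
            A[r, free_idx[e.from_node]] += 1.0
        else:
            b[r] -= bound[e.from_node]
        if e.to_node in free_idx:
            A[r, free_idx[e.to_node]] -= 1.0
        else:
            b[r] += bound[e.to_node]
        b[r] += offset

    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    residual = float(np.linalg.norm(A @ x - b))
    scale = max(1.0, float(np.linalg.norm(b)), max((abs(p) for p in bound.values()), default=1.0))
    if residual > 1e-8 * scale:
        raise TopologyError(f"inconsistent network equations (residual {residual:.3g})")

    pressures = dict(bound)
    for nid in free:
        pressures[nid] = float(x[free_idx[nid]])

    flows: dict[str, float] = {e.id: 0.0 for e in network.elements}
    for e, offset in resistive:
        flows[e.id] = (pressures[e.from_node] - pressures[e.to_node] - offset) / e.resistance
    for k, (e, _offset) in enumerate(constrained):
        flows[e.id] = float(x[n_free + k])

    # mass-conservation check at interior nodes, relative to the largest
    # flow anywhere in the network (per-node normalization is meaningless
    # at stagnant nodes)
    net = {nid: 0.0 for nid in free}
    for e in network.elements:
        q = flows[e.id]
        if e.from_node in net:
            net[e.from_node] -= q
        if e.to_node in net:
            net[e.to_node] += q
    q_scale = max((abs(q) for q in flows.values()), default=0.0)
    kcl = max((abs(v) for v in net.values()), default=0.0) / max(q_scale, 1e-300)
    if q_scale == 0.0:
        kcl = 0.0
    states = {v.id: open_valves.get(v.id, False) for v in network.valves}
    return NetworkSolution(pressures, flows, states, kcl)


def solve_linear(network: FluidicNetwork) -> NetworkSolution:
    """Solve a purely resistive network (no valves allowed)."""
    if network.valves:
        raise ValueError("network contains check valves; use solve_with_valves")
    if len(network.boundary_nodes()) < 1:
        raise TopologyError("at least one boundary pressure required")
    return _assemble_and_solve(network, {})


def _states_consistent(network: FluidicNetwork, sol: NetworkSolution,
                       states: dict[str, bool], tol: float) -> bool:
    for v in network.valves:
        dp = sol.node_pressures[v.from_node] - sol.node_pressures[v.to_node]
        if states[v.id]:
            if sol.element_flows[v.id] < -tol:
                return False
        else:
            if dp > v.cracking_pressure + tol:
                return False
    return True


def solve_with_valves(network: FluidicNetwork, max_iter: int = 50,
                      tol: float = 1e-9) -> NetworkSolution:
    """Solve a network containing check valves.

    Fixed-point iteration over valve open/closed states: closed valves
    whose forward drop exceeds the cracking pressure are opened, open
    valves carrying reverse flow are closed.  Falls back to exhaustive
    enumeration if the iteration cycles (feasible for small bridges).
    """
    valves = network.valves
    if not valves:
        return solve_linear(network)
    states = {v.id: False for v in valves}
    seen = set()
    for _ in range(max_iter):
        key = tuple(sorted(states.items()))
        if key in seen:
            break
        seen.add(key)
        sol = _assemble_and_solve(network, states)
        changed = False
        for v in valves:
            dp = sol.node_pressures[v.from_node] - sol.node_pressures[v.to_node]
            if states[v.id] and sol.element_flows[v.id] < -tol:
                states[v.id] = False
                changed = True
            elif not states[v.id] and dp > v.cracking_pressure + tol:
                states[v.id] = True
                changed = True
        if not changed:
            if _states_consistent(network, sol, states, tol):
                return sol
            break
    # exhaustive fallback
    if len(valves) > 16:
        raise ValveSolverError("too many valves for exhaustive enumeration")
    for combo in itertools.product([False, True], repeat=len(valves)):
        states = {v.id: o for v, o in zip(valves, combo)}
        try:
            sol = _assemble_and_solve(network, states)
        except TopologyError:
            continue
        if _states_consistent(network, sol, states, tol):
            return sol
    raise ValveSolverError("no consistent valve-state assignment found")


@dataclass
class BoardLayout:
    """A built perfusion board: the network plus bookkeeping for analysis.

    The feeder ladder runs A → F1 → … → Fn and the waste ladder
    W1 → … → Wn → B, so every sample's path crosses the same number of
    loop segments (counterflow ladder); with equal segment resistances
    this equalizes the driving ΔP across sample positions.
    """

    network: FluidicNetwork
    sample_ids: list[str]
    branch_pairs: list[tuple[str, str]]
    feeder_sensor: str = "A"
    waste_sensor: str = "B"


def build_board(
    branch_resistances: list[float],
    feeder_segment_resistance: float = 0.0,
    waste_segment_resistance: float = 0.0,
    supply_resistance: float = 0.0,
    with_valves: bool = True,
    cracking_pressure: float = 1200.0,
    valve_open_resistance: float = 0.0,
) -> BoardLayout:
    """Assemble the recirculating perfusion board network.

    ``branch_resistances`` holds one total branch resistance per sample
    (equalizing resistor + lumen).  With valves, the four check valves
    form a rectifier bridge between reservoirs R1/R2 and the board nodes
    A (feeder inlet) / B (waste outlet); without valves, R1 feeds A and
    B drains to R2 through plain supply resistors (or direct ties).
    """
    n = len(branch_resistances)
    if n < 1:
        raise ValueError("at least one sample branch required")
    net = FluidicNetwork()
    for nid in ("R1", "R2", "A", "B"):
        net.add_node(nid)

    if with_valves:
        net.add_check_valve("valve_r1_feed", "R1", "A", cracking_pressure, valve_open_resistance)
        net.add_check_valve("valve_r2_feed", "R2", "A", cracking_pressure, valve_open_resistance)
        net.add_check_valve("valve_waste_r1", "B", "R1", cracking_pressure, valve_open_resistance)
        net.add_check_valve("valve_waste_r2", "B", "R2", cracking_pressure, valve_open_resistance)
        if supply_resistance > 0:
            # supply tubing sits between each reservoir and its valve pair
            for res in ("R1", "R2"):
                net.add_resistor(f"tubing_{res}", res, f"{res}t", supply_resistance / 2.0)
            for v in net.valves:
                if v.from_node in ("R1", "R2"):
                    v.from_node = f"{v.from_node}t"
                if v.to_node in ("R1", "R2"):
                    v.to_node = f"{v.to_node}t"
                net.add_node(v.from_node)
                net.add_node(v.to_node)
    else:
        net.add_resistor("supply_in", "R1", "A", max(supply_resistance, 0.0))
        net.add_resistor("supply_out", "B", "R2", max(supply_resistance, 0.0))

    sample_ids, branch_pairs = [], []
    prev = "A"
    for i in range(1, n + 1):
        net.add_resistor(f"feeder_seg{i}", prev, f"F{i}", feeder_segment_resistance)
        prev = f"F{i}"
    for i in range(1, n + 1):
        sid = f"sample{i}"
        net.add_resistor(sid, f"F{i}", f"W{i}", branch_resistances[i - 1])
        sample_ids.append(sid)
        branch_pairs.append((f"F{i}", f"W{i}"))
    for i in range(1, n):
        net.add_resistor(f"waste_seg{i}", f"W{i}", f"W{i + 1}", waste_segment_resistance)
    net.add_resistor(f"waste_seg{n}", f"W{n}", "B", waste_segment_resistance)
    return BoardLayout(net, sample_ids, branch_pairs)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def network_to_dict(network: FluidicNetwork) -> dict:
    return {
        "nodes": [
            {"id": n.id, "boundary_pressure": n.boundary_pressure, "unit": "Pa"}
            for n in network.nodes.values()
        ],
        "elements": [
            {
                "id": e.id,
                "from": e.from_node,
                "to": e.to_node,
                "kind": e.kind,
                "resistance": e.resistance,
                "cracking_pressure": e.cracking_pressure,
                "pressure": e.pressure,
                "units": {"resistance": "Pa.s/m3", "pressure": "Pa"},
            }
            for e in network.elements
        ],
    }


def network_from_dict(data: dict) -> FluidicNetwork:
    net = FluidicNetwork()
    for n in data.get("nodes", []):
        net.add_node(n["id"], n.get("boundary_pressure"))
    for e in data.get("elements", []):
        net._add_element(
            HydraulicElement(
                e["id"], e["from"], e["to"], e.get("kind", RESISTOR),
                resistance=e.get("resistance", 0.0),
                cracking_pressure=e.get("cracking_pressure", 0.0),
                pressure=e.get("pressure", 0.0),
            )
        )
    return net


def solution_to_table(network: FluidicNetwork, solution: NetworkSolution):
    """Per-element flow and pressure drop as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    rows = []
    for e in network.elements:
        rows.append(
            {
                "element": e.id,
                "kind": e.kind,
                "flow_m3_per_s": solution.element_flows[e.id],
                "dp_pa": solution.node_pressures[e.from_node]
                - solution.node_pressures[e.to_node],
                "valve_open": solution.valve_states.get(e.id, ""),
            }
        )
    return pd.DataFrame(rows)


def branch_pressure_uniformity(
    solution: NetworkSolution, branch_pairs: list[tuple[str, str]]
) -> float:
    """Relative spread (max − min)/mean of ΔP across (feeder, waste) tap pairs.

    Zero means every sample position sees an identical driving pressure.
    """
    dps = [solution.node_pressures[f] - solution.node_pressures[w] for f, w in branch_pairs]
    mean = sum(dps) / len(dps)
    if mean == 0:
        raise ValueError("mean branch pressure difference is zero")
    return (max(dps) - min(dps)) / mean
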
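"""Selection diagrams and transportability classification.

A selection diagram is a causal DAG over the variables shared by a study and a
target population, augmented with selection (S) nodes pointing at every
variable whose generating mechanism differs between the two populations.  The
question "does the effect of the exposure on the outcome transport?" reduces
to a d-separation test: in the graph with all incoming arrows to the exposure
removed, the effect transports directly if the S nodes are d-separated from
the outcome unconditionally, and transports after recalibration on a covariate
set Z measured in the target if S is d-separated from the outcome given Z.
If no measured set blocks the S-outcome paths, transport is not guaranteed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

_S_PREFIX = "__S__"


@dataclass(frozen=True)
class SelectionDiagram:
    """A DAG plus the set of nodes receiving an arrow from a selection variable."""

    nodes: frozenset
    edges: frozenset
    exposure: str
    outcome: str
    s_pointed: frozenset

    def graph(self) -> nx.DiGraph:
        """The bare DAG, without selection nodes."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def augmented_graph(self, shared_s: bool = False) -> nx.DiGraph:
        """DAG with selection variables materialized as exogenous parents.

        By default one S node per member of ``s_pointed`` (matching the notion
        of a *set* of selection variables); with ``shared_s=True`` a single S
        node points at all of them.
        """
        g = self.graph()
        if shared_s:
            if self.s_pointed:
                g.add_node(_S_PREFIX)
                for v in sorted(self.s_pointed):
                    g.add_edge(_S_PREFIX, v)
        else:
            for v in sorted(self.s_pointed):
                g.add_edge(f"{_S_PREFIX}{v}", v)
        return g

    def selection_nodes(self, shared_s: bool = False) -> set:
        if shared_s:
            return {_S_PREFIX} if self.s_pointed else set()
        return {f"{_S_PREFIX}{v}" for v in self.s_pointed}


@dataclass(frozen=True)
class TransportClass:
    """Outcome of the transportability classification.

    ``category`` is one of ``trivial`` (the effect is identifiable in the
    target population itself), ``direct`` (transports with no recalibration),
    ``via_recalibration`` (transports after standardizing over
    ``adjustment_set``), or ``not_identified_by_rule``.
    """

    category: str
    adjustment_set: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        valid = {"trivial", "direct", "via_recalibration", "not_identified_by_rule"}
        if self.category not in valid:
            raise ValueError(f"category must be one of {sorted(valid)}")
        if self.adjustment_set and self.category != "via_recalibration":
            raise ValueError("adjustment_set may be nonempty only for via_recalibration")


def build_diagram(nodes, edges, exposure, outcome, s_pointed=()) -> SelectionDiagram:
    """Validate inputs and construct a :class:`SelectionDiagram`.

    Rejects cycles, edges or selection marks on undeclared nodes, and
    coinciding exposure/outcome labels.
    """
    nodes = frozenset(nodes)
    edges = frozenset((str(u), str(v)) for u, v in edges)
    s_pointed = frozenset(s_pointed)
    if exposure == outcome:
        raise ValueError("exposure and outcome must be distinct nodes")
    for label, node in (("exposure", exposure), ("outcome", outcome)):
        if node not in nodes:
            raise ValueError(f"{label} node {node!r} is not a declared node")
    for u, v in edges:
        if u not in nodes or v not in nodes:
            raise ValueError(f"edge ({u!r}, {v!r}) uses an undeclared node")
    unknown = s_pointed - nodes
    if unknown:
        raise ValueError(f"s_pointed contains undeclared nodes: {sorted(unknown)}")
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"graph contains a cycle: {cycle}")
    return SelectionDiagram(nodes=nodes, edges=edges, exposure=exposure, outcome=outcome, s_pointed=s_pointed)


def d_separated(diagram: SelectionDiagram | nx.DiGraph, x, y, z=(), *, include_s: bool = True) -> bool:
    """Test whether node sets ``x`` and ``y`` are d-separated given ``z``.

    Standard semantics: chains and forks are blocked by conditioning, colliders
    are open only if the collider or one of its descendants is conditioned on.
    When a :class:`SelectionDiagram` is passed, its selection variables are
    materialized as explicit parent nodes before testing (so ``x`` or ``y`` may
    refer to them via :meth:`SelectionDiagram.selection_nodes`).
    """
    if isinstance(diagram, SelectionDiagram):
        g = diagram.augmented_graph() if include_s else diagram.graph()
    else:
        g = diagram
    x, y, z = set(x), set(y), set(z)
    if (x & y) or (x & z) or (y & z):
        raise ValueError("x, y, z must be pairwise disjoint")
    for nset, name in ((x, "x"), (y, "y"), (z, "z")):
        unknown = nset - set(g.nodes)
        if unknown:
            raise ValueError(f"{name} contains unknown nodes: {sorted(unknown)}")
    if not x or not y:
        return True
    return nx.is_d_separator(g, x, y, z)


def _remove_incoming_to(g: nx.DiGraph, node) -> nx.DiGraph:
    h = g.copy()
    h.remove_edges_from(list(h.in_edges(node)))
    return h


def transportability_class(
    diagram: SelectionDiagram,
    measured_target_covariates=(),
    *,
    target_has_trial_data: bool = False,
) -> TransportClass:
    """Classify transportability of the exposure-outcome effect.

    Applies the graphical rule: remove every incoming arrow to the exposure,
    then ask whether the selection nodes are d-separated from the outcome —
    unconditionally (direct transport) or given some subset of the covariates
    measured in the target (transport via recalibration, reported with a
    minimal such subset).  ``target_has_trial_data`` asserts that exposure and
    outcome are themselves observed in the target population, in which case the
    effect is trivially identifiable there and no transport is needed; that
    assertion is causal knowledge outside the diagram and is never inferred.

    Ties among equal-size minimal adjustment sets are broken lexicographically.
    """
    measured = frozenset(measured_target_covariates)
    forbidden = measured & {diagram.exposure, diagram.outcome}
    if forbidden:
        raise ValueError(f"measured covariates may not include exposure/outcome: {sorted(forbidden)}")
    unknown = measured - diagram.nodes
    if unknown:
        raise ValueError(f"measured covariates are not diagram nodes: {sorted(unknown)}")

    if target_has_trial_data:
        return TransportClass(category="trivial")
    if not diagram.s_pointed:
        return TransportClass(category="direct")

    g = _remove_incoming_to(diagram.augmented_graph(), diagram.exposure)
    s_nodes = diagram.selection_nodes()
    # selection nodes whose only child was the exposure are now isolated
    if nx.is_d_separator(g, s_nodes, {diagram.outcome}, set()):
        return TransportClass(category="direct")
    for size in range(1, len(measured) + 1):
        for subset in sorted(itertools.combinations(sorted(measured), size)):
            z = set(subset)
            if nx.is_d_separator(g, s_nodes - z, {diagram.outcome} - z, z):
                return TransportClass(category="via_recalibration", adjustment_set=frozenset(subset))
    return TransportClass(category="not_identified_by_rule")


def parse_edge_list(text: str) -> list[tuple[str, str]]:
    """Parse a ``"Z1 -> A"`` one-edge-per-line description into edge pairs."""
    edges = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "->" not in line:
            raise ValueError(f"line {lineno}: expected 'U -> V', got {raw!r}")
        u, v = (part.strip() for part in line.split("->", 1))
        if not u or not v:
            raise ValueError(f"line {lineno}: empty endpoint in {raw!r}")
        edges.append((u, v))
    return edges
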
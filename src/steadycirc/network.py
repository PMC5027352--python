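"""Series-parallel resistance networks and pressure-transfer coefficients.

Each vascular circuit (pulmonary or systemic) is a series-parallel
composition of compartments.  A compartment's capacitive node sits
between its arterial (inflow) resistance RA and venous (outflow)
resistance RV, so in steady flow the node pressure exceeds the
downstream atrial pressure by the resistive drop accumulated between
the node and the atrium:

    P_n = P_atrium + G_n * Q

where Q is total cardiac output.  G_n sums every resistance on the
path from the node to the atrium, each weighted by the fraction of Q
that actually traverses it.  For a compartment inside a parallel
group, the branch flow fraction is the group's equivalent resistance
divided by the branch's total resistance.

Only series-parallel trees are supported: they reduce exactly by
recursion, and the branch-fraction definition above is then unique.
Arbitrary resistor graphs (bridges, meshes) raise
:class:`~steadycirc.errors.UnsupportedTopologyError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Tuple, Union

from .errors import InvalidModelError, UnsupportedTopologyError

__all__ = [
    "Leaf",
    "Series",
    "Parallel",
    "series",
    "parallel",
    "leaf_ids",
    "ResistanceNetwork",
    "GCoefficients",
    "equivalent_resistance",
    "derive_g_coefficients",
]


# --------------------------------------------------------------------------
# Topology nodes


@dataclass(frozen=True)
class Leaf:
    """A single compartment in the circuit (carries RA and RV)."""

    compartment: str


@dataclass(frozen=True)
class Series:
    """Children in series, ordered from the arterial (upstream) side to
    the venous (atrial) side: the last child is adjacent to the atrium."""

    children: Tuple["Node", ...]


@dataclass(frozen=True)
class Parallel:
    """Branches sharing the same entry and exit nodes."""

    branches: Tuple["Node", ...]


Node = Union[Leaf, Series, Parallel]
NodeLike = Union[str, Node]


def _coerce(item: NodeLike) -> Node:
    if isinstance(item, str):
        return Leaf(item)
    if isinstance(item, (Leaf, Series, Parallel)):
        return item
    raise UnsupportedTopologyError(
        f"cannot interpret {item!r} as a series-parallel topology node"
    )


def series(*items: NodeLike) -> Node:
    """Build a series chain; single-item chains collapse to the item."""
    nodes = tuple(_coerce(i) for i in items)
    if not nodes:
        raise UnsupportedTopologyError("empty series group")
    return nodes[0] if len(nodes) == 1 else Series(nodes)


def parallel(*items: NodeLike) -> Node:
    """Build a parallel group; single-branch groups collapse to the branch."""
    nodes = tuple(_coerce(i) for i in items)
    if not nodes:
        raise UnsupportedTopologyError("empty parallel group")
    return nodes[0] if len(nodes) == 1 else Parallel(nodes)


def leaf_ids(node: Node) -> List[str]:
    """Compartment ids in the subtree, in traversal order."""
    if isinstance(node, Leaf):
        return [node.compartment]
    if isinstance(node, Series):
        out: List[str] = []
        for c in node.children:
            out.extend(leaf_ids(c))
        return out
    if isinstance(node, Parallel):
        out = []
        for b in node.branches:
            out.extend(leaf_ids(b))
        return out
    raise UnsupportedTopologyError(f"unknown topology node {node!r}")


# --------------------------------------------------------------------------
# Bound network (topology + resistances)


@dataclass(eq=False)
class ResistanceNetwork:
    """A series-parallel topology bound to per-compartment RA/RV values."""

    root: Node
    arterial: Dict[str, float]
    venous: Dict[str, float]

    def __post_init__(self) -> None:
        ids = leaf_ids(self.root)
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise UnsupportedTopologyError(
                f"compartment(s) {dupes} appear in more than one leaf"
            )
        missing = set(ids) - set(self.arterial) | set(ids) - set(self.venous)
        if missing:
            raise InvalidModelError(
                f"no resistances supplied for compartment(s) {sorted(missing)}"
            )
        for cid in ids:
            if self.arterial[cid] < 0 or self.venous[cid] < 0:
                raise InvalidModelError(f"negative resistance on {cid!r}")

    @classmethod
    def from_compartments(cls, root: NodeLike, compartments: Iterable) -> "ResistanceNetwork":
        """Bind a topology to :class:`~steadycirc.model.Compartment` objects.

        Every supplied compartment must appear in exactly one leaf.
        """
        root = _coerce(root)
        comps = list(compartments)
        ids = leaf_ids(root)
        comp_ids = [c.id for c in comps]
        if sorted(ids) != sorted(comp_ids):
            raise UnsupportedTopologyError(
                f"topology leaves {sorted(ids)} do not match circuit "
                f"compartments {sorted(comp_ids)}"
            )
        arterial = {c.id: float(c.RA) for c in comps}
        venous = {c.id: float(c.RV) for c in comps}
        return cls(root, arterial, venous)

    def equivalent_resistance(self) -> float:
        return equivalent_resistance(self)

    def g_coefficients(self) -> "GCoefficients":
        return derive_g_coefficients(self)


@dataclass(frozen=True)
class GCoefficients:
    """Pressure-transfer coefficients for one circuit.

    Attributes
    ----------
    G : mapping id -> mmHg/(L/min)
        ``P_n = P_atrium + G[n] * Q`` for each capacitive node.
    fractions : mapping id -> dimensionless
        Fraction of cardiac output flowing through each compartment.
    groups : tuple of tuples
        Branch flow fractions of each parallel group, normalized to the
        flow entering the group (each inner tuple sums to 1).
    """

    G: Mapping[str, float]
    fractions: Mapping[str, float]
    groups: Tuple[Tuple[float, ...], ...] = field(default_factory=tuple)


def _req(node: Node, net: ResistanceNetwork) -> float:
    """Equivalent resistance of a subtree."""
    if isinstance(node, Leaf):
        return net.arterial[node.compartment] + net.venous[node.compartment]
    if isinstance(node, Series):
        return sum(_req(c, net) for c in node.children)
    if isinstance(node, Parallel):
        branch_r = [_req(b, net) for b in node.branches]
        if any(r <= 0.0 for r in branch_r):
            raise InvalidModelError(
                "parallel branch with zero total resistance (short circuit)"
            )
        return 1.0 / sum(1.0 / r for r in branch_r)
    raise UnsupportedTopologyError(f"unknown topology node {node!r}")


def equivalent_resistance(net: ResistanceNetwork) -> float:
    """Total equivalent resistance of the circuit (TPR for the systemic bed)."""
    r = _req(net.root, net)
    if r <= 0.0:
        raise InvalidModelError("circuit equivalent resistance must be positive")
    return r


def derive_g_coefficients(net: ResistanceNetwork) -> GCoefficients:
    """Reduce a series-parallel circuit to pressure-transfer coefficients.

    The recursion carries two quantities into each subtree: the flow
    fraction ``f`` through it, and ``g0`` — the pressure drop (per unit
    cardiac output) from the subtree's exit node down to the atrium,
    already accumulated on shared segments.  A leaf then contributes
    ``G = g0 + RV * f``.
    """
    G: Dict[str, float] = {}
    fractions: Dict[str, float] = {}
    groups: List[Tuple[float, ...]] = []

    def walk(node: Node, f: float, g0: float) -> None:
        if isinstance(node, Leaf):
            cid = node.compartment
            fractions[cid] = f
            G[cid] = g0 + net.venous[cid] * f
        elif isinstance(node, Series):
            # children ordered arterial -> venous; child i sees the
            # equivalent resistance of everything downstream of it
            downstream = 0.0
            offsets = []
            for child in reversed(node.children):
                offsets.append(downstream)
                downstream += _req(child, net)
            for child, extra in zip(node.children, reversed(offsets)):
                walk(child, f, g0 + f * extra)
        elif isinstance(node, Parallel):
            rp = _req(node, net)
            branch_fracs = tuple(rp / _req(b, net) for b in node.branches)
            groups.append(branch_fracs)
            for b, fb in zip(node.branches, branch_fracs):
                walk(b, f * fb, g0)
        else:  # pragma: no cover - guarded by _coerce/_req
            raise UnsupportedTopologyError(f"unknown topology node {node!r}")

    walk(net.root, 1.0, 0.0)
    return GCoefficients(G=G, fractions=fractions, groups=tuple(groups))
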